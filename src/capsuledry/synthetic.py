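"""Synthetic drying curves and MRI phantoms with the study's structure.

The generator emulates a hard-capsule drying experiment: an initial
dry-basis moisture of 8.44 g/g, a 0.2 mm shell split into 4 layers, five
drying conditions (35/40/45 degC at RH 60 %, and RH 40/50/60 % at 35 degC),
20-minute sampling and multiplicative measurement noise below 10 %
coefficient of variation.

The default diffusivity magnitude is chosen internally consistent with the
~140-minute drying timescale at the 0.2 mm thickness (order 1e-12 to 1e-11
m^2 s^-1): a slab of thickness L dries on the scale L^2/D, so diffusivities
of a few 1e-10 m^2 s^-1 would empty this film in about a minute.  The
``paper_scale`` preset instead uses diffusivities in the few-1e-10 range
with a proportionally shorter time axis, preserving the identical
dimensionless drying problem.

All randomness is drawn from ``numpy`` generators seeded from the config
seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Union

import numpy as np

from .diffusivity import DeffParams, DryingConditions
from .errors import ConfigError
from .estimation import DryingCurve
from .mri import MRISequenceParams, MRISeries, signal_from_density
from .solver import (
    MoistureHistory,
    ShellGrid,
    SolverOptions,
    build_grid,
    simulate,
)

#: Default equilibrium moisture [g/g]; the study never reports per-condition
#: values, so a single configurable plateau is used for every condition.
DEFAULT_EQUILIBRIUM_MOISTURE = 0.10


def default_conditions(
    equilibrium_moisture: Union[float, dict] = DEFAULT_EQUILIBRIUM_MOISTURE,
) -> List[DryingConditions]:
    """The five study conditions: RH 40/50/60 % at 35 degC, then 40 and
    45 degC at RH 60 %; hot air at 2 m s^-1.

    ``equilibrium_moisture`` may be a scalar applied to every condition or a
    ``{(T_c, RH): M_e}`` mapping.
    """
    pairs = [(35.0, 40.0), (35.0, 50.0), (35.0, 60.0), (40.0, 60.0), (45.0, 60.0)]
    out = []
    for t_c, rh in pairs:
        if isinstance(equilibrium_moisture, dict):
            m_e = equilibrium_moisture[(t_c, rh)]
        else:
            m_e = float(equilibrium_moisture)
        out.append(
            DryingConditions(
                temperature_c=t_c,
                relative_humidity=rh,
                equilibrium_moisture=m_e,
                air_velocity=2.0,
            )
        )
    return out


@dataclass(frozen=True)
class PhantomGeometry:
    """Annular shell cross-section rendered onto a square image."""

    image_size: int = 64
    r_inner: float = 20.0
    r_outer: float = 28.0
    pixel_size: float = 1e-4
    noise_sigma_frac: float = 0.01
    erode_px: float = 1.0

    def __post_init__(self) -> None:
        if self.r_inner <= 0 or self.r_outer <= self.r_inner:
            raise ConfigError("annulus radii must satisfy 0 < r_inner < r_outer")
        if self.image_size < 2 * self.r_outer:
            raise ConfigError("image too small for the annulus")
        if self.noise_sigma_frac < 0 or self.erode_px < 0:
            raise ConfigError("noise and erosion settings must be non-negative")


def _default_params() -> DeffParams:
    # Rise-then-fall moisture dependence peaking at M = a/(2b) = 2 g/g;
    # magnitude consistent with the 140-min drying of a 0.2 mm film
    # (mean moisture ratio ~0.045 at 80 min under the slowest condition).
    return DeffParams(D0=1e-6, Ea=3.0e4, a=0.2, b=0.05)


@dataclass
class GeneratorConfig:
    """Study conditions and noise model for the synthetic experiment."""

    true_params: DeffParams = field(default_factory=_default_params)
    M0: float = 8.44
    conditions: List[DryingConditions] = field(default_factory=default_conditions)
    grid: ShellGrid = field(default_factory=lambda: build_grid(2e-4, 4))
    sampling_interval_min: float = 20.0
    duration_min: float = 140.0
    noise_cv: float = 0.05
    seed: int = 20230605
    solver: SolverOptions = field(default_factory=SolverOptions)
    phantom: PhantomGeometry = field(default_factory=PhantomGeometry)
    sequence_params: MRISequenceParams = field(default_factory=MRISequenceParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.1:
            raise ConfigError(
                "noise_cv must be within [0, 0.1] (experimental error < 10 %)"
            )
        if self.sampling_interval_min <= 0 or self.duration_min <= 0:
            raise ConfigError("sampling interval and duration must be positive")
        if self.M0 <= 0:
            raise ConfigError("initial moisture must be positive")

    @property
    def sample_times_min(self) -> np.ndarray:
        n = int(round(self.duration_min / self.sampling_interval_min))
        return np.arange(n + 1) * self.sampling_interval_min

    @classmethod
    def paper_scale(cls, scale: float = 50.0, **kwargs) -> "GeneratorConfig":
        """Preset with diffusivities in the few-1e-10 m^2 s^-1 range and a
        time axis shortened by the same factor (identical dimensionless
        problem)."""
        base = _default_params()
        return cls(
            true_params=dataclasses.replace(base, D0=base.D0 * scale),
            sampling_interval_min=20.0 / scale,
            duration_min=140.0 / scale,
            **kwargs,
        )


def _truncated_multiplicative(rng, shape, cv: float) -> np.ndarray:
    eps = rng.normal(0.0, cv, size=shape)
    return 1.0 + np.clip(eps, -3.0 * cv, 3.0 * cv)


def simulate_condition(cfg: GeneratorConfig, cond: DryingConditions) -> MoistureHistory:
    """Noiseless solver run for one condition at the sampling times."""
    times_s = cfg.sample_times_min * 60.0
    return simulate(
        m0=cfg.M0,
        params=cfg.true_params,
        cond=cond,
        grid=cfg.grid,
        t_end=float(times_s[-1]),
        output_times=times_s,
        options=cfg.solver,
    )


def generate_drying_experiment(cfg: GeneratorConfig) -> List[DryingCurve]:
    """Synthetic weighing-style drying curves for every configured condition.

    Each condition is simulated noiselessly, sampled at the configured
    interval, and perturbed with multiplicative Gaussian noise (coefficient
    of variation ``noise_cv``, truncated at +-3 sigma) independently for the
    average series and for every nodal (per-layer) series; values are
    clamped at the equilibrium moisture.  The t = 0 average is the uniform
    film value M0 (the film is weighed before the surface equilibrates).
    Deterministic per seed; a warning is recorded in the curve metadata when
    the configured duration leaves the film at more than half its initial
    moisture.
    """
    curves = []
    for i, cond in enumerate(cfg.conditions):
        hist = simulate_condition(cfg, cond)
        avg_true = hist.average()
        avg_true[0] = cfg.M0
        layers_true = hist.fields.copy()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        m_e = cond.equilibrium_moisture
        avg_obs = np.maximum(
            avg_true * _truncated_multiplicative(rng, avg_true.shape, cfg.noise_cv),
            m_e,
        )
        layer_obs = np.maximum(
            layers_true
            * _truncated_multiplicative(rng, layers_true.shape, cfg.noise_cv),
            m_e,
        )
        warnings = []
        if avg_true[-1] > 0.5 * cfg.M0:
            warnings.append(
                "duration inconsistent with diffusivity: film still above half "
                "its initial moisture at the end of the run"
            )
        curves.append(
            DryingCurve(
                condition=cond,
                times_min=cfg.sample_times_min,
                m_avg=avg_obs,
                per_layer=layer_obs,
                m0_nominal=cfg.M0,
                provenance="synthetic",
                m_avg_true=avg_true,
                per_layer_true=layers_true,
                warnings=warnings,
            )
        )
    return curves


def phantom_masks(geom: PhantomGeometry, n_layers: int):
    """Radial annulus masks: shell zone (eroded), layer labels, middle band.

    Layer labels split the annulus into Z+1 equal radial bands, node 0 at
    the inner (pin-side) radius and node Z at the outer (air-side) radius.
    The analysis zone is the annulus with ``erode_px`` trimmed from both
    radial boundaries, excluding partial-volume pixels.
    """
    if geom.r_outer - geom.r_inner < n_layers:
        raise ConfigError(
            "annulus thinner than the number of shell layers; cannot label layers"
        )
    n = geom.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    shell = (r >= geom.r_inner) & (r < geom.r_outer)
    width = geom.r_outer - geom.r_inner
    frac = np.clip((r - geom.r_inner) / width, 0.0, 1.0 - 1e-12)
    labels = np.where(shell, np.floor(frac * (n_layers + 1)).astype(int), -1)
    zone = (r >= geom.r_inner + geom.erode_px) & (r < geom.r_outer - geom.erode_px)
    band = width / 3.0
    middle = (r >= geom.r_inner + band) & (r < geom.r_outer - band)
    return shell, labels, zone, middle


def generate_mri_series(cfg: GeneratorConfig, history: MoistureHistory) -> MRISeries:
    """Render a MoistureHistory as a proton-density phantom image series.

    Each shell pixel's hydrogen density is proportional to the moisture of
    its radial layer; the signal follows the spin-echo law with the config's
    sequence parameters, plus additive Gaussian background noise with sigma
    equal to ``noise_sigma_frac`` of the mean initial shell signal.
    """
    geom = cfg.phantom
    z = history.grid.n_layers
    shell, labels, zone, _middle = phantom_masks(geom, z)
    p = cfg.sequence_params
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9999]))
    frames = np.zeros((history.times.size, geom.image_size, geom.image_size))
    for i in range(history.times.size):
        rho = np.zeros_like(frames[0])
        nodal = history.fields[i]
        rho[shell] = nodal[labels[shell]]
        frames[i] = signal_from_density(p, rho)
    sigma = geom.noise_sigma_frac * float(frames[0][shell].mean())
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)
    return MRISeries(
        frames=frames,
        zone_mask=zone,
        pixel_size=geom.pixel_size,
        times_min=history.times / 60.0,
        layer_labels=labels,
        sequence_params=p,
    )
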