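"""Explicit finite-difference solver for 1-D drying of the capsule shell.

The shell is a thin film of thickness L divided into Z layers (Z+1 nodes).
Node 0 is the inner, pin-side face where the moisture flux is zero; node Z is
the outer, air-side face held at the equilibrium moisture M_e from t = 0+
(the surface is assumed to equilibrate instantaneously).  Moisture moves by
Fickian diffusion with a state-dependent effective diffusivity,

    dM/dt = d/dx ( D_eff(M, T) dM/dx ),   0 < x < L,

discretized forward in time.  The explicit scheme is conditionally stable;
time steps are bounded by dl^2 / (6 * max D_eff), the stricter of the two
stability limits (interior and inner-boundary), and recomputed every step
for variable-diffusivity runs.

Two inner-boundary updates are provided: the coefficient-6 rule
M0 += 6*D*dt/dl^2 * (M1 - M0) (``boundary_scheme="paper"``, the default,
matching its dl^2/(6D) stability bound) and the textbook ghost-node rule
with coefficient 2 (``boundary_scheme="ghost"``).  Both enforce the zero-flux
condition in the fine-grid limit and agree closely already at Z = 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .diffusivity import DeffParams, DryingConditions, effective_diffusivity
from .errors import ConfigError, NumericalError, StabilityError

_GEOMETRIES = {"planar": 0.0, "cylindrical": 1.0, "spherical": 2.0}
_BOUNDARY_COEFF = {"paper": 6.0, "ghost": 2.0}


@dataclass(frozen=True)
class ShellGrid:
    """Spatial grid across the shell thickness: Z layers, Z+1 nodes."""

    thickness: float
    n_layers: int

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigError("shell thickness must be positive")
        if int(self.n_layers) != self.n_layers or self.n_layers < 2:
            raise ConfigError("number of layers Z must be an integer >= 2")

    @property
    def spacing(self) -> float:
        """Node spacing dl = L / Z [m]."""
        return self.thickness / self.n_layers

    @property
    def n_nodes(self) -> int:
        return self.n_layers + 1

    @property
    def node_positions(self) -> np.ndarray:
        """Positions [m] of nodes x = 0 (inner face) .. Z (outer face)."""
        return np.linspace(0.0, self.thickness, self.n_nodes)


def build_grid(thickness: float, n_layers: int) -> ShellGrid:
    """Build the shell grid; dl = thickness / n_layers."""
    return ShellGrid(thickness=float(thickness), n_layers=int(n_layers))


@dataclass(frozen=True)
class SolverOptions:
    """Scheme choices for the explicit march.

    geometry : "planar" | "cylindrical" | "spherical"
        Planar (default) matches the thin-film assumption; the curvilinear
        options add the g * D/r radial term (g = 1 or 2) at interior nodes.
    boundary_scheme : "paper" | "ghost"
        Inner zero-flux node update coefficient, 6 or 2.
    safety : float
        Fraction of the stability bound actually used for the step.
    equilibrium_tol : float
        March stops early once (M_avg - M_e)/(M0 - M_e) falls below this.
    max_steps : int
        Step budget per run; exhausting it raises instead of looping on a
        pathologically stiff parameter set.
    """

    geometry: str = "planar"
    boundary_scheme: str = "paper"
    safety: float = 0.9
    equilibrium_tol: float = 1e-3
    max_steps: int = 5_000_000

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ConfigError(f"geometry must be one of {sorted(_GEOMETRIES)}")
        if self.boundary_scheme not in _BOUNDARY_COEFF:
            raise ConfigError("boundary_scheme must be 'paper' or 'ghost'")
        if not 0.0 < self.safety <= 1.0:
            raise ConfigError("safety must be in (0, 1]")
        if self.equilibrium_tol <= 0:
            raise ConfigError("equilibrium_tol must be positive")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be positive")


@dataclass
class MoistureField:
    """Nodal dry-basis moisture [g/g] across the shell at one instant."""

    grid: ShellGrid
    time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes,):
            raise ConfigError(
                f"expected {self.grid.n_nodes} nodal values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ConfigError("nodal moisture must be finite and non-negative")


@dataclass
class MoistureHistory:
    """Snapshots of the nodal moisture at requested output times.

    ``fields`` has shape (n_times, Z+1); times are in seconds, strictly
    increasing.  ``dt_first`` records the first stability-limited step used.
    """

    grid: ShellGrid
    condition: DryingConditions
    times: np.ndarray
    fields: np.ndarray
    options: SolverOptions = field(default_factory=SolverOptions)
    dt_first: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("snapshot times must be strictly increasing")
        if self.fields.shape != (self.times.size, self.grid.n_nodes):
            raise ConfigError("fields shape does not match times/grid")

    def average(self) -> np.ndarray:
        """Trapezoid-weighted spatial mean moisture [g/g] per snapshot."""
        dl = self.grid.spacing
        return np.trapezoid(self.fields, dx=dl, axis=1) / self.grid.thickness

    def field_at(self, i: int) -> MoistureField:
        return MoistureField(self.grid, float(self.times[i]), self.fields[i].copy())


def stable_timestep(grid: ShellGrid, d_max: float, safety: float = 1.0) -> float:
    """Largest stable explicit step: safety * dl^2 / (6 * d_max) [s].

    The inner-boundary bound dl^2/(6D) is stricter than the interior bound
    dl^2/(2D) and governs.
    """
    if d_max <= 0:
        raise ConfigError("d_max must be positive")
    if not 0.0 < safety <= 1.0:
        raise ConfigError("safety must be in (0, 1]")
    return safety * grid.spacing**2 / (6.0 * d_max)


def _advance(
    values: np.ndarray,
    nodal_d: np.ndarray,
    grid: ShellGrid,
    m_e: float,
    dt: float,
    options: SolverOptions,
) -> np.ndarray:
    """One explicit step given nodal diffusivities; outer node pinned at M_e."""
    dl = grid.spacing
    d_max = float(np.max(nodal_d))
    if dt > dl * dl / (6.0 * d_max) * (1.0 + 1e-9):
        raise StabilityError(
            f"dt={dt:g} s exceeds the stability bound {dl * dl / (6.0 * d_max):g} s"
        )
    new = values.copy()
    c = _BOUNDARY_COEFF[options.boundary_scheme]
    new[0] = values[0] + c * nodal_d[0] * dt / dl**2 * (values[1] - values[0])
    lap = (values[2:] - 2.0 * values[1:-1] + values[:-2]) / dl**2
    grad_m = (values[2:] - values[:-2]) / (2.0 * dl)
    grad_d = (nodal_d[2:] - nodal_d[:-2]) / (2.0 * dl)
    update = nodal_d[1:-1] * lap + grad_d * grad_m
    g = _GEOMETRIES[options.geometry]
    if g:
        r = np.arange(1, grid.n_layers) * dl
        update = update + g * nodal_d[1:-1] * grad_m / r
    new[1:-1] = values[1:-1] + dt * update
    new[-1] = m_e
    if not np.all(np.isfinite(new)):
        raise NumericalError("non-finite moisture after explicit step")
    return new


def step_variable(
    field_: MoistureField,
    params: DeffParams,
    cond: DryingConditions,
    dt: float,
    options: SolverOptions = SolverOptions(),
) -> MoistureField:
    """One explicit step with nodal D_eff(M, T) evaluated at the current state."""
    nodal_d = np.asarray(
        effective_diffusivity(params, field_.values, cond.temperature_k)
    )
    new = _advance(
        field_.values, nodal_d, field_.grid, cond.equilibrium_moisture, dt, options
    )
    return MoistureField(field_.grid, field_.time + dt, new)


def step_constant(
    field_: MoistureField,
    d_eff: float,
    cond: DryingConditions,
    dt: float,
    options: SolverOptions = SolverOptions(),
) -> MoistureField:
    """One explicit step with a single diffusivity at every node."""
    if d_eff <= 0:
        raise ConfigError("diffusivity must be positive")
    nodal_d = np.full(field_.grid.n_nodes, float(d_eff))
    new = _advance(
        field_.values, nodal_d, field_.grid, cond.equilibrium_moisture, dt, options
    )
    return MoistureField(field_.grid, field_.time + dt, new)


def simulate(
    m0: float,
    params: Optional[DeffParams],
    cond: DryingConditions,
    grid: ShellGrid,
    t_end: float,
    output_times: Sequence[float],
    options: SolverOptions = SolverOptions(),
    constant_d: Optional[float] = None,
) -> MoistureHistory:
    """March the drying PDE and return snapshots at ``output_times`` [s].

    All nodes start at ``m0`` except the outer node, pinned at the condition's
    equilibrium moisture from the outset.  The step size is recomputed every
    step from the current maximum nodal diffusivity.  Snapshots at requested
    times are linearly interpolated between the two bracketing internal steps.
    The march stops early once the normalized mean moisture ratio drops below
    ``options.equilibrium_tol``; later snapshots repeat the final state.

    Pass ``constant_d`` (and ``params=None``) for the constant-diffusivity
    model; otherwise nodal diffusivities follow ``params``.
    """
    if t_end <= 0:
        raise ConfigError("t_end must be positive")
    out_t = np.asarray(output_times, dtype=float)
    if out_t.size == 0:
        raise ConfigError("at least one output time is required")
    if np.any(np.diff(out_t) <= 0):
        raise ConfigError("output times must be strictly increasing")
    if out_t[0] < 0 or out_t[-1] > t_end * (1 + 1e-12):
        raise ConfigError("output times must lie within [0, t_end]")
    m_e = cond.equilibrium_moisture
    if m0 < m_e:
        raise ConfigError("initial moisture must be >= equilibrium moisture")
    if constant_d is None and params is None:
        raise ConfigError("either params or constant_d must be given")

    if constant_d is not None and constant_d <= 0:
        raise ConfigError("constant_d must be positive")

    snaps = np.empty((out_t.size, grid.n_nodes))
    use_const = constant_d is not None
    if use_const:
        d0, ea_rt, a, b, additive, floor = 1.0, 0.0, 0.0, 0.0, False, 0.0
    else:
        from .diffusivity import R_GAS

        d0 = params.D0
        ea_rt = params.Ea / (R_GAS * cond.temperature_k)
        a, b = params.a, params.b
        additive = params.form == "additive"
        floor = params.floor
    dt_first = _kernels.march(
        out_t,
        snaps,
        grid.n_nodes,
        grid.spacing,
        grid.thickness,
        float(m0),
        float(m_e),
        float(t_end),
        float(options.safety),
        float(options.equilibrium_tol),
        float(d0),
        float(ea_rt),
        float(a),
        float(b),
        additive,
        float(floor),
        float(constant_d if use_const else 0.0),
        use_const,
        _BOUNDARY_COEFF[options.boundary_scheme],
        _GEOMETRIES[options.geometry],
        options.max_steps,
    )
    if dt_first == -2.0:
        raise NumericalError(
            "step budget exhausted: parameters imply extreme stiffness "
            "(fast boundary node, near-frozen interior)"
        )
    if dt_first < 0.0:
        dt_first = None
    if not np.all(np.isfinite(snaps)):
        raise NumericalError("non-finite moisture during the march")

    return MoistureHistory(
        grid=grid,
        condition=cond,
        times=out_t,
        fields=snaps,
        options=options,
        dt_first=dt_first,
    )


def analytic_slab_ratio(d_eff: float, thickness: float, t: float, n_terms: int = 50):
    """Series solution for the mean moisture ratio of a slab, constant D.

    Classical solution for a slab insulated at x = 0 and held at equilibrium
    at x = L (equivalent to a slab of half-thickness L):

        MR(t) = sum_{n=0}^{n_terms-1} 8/((2n+1)^2 pi^2)
                * exp(-(2n+1)^2 pi^2 D t / (4 L^2))

    Serves as the independent oracle for the finite-difference march.
    ``t`` may be a scalar or an array [s].
    """
    if d_eff <= 0 or thickness <= 0:
        raise ConfigError("d_eff and thickness must be positive")
    if n_terms < 1:
        raise ConfigError("n_terms must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ConfigError("t must be non-negative")
    n = np.arange(n_terms)
    k = (2 * n + 1).astype(float)
    coef = 8.0 / (k**2 * np.pi**2)
    rate = k**2 * np.pi**2 * d_eff / (4.0 * thickness**2)
    out = np.sum(coef * np.exp(-np.outer(t_arr, rate)), axis=1)
    return out if np.ndim(t) else float(out[0])


def average_moisture(field_: MoistureField) -> float:
    """Trapezoid-weighted spatial mean of the nodal moisture [g/g]."""
    return float(
        np.trapezoid(field_.values, dx=field_.grid.spacing) / field_.grid.thickness
    )


def deff_avg(field_: MoistureField, params: DeffParams, temperature_k: float) -> float:
    """Moisture-weighted mean diffusivity over the shell [m^2 s^-1].

    Discrete reading of the moisture-integral average
    int D_eff dM / int dM: sum_x D_eff(M_x, T) * M_x / sum_x M_x.  Undefined
    (raises) when every node is dry.
    """
    m = field_.values
    total = float(np.sum(m))
    if total <= 0:
        raise NumericalError("moisture-weighted average undefined for an all-dry field")
    d = np.asarray(effective_diffusivity(params, m, temperature_k))
    return float(np.sum(d * m) / total)
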