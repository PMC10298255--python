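"""Effective moisture diffusivity of the capsule gel film.

The transport coefficient lumps liquid, vapor and surface diffusion into a
single effective diffusivity D_eff that depends on the local dry-basis
moisture content M [g water / g dry matter] and on the drying-air
temperature T.  The default law keeps every term in the exponent,

    D_eff(M, T) = D0 * exp(-Ea / (R*T) + a*M - b*M**2),

which is strictly positive for any finite M and T and reduces to the plain
Arrhenius form when the moisture coefficients a and b vanish.  An additive
variant D0*exp(-Ea/(R*T)) + a*M - b*M**2 is available behind
``form="additive"``; because it can cross zero it is clamped at a small
positive floor.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

#: Universal gas constant [J mol^-1 K^-1]; fixed, never user-settable.
R_GAS = 8.3145

_FORMS = ("exponent", "additive")


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert a temperature from degrees Celsius to Kelvin."""
    return float(temperature_c) + 273.15


@dataclass(frozen=True)
class DeffParams:
    """Parameters of the effective-diffusivity law.

    Attributes
    ----------
    D0 : float
        Arrhenius pre-exponential factor [m^2 s^-1]; the reference
        diffusivity at infinitely high temperature.  Must be positive.
    Ea : float
        Activation energy [J mol^-1].
    a : float
        Linear moisture coefficient [(g/g)^-1].
    b : float
        Quadratic moisture coefficient [(g/g)^-2].
    form : str
        ``"exponent"`` (default) keeps the moisture terms inside the
        exponential; ``"additive"`` adds them outside, clamped at ``floor``.
    floor : float
        Positivity floor [m^2 s^-1] applied only to the additive form.
    """

    D0: float
    Ea: float
    a: float
    b: float
    form: str = "exponent"
    floor: float = 1e-14

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D0) and self.D0 > 0):
            raise ConfigError(f"D0 must be positive and finite, got {self.D0!r}")
        for name in ("Ea", "a", "b"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.form not in _FORMS:
            raise ConfigError(f"form must be one of {_FORMS}, got {self.form!r}")
        if self.floor <= 0:
            raise ConfigError("floor must be positive")

    def restricted_constant(self) -> "DeffParams":
        """The a = b = 0 restriction (moisture dependence removed)."""
        return dataclasses.replace(self, a=0.0, b=0.0)


@dataclass(frozen=True)
class DryingConditions:
    """One drying condition: air temperature, humidity, equilibrium moisture.

    ``equilibrium_moisture`` is the dry-basis moisture content M_e [g/g] the
    film would reach in equilibrium with air at this temperature and relative
    humidity; it is a per-condition input, not derived from a sorption
    isotherm.  ``air_velocity`` [m s^-1] is carried as metadata only.
    """

    temperature_c: float
    relative_humidity: float
    equilibrium_moisture: float
    air_velocity: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature_c <= 100.0:
            raise ConfigError(
                f"temperature {self.temperature_c} degC outside the validated 0-100 range"
            )
        if not 0.0 < self.relative_humidity <= 100.0:
            raise ConfigError("relative humidity must be in (0, 100]")
        if self.equilibrium_moisture < 0:
            raise ConfigError("equilibrium moisture must be non-negative")

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    @property
    def label(self) -> str:
        rh = self.relative_humidity
        rh_s = f"{rh:g}"
        return f"{self.temperature_c:g}C_RH{rh_s}"


def _validate_state(M, T) -> None:
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)) or np.any(M < 0):
        raise ConfigError("moisture content must be finite and non-negative")
    if not np.all(np.isfinite(T)) or np.any(np.asarray(T) <= 0):
        raise ConfigError("temperature must be positive and finite (Kelvin)")


def effective_diffusivity(params: DeffParams, M, T):
    """Evaluate D_eff(M, T) [m^2 s^-1].

    Parameters
    ----------
    params : DeffParams
    M : float or ndarray
        Dry-basis moisture content [g/g], >= 0.
    T : float
        Absolute temperature [K], > 0.
    """
    _validate_state(M, T)
    M = np.asarray(M, dtype=float)
    arrhenius = -params.Ea / (R_GAS * T)
    if params.form == "exponent":
        out = params.D0 * np.exp(arrhenius + params.a * M - params.b * M * M)
    else:
        out = np.maximum(
            params.D0 * np.exp(arrhenius) + params.a * M - params.b * M * M,
            params.floor,
        )
    return out if out.ndim else float(out)


def constant_diffusivity(params: DeffParams, T) -> float:
    """The moisture-independent counterpart D0 * exp(-Ea/(R*T)).

    Identical to :func:`effective_diffusivity` with a = b = 0, in either form.
    """
    _validate_state(0.0, T)
    return float(params.D0 * np.exp(-params.Ea / (R_GAS * T)))
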