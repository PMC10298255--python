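"""Moisture quantification from proton-density-weighted image series.

In a spin-echo acquisition with long repetition time and short echo time the
signal is proportional to the hydrogen (water) density:

    I = k * rho_H * (1 - exp(-TR/T1)) * exp(-TE/T2).

Because the signal is linear in moisture, a moisture percentage can be read
off a time series of images by normalizing each frame's mean zone signal
between the initial frame (100 %) and the final, equilibrium frame (0 %):

    pct(t) = 100 * (S(t) - S(final)) / (S(0) - S(final)),

with S the mean signal over the analysis zone.  The same normalization
applied per shell layer gives a radial moisture profile.  Both are invariant
under any global affine rescaling of the signal (scanner gain/offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import ConfigError, NumericalError


@dataclass(frozen=True)
class MRISequenceParams:
    """Spin-echo sequence parameters (times in ms, k and rho_H in a.u.)."""

    k: float = 1.0
    TR: float = 2000.0
    TE: float = 18.125
    T1: float = 500.0
    T2: float = 50.0
    rho_H: float = 1.0

    def __post_init__(self) -> None:
        for name in ("TR", "TE", "T1", "T2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.TE >= self.TR:
            raise ConfigError("echo time TE must be shorter than repetition time TR")


def signal_intensity(p: MRISequenceParams) -> float:
    """Spin-echo signal for the given sequence parameters [a.u.]."""
    return float(
        p.k * p.rho_H * (1.0 - np.exp(-p.TR / p.T1)) * np.exp(-p.TE / p.T2)
    )


def signal_from_density(p: MRISequenceParams, rho_h) -> np.ndarray:
    """Spin-echo signal for an array of hydrogen densities."""
    rho = np.asarray(rho_h, dtype=float)
    return p.k * rho * (1.0 - np.exp(-p.TR / p.T1)) * np.exp(-p.TE / p.T2)


@dataclass
class MRISeries:
    """Time-indexed 2-D signal grids with shell-zone and layer masks.

    ``frames`` has shape (n_times, H, W); ``zone_mask`` is the boolean shell
    analysis zone; ``layer_labels`` assigns each pixel a radial node index
    0..Z (−1 for background).  Frame 0 is t = 0 and the last frame is the
    designated equilibrium frame unless stated otherwise.
    """

    frames: np.ndarray
    zone_mask: np.ndarray
    pixel_size: float
    times_min: np.ndarray
    layer_labels: Optional[np.ndarray] = None
    sequence_params: MRISequenceParams = field(default_factory=MRISequenceParams)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.zone_mask = np.asarray(self.zone_mask, dtype=bool)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (n_times, H, W) array")
        if self.zone_mask.shape != self.frames.shape[1:]:
            raise ConfigError("zone mask shape must match the frames")
        if not self.zone_mask.any():
            raise ConfigError("zone mask is empty")
        if self.times_min.size != self.frames.shape[0]:
            raise ConfigError("one acquisition time per frame is required")
        if self.times_min[0] != 0.0 or np.any(np.diff(self.times_min) <= 0):
            raise ConfigError("times must start at 0 and increase strictly")
        if self.pixel_size <= 0:
            raise ConfigError("pixel size must be positive")
        if self.layer_labels is not None:
            self.layer_labels = np.asarray(self.layer_labels, dtype=int)
            if self.layer_labels.shape != self.frames.shape[1:]:
                raise ConfigError("layer labels shape must match the frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _zone_mean(series: MRISeries, t_index: int, mask: np.ndarray) -> float:
    return float(series.frames[t_index][mask].mean())


def moisture_percentage(
    series: MRISeries, t_index: int, final_index: int = -1
) -> float:
    """Moisture percentage of one frame, normalized over the analysis zone.

    100 % at the initial frame and 0 % at the equilibrium frame by
    construction.  Raises when the initial and equilibrium zone means
    coincide (nothing dried — the normalization is undefined).
    """
    mask = series.zone_mask
    s_t = _zone_mean(series, t_index, mask)
    s_0 = _zone_mean(series, 0, mask)
    s_f = _zone_mean(series, final_index, mask)
    if s_0 == s_f:
        raise NumericalError(
            "initial and equilibrium zone signals coincide; percentage undefined"
        )
    return 100.0 * (s_t - s_f) / (s_0 - s_f)


def layer_profile(
    series: MRISeries, t_index: int, final_index: int = -1
) -> np.ndarray:
    """Per-layer moisture percentage, indexed by shell node 0..Z.

    Applies the zone normalization separately to each radial layer.  Layers
    whose initial and equilibrium means coincide (e.g. the outer face, at
    equilibrium throughout) yield NaN.  An empty layer raises.
    """
    if series.layer_labels is None:
        raise ConfigError("series has no layer labels")
    n_layers = int(series.layer_labels.max()) + 1
    if n_layers < 1:
        raise ConfigError("layer labels contain no shell pixels")
    out = np.empty(n_layers)
    for lay in range(n_layers):
        mask = series.layer_labels == lay
        if not mask.any():
            raise ConfigError(f"layer {lay} has no pixels")
        s_t = _zone_mean(series, t_index, mask)
        s_0 = _zone_mean(series, 0, mask)
        s_f = _zone_mean(series, final_index, mask)
        out[lay] = np.nan if s_0 == s_f else 100.0 * (s_t - s_f) / (s_0 - s_f)
    return out


def percentage_table(series: MRISeries) -> Dict[str, np.ndarray]:
    """Zone percentage for every frame; convenience for reporting."""
    pct = np.array(
        [moisture_percentage(series, i) for i in range(series.n_frames)]
    )
    return {"times_min": series.times_min.copy(), "percentage": pct}
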