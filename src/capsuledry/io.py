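"""Reading and writing the package's on-disk formats.

Drying curves and solver histories are tab-separated tables with a single
``#``-prefixed JSON header line carrying the condition, grid and scheme
metadata.  MRI series are directories of per-frame matrices (plain text by
default, 16-bit grayscale TIFF optionally) plus a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .diffusivity import DryingConditions
from .errors import ConfigError
from .estimation import DryingCurve, FitResult
from .mri import MRISequenceParams, MRISeries
from .solver import MoistureHistory, SolverOptions, build_grid

PathLike = Union[str, Path]


def _node_columns(n_nodes: int):
    return [f"M_x{i}" for i in range(n_nodes)]


def _condition_meta(cond: DryingConditions) -> dict:
    return {
        "temperature_c": cond.temperature_c,
        "relative_humidity": cond.relative_humidity,
        "equilibrium_moisture": cond.equilibrium_moisture,
        "air_velocity": cond.air_velocity,
    }


def _write_table(path: Path, header: dict, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path: Path):
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ConfigError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        frame = pd.read_csv(fh, sep="\t")
    return header, frame


def write_curve(path: PathLike, curve: DryingCurve) -> None:
    """Write a drying curve (and optional per-layer columns) as TSV."""
    data = {"time_min": curve.times_min, "M_avg": curve.m_avg}
    if curve.per_layer is not None:
        for i, col in enumerate(_node_columns(curve.per_layer.shape[1])):
            data[col] = curve.per_layer[:, i]
    header = {
        "kind": "drying_curve",
        "condition": _condition_meta(curve.condition),
        "provenance": curve.provenance,
        "m0_nominal": curve.m0_nominal,
        "warnings": curve.warnings,
    }
    _write_table(Path(path), header, pd.DataFrame(data))


def read_curve(path: PathLike) -> DryingCurve:
    header, frame = _read_table(Path(path))
    if header.get("kind") != "drying_curve":
        raise ConfigError(f"{path}: not a drying-curve file")
    cond = DryingConditions(**header["condition"])
    node_cols = [c for c in frame.columns if c.startswith("M_x")]
    per_layer = frame[node_cols].to_numpy() if node_cols else None
    return DryingCurve(
        condition=cond,
        times_min=frame["time_min"].to_numpy(),
        m_avg=frame["M_avg"].to_numpy(),
        per_layer=per_layer,
        m0_nominal=header.get("m0_nominal"),
        provenance=header.get("provenance", "weighing"),
        warnings=list(header.get("warnings", [])),
    )


def write_history(path: PathLike, history: MoistureHistory) -> None:
    """Write solver snapshots: time_min, M_avg, then one column per node."""
    data = {"time_min": history.times / 60.0, "M_avg": history.average()}
    for i, col in enumerate(_node_columns(history.grid.n_nodes)):
        data[col] = history.fields[:, i]
    header = {
        "kind": "moisture_history",
        "condition": _condition_meta(history.condition),
        "grid": {"thickness": history.grid.thickness, "n_layers": history.grid.n_layers},
        "scheme": dataclasses.asdict(history.options),
        "dt_first_s": history.dt_first,
    }
    _write_table(Path(path), header, pd.DataFrame(data))


def read_history(path: PathLike) -> MoistureHistory:
    header, frame = _read_table(Path(path))
    if header.get("kind") != "moisture_history":
        raise ConfigError(f"{path}: not a moisture-history file")
    grid = build_grid(header["grid"]["thickness"], header["grid"]["n_layers"])
    node_cols = _node_columns(grid.n_nodes)
    return MoistureHistory(
        grid=grid,
        condition=DryingConditions(**header["condition"]),
        times=frame["time_min"].to_numpy() * 60.0,
        fields=frame[node_cols].to_numpy(),
        options=SolverOptions(**header["scheme"]),
        dt_first=header.get("dt_first_s"),
    )


def write_fit_result(path: PathLike, result: FitResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_mri_series(
    directory: PathLike, series: MRISeries, fmt: str = "txt"
) -> Path:
    """Write frames plus masks and a JSON sidecar into ``directory``.

    ``fmt="txt"`` stores each frame as a whitespace-delimited matrix;
    ``fmt="tiff"`` stores 16-bit grayscale TIFFs (signal scaled to the
    series maximum).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame_files = []
    if fmt == "txt":
        for i in range(series.n_frames):
            name = f"frame_{i:03d}.txt"
            np.savetxt(directory / name, series.frames[i], fmt="%.8g")
            frame_files.append(name)
    elif fmt == "tiff":
        import tifffile

        peak = float(series.frames.max()) or 1.0
        for i in range(series.n_frames):
            name = f"frame_{i:03d}.tif"
            scaled = np.clip(series.frames[i] / peak, 0.0, 1.0)
            tifffile.imwrite(directory / name, (scaled * 65535).astype(np.uint16))
            frame_files.append(name)
    else:
        raise ConfigError("fmt must be 'txt' or 'tiff'")
    np.savetxt(directory / "zone_mask.txt", series.zone_mask.astype(int), fmt="%d")
    sidecar = {
        "pixel_size_m": series.pixel_size,
        "times_min": [float(t) for t in series.times_min],
        "zone_mask_file": "zone_mask.txt",
        "frame_files": frame_files,
        "format": fmt,
        "sequence_params": dataclasses.asdict(series.sequence_params),
    }
    if series.layer_labels is not None:
        np.savetxt(directory / "layer_labels.txt", series.layer_labels, fmt="%d")
        sidecar["layer_labels_file"] = "layer_labels.txt"
    with open(directory / "series.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory / "series.json"


def read_mri_series(directory: PathLike) -> MRISeries:
    directory = Path(directory)
    with open(directory / "series.json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format", "txt") == "txt":
        frames = np.stack(
            [np.loadtxt(directory / name) for name in sidecar["frame_files"]]
        )
    else:
        import tifffile

        frames = np.stack(
            [
                tifffile.imread(directory / name).astype(float)
                for name in sidecar["frame_files"]
            ]
        )
    zone = np.loadtxt(directory / sidecar["zone_mask_file"]).astype(bool)
    labels = None
    if "layer_labels_file" in sidecar:
        labels = np.loadtxt(directory / sidecar["layer_labels_file"]).astype(int)
    return MRISeries(
        frames=frames,
        zone_mask=zone,
        pixel_size=sidecar["pixel_size_m"],
        times_min=np.asarray(sidecar["times_min"]),
        layer_labels=labels,
        sequence_params=MRISequenceParams(**sidecar["sequence_params"]),
    )
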