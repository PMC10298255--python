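"""End-to-end pipeline: generate or load data, fit, quantify, report.

``run_full`` reproduces the study's analysis artifacts on synthetic data:
drying curves per condition, variable- and constant-diffusivity fits, the
model-comparison table, the moisture-weighted average-diffusivity vs
moisture table, per-layer moisture and diffusivity tables, and MRI-phantom
quantification.  Every output is a delimited-text or JSON file listed in a
manifest with content hashes; outputs are deterministic for a given config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as cdio
from .diffusivity import DeffParams
from .errors import ConfigError
from .estimation import (
    DryingCurve,
    FitConfig,
    FitResult,
    compare_models,
    fit_constant,
    fit_variable,
)
from .mri import layer_profile, percentage_table
from .solver import MoistureField, MoistureHistory, deff_avg
from .synthetic import GeneratorConfig, generate_drying_experiment, generate_mri_series, simulate_condition

logger = logging.getLogger("capsuledry")

_MODES = ("generate", "fit", "quantify", "full")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through JSON."""

    mode: str = "full"
    outdir: str = "capsuledry_run"
    curves_path: Optional[str] = None
    mri_path: Optional[str] = None
    seed: int = 20230605
    noise_cv: float = 0.05
    duration_min: float = 140.0
    sampling_interval_min: float = 20.0
    geometry: str = "planar"
    boundary_scheme: str = "paper"
    safety: float = 0.9
    deff_form: str = "exponent"
    fit_maxiter: int = 300
    per_condition: bool = False
    log_level: str = "INFO"
    deff_params: Optional[Dict[str, Any]] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def generator_config(self) -> GeneratorConfig:
        from .solver import SolverOptions

        kwargs: Dict[str, Any] = {}
        if self.deff_params:
            dp = dict(self.deff_params)
            dp.setdefault("form", self.deff_form)
            kwargs["true_params"] = DeffParams(**dp)
        return GeneratorConfig(
            noise_cv=self.noise_cv,
            seed=self.seed,
            duration_min=self.duration_min,
            sampling_interval_min=self.sampling_interval_min,
            solver=SolverOptions(
                geometry=self.geometry,
                boundary_scheme=self.boundary_scheme,
                safety=self.safety,
            ),
            **kwargs,
        )

    def fit_config(self) -> FitConfig:
        return FitConfig(
            maxiter=self.fit_maxiter,
            seed=self.seed,
            geometry=self.geometry,
            boundary_scheme=self.boundary_scheme,
            safety=self.safety,
            deff_form=self.deff_form,
            per_condition=self.per_condition,
        )


def report_deff_vs_moisture(fit: FitResult, history: MoistureHistory) -> pd.DataFrame:
    """Rows of (time, average moisture, moisture-weighted mean diffusivity).

    Evaluates the fitted diffusivity law on each snapshot of a simulated
    history, averaging the nodal values weighted by the nodal moisture.
    """
    params = fit.params
    if isinstance(params, dict):
        params = params[history.condition.label]
    if not isinstance(params, DeffParams):
        raise ConfigError("a variable-model fit is required")
    rows = []
    t_k = history.condition.temperature_k
    for i, t in enumerate(history.times):
        f = MoistureField(history.grid, float(t), history.fields[i].copy())
        rows.append(
            {
                "time_min": float(t) / 60.0,
                "M_avg": float(history.average()[i]),
                "D_eff_avg": deff_avg(f, params, t_k),
            }
        )
    return pd.DataFrame(rows)


def layer_diffusivity_table(params: DeffParams, history: MoistureHistory) -> pd.DataFrame:
    """Nodal diffusivity per snapshot: columns time_min, D_x0..D_xZ."""
    from .diffusivity import effective_diffusivity

    t_k = history.condition.temperature_k
    data: Dict[str, Any] = {"time_min": history.times / 60.0}
    d = np.asarray(effective_diffusivity(params, history.fields, t_k))
    for i in range(history.grid.n_nodes):
        data[f"D_x{i}"] = d[:, i]
    return pd.DataFrame(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _setup_logging(outdir: Path, level: str):
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    return handler


def generate_outputs(config: RunConfig, outdir: Path) -> List[DryingCurve]:
    gen = config.generator_config()
    curves = generate_drying_experiment(gen)
    for curve in curves:
        cdio.write_curve(outdir / f"curve_{curve.label}.tsv", curve)
    logger.info("generated %d synthetic drying curves", len(curves))
    return curves


def load_curves(config: RunConfig) -> List[DryingCurve]:
    if not config.curves_path:
        raise ConfigError("curves_path is required in fit mode")
    paths = sorted(Path(config.curves_path).glob("curve_*.tsv"))
    if not paths:
        raise ConfigError(f"no curve files found under {config.curves_path}")
    return [cdio.read_curve(p) for p in paths]


def fit_outputs(config: RunConfig, curves: List[DryingCurve], outdir: Path):
    gen = config.generator_config()
    fit_cfg = config.fit_config()
    fit_v = fit_variable(curves, gen.grid, fit_cfg)
    fit_c = fit_constant(curves, gen.grid, fit_cfg)
    cdio.write_fit_result(outdir / "fit_variable.json", fit_v)
    cdio.write_fit_result(outdir / "fit_constant.json", fit_c)
    comparison = compare_models(fit_v, fit_c)
    _write_df(outdir / "model_comparison.tsv", comparison.summary)
    _write_df(outdir / "model_comparison_per_time.tsv", comparison.per_time)

    # analysis tables from the fitted variable model, one per condition
    params = fit_v.params
    for curve in curves:
        p = params[curve.label] if isinstance(params, dict) else params
        hist = simulate_condition(
            dataclasses.replace(gen, true_params=p, noise_cv=0.0), curve.condition
        )
        cdio.write_history(outdir / f"history_{curve.label}.tsv", hist)
        _write_df(
            outdir / f"deff_vs_moisture_{curve.label}.tsv",
            report_deff_vs_moisture(fit_v, hist),
        )
        _write_df(
            outdir / f"deff_layers_{curve.label}.tsv",
            layer_diffusivity_table(p, hist),
        )
    logger.info(
        "fits done: variable sse=%.4g constant sse=%.4g",
        fit_v.diagnostics["sse"],
        fit_c.diagnostics["sse"],
    )
    return fit_v, fit_c


def quantify_outputs(config: RunConfig, outdir: Path) -> pd.DataFrame:
    gen = config.generator_config()
    if config.mri_path:
        series = cdio.read_mri_series(config.mri_path)
    else:
        hist = simulate_condition(gen, gen.conditions[0])
        series = generate_mri_series(gen, hist)
        cdio.write_mri_series(outdir / f"phantom_{gen.conditions[0].label}", series)
    table = percentage_table(series)
    rows = {"time_min": table["times_min"], "moisture_pct": table["percentage"]}
    if series.layer_labels is not None:
        profiles = np.stack(
            [layer_profile(series, i) for i in range(series.n_frames)]
        )
        for lay in range(profiles.shape[1]):
            rows[f"layer{lay}_pct"] = profiles[:, lay]
    frame = pd.DataFrame(rows)
    _write_df(outdir / "mri_quantification.tsv", frame)
    logger.info("quantified %d frames", series.n_frames)
    return frame


def _try_plots(outdir: Path, curves: List[DryingCurve], fit_v: FitResult) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort; tables are the contract
        logger.info("matplotlib unavailable; skipping plots")
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.times_min, curve.m_avg, "o", ms=3, label=f"{curve.label} obs")
        ax.plot(curve.times_min, fit_v.predicted[curve.label], "-", lw=1)
    ax.set_xlabel("time [min]")
    ax.set_ylabel("moisture [g/g dry basis]")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "drying_curves.png", dpi=120)
    plt.close(fig)


def run_full(config: RunConfig) -> Dict[str, Any]:
    """Execute the configured pipeline stage(s); returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir, config.log_level)
    report: Dict[str, Any] = {"mode": config.mode}
    try:
        config.to_json(outdir / "config.json")
        curves: List[DryingCurve] = []
        if config.mode in ("generate", "full"):
            curves = generate_outputs(config, outdir)
        elif config.mode == "fit":
            curves = load_curves(config)
        if config.mode in ("fit", "full"):
            fit_v, fit_c = fit_outputs(config, curves, outdir)
            report["variable_sse"] = fit_v.diagnostics["sse"]
            report["constant_sse"] = fit_c.diagnostics["sse"]
            report["per_condition"] = fit_v.per_condition
            _try_plots(outdir, curves, fit_v)
        if config.mode in ("quantify", "full"):
            frame = quantify_outputs(config, outdir)
            report["mri_frames"] = int(frame.shape[0])
        manifest = {
            "files": {
                p.name: _sha256(p)
                for p in sorted(outdir.iterdir())
                if p.is_file() and p.suffix in (".tsv", ".json") and p.name != "manifest.json"
            },
            "seed": config.seed,
        }
        # phantom frame files live in a subdirectory
        for sub in sorted(outdir.glob("phantom_*/")):
            for p in sorted(sub.iterdir()):
                manifest["files"][f"{sub.name}/{p.name}"] = _sha256(p)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["manifest"] = str(outdir / "manifest.json")
        report["n_outputs"] = len(manifest["files"])
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
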