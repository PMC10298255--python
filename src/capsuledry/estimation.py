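"""Fitting diffusivity laws to drying curves and scoring the fits.

Two estimators, both scikit-learn compatible (``get_params``/``set_params``,
fitted attributes with a trailing underscore):

* :class:`VariableDiffusivityModel` fits the four-parameter moisture- and
  temperature-dependent law D_eff(M, T) to one or more observed drying
  curves by bounded derivative-free least squares: differential evolution
  seeded from a Latin-hypercube population, with a Powell refinement.
* :class:`ConstantDiffusivityModel` fits one scalar diffusivity per drying
  condition by a bounded scalar search, the conventional benchmark the
  variable model is compared against.

``X`` is a list of :class:`DryingCurve` objects (time series of dry-basis
average moisture per condition); there is no separate ``y``.  The module
functions :func:`fit_variable`, :func:`fit_constant` and
:func:`compare_models` are thin wrappers over the estimators.

A note on the t = 0 point: the marching scheme pins the outer node at the
equilibrium moisture from t = 0+, so the spatial average of the initial
snapshot sits slightly below M0.  A weighed film at t = 0, however, is still
uniform at M0.  Predictions therefore report M0 itself at t = 0 and the
marched average at every later time, matching how the synthetic generator
defines its observations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .diffusivity import R_GAS, DeffParams, DryingConditions
from .errors import ConfigError, NumericalError
from .solver import MoistureHistory, ShellGrid, SolverOptions, build_grid, simulate

DEFAULT_BOUNDS: Dict[str, tuple] = {
    "D0": (1e-12, 1e-2),
    "Ea": (0.0, 1e5),
    "a": (0.0, 5.0),
    "b": (0.0, 2.0),
}


@dataclass
class DryingCurve:
    """Observed (or synthetic) drying curve for one condition.

    times are minutes from the start of drying, strictly increasing from 0;
    ``m_avg`` is the dry-basis average moisture [g/g].  ``per_layer`` holds
    optional nodal observations with shape (n_times, Z+1).  ``m0_nominal``
    is the film's known initial moisture from preparation; when present it
    supplies the simulation's initial condition instead of the (noisy) first
    observation.  The ``*_true`` arrays carry the noiseless counterparts
    when the curve is synthetic.
    """

    condition: DryingConditions
    times_min: np.ndarray
    m_avg: np.ndarray
    per_layer: Optional[np.ndarray] = None
    m0_nominal: Optional[float] = None
    provenance: str = "synthetic"
    m_avg_true: Optional[np.ndarray] = None
    per_layer_true: Optional[np.ndarray] = None
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.m_avg = np.asarray(self.m_avg, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.size != self.m_avg.size:
            raise ConfigError("times and observations must be 1-D and equal length")
        if self.times_min[0] != 0.0 or np.any(np.diff(self.times_min) <= 0):
            raise ConfigError("times must start at 0 and increase strictly")
        if self.provenance not in ("weighing", "mri", "synthetic"):
            raise ConfigError("provenance must be weighing, mri or synthetic")
        if self.m_avg[0] <= self.condition.equilibrium_moisture:
            raise ConfigError("initial observed moisture must exceed equilibrium")
        if self.m0_nominal is not None and self.m0_nominal <= self.condition.equilibrium_moisture:
            raise ConfigError("nominal initial moisture must exceed equilibrium")
        if self.per_layer is not None:
            self.per_layer = np.asarray(self.per_layer, dtype=float)
            if self.per_layer.shape[0] != self.times_min.size:
                raise ConfigError("per-layer observations must match the time axis")

    @property
    def label(self) -> str:
        return self.condition.label


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean square error sqrt(sum((pred - obs)^2) / n)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ConfigError("predicted and observed must have equal nonzero length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(
    predicted: Sequence[float],
    observed: Sequence[float],
    denominator: str = "predicted_mean",
) -> float:
    """Determination coefficient 1 - SS_res / SS_tot.

    The default total sum of squares is taken about the mean of the
    *predicted* values, the form used in this drying literature; pass
    ``denominator="observed_mean"`` for the conventional definition.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ConfigError("need >= 2 aligned points")
    if denominator == "predicted_mean":
        center = p.mean()
    elif denominator == "observed_mean":
        center = o.mean()
    else:
        raise ConfigError("denominator must be 'predicted_mean' or 'observed_mean'")
    ss_tot = float(np.sum((center - o) ** 2))
    if ss_tot == 0.0:
        raise NumericalError("determination coefficient undefined: zero total sum of squares")
    return 1.0 - float(np.sum((p - o) ** 2)) / ss_tot


@dataclass
class FitResult:
    """Outcome of a curve fit: parameters, per-condition scores, predictions."""

    model: str
    params: Any
    per_condition: List[Dict[str, float]]
    times_min: Dict[str, np.ndarray]
    observed: Dict[str, np.ndarray]
    predicted: Dict[str, np.ndarray]
    diagnostics: Dict[str, Any]
    estimator: Any = None

    def to_dict(self) -> Dict[str, Any]:
        if isinstance(self.params, DeffParams):
            params = dataclasses.asdict(self.params)
        elif isinstance(self.params, dict):
            params = {
                k: (dataclasses.asdict(v) if isinstance(v, DeffParams) else v)
                for k, v in self.params.items()
            }
        else:
            params = self.params
        return {
            "model": self.model,
            "params": params,
            "per_condition": self.per_condition,
            "predicted": {k: list(map(float, v)) for k, v in self.predicted.items()},
            "observed": {k: list(map(float, v)) for k, v in self.observed.items()},
            "times_min": {k: list(map(float, v)) for k, v in self.times_min.items()},
            "diagnostics": self.diagnostics,
        }


def predicted_average(history: MoistureHistory, m0: float) -> np.ndarray:
    """Average-moisture prediction with the uniform film value M0 at t = 0."""
    avg = history.average()
    if history.times[0] == 0.0:
        avg = avg.copy()
        avg[0] = m0
    return avg


def _check_curves(X: Sequence[DryingCurve], min_points: int = 4) -> List[DryingCurve]:
    curves = list(X)
    if not curves:
        raise ConfigError("at least one drying curve is required")
    for c in curves:
        if not isinstance(c, DryingCurve):
            raise ConfigError("X must be a sequence of DryingCurve objects")
        if c.times_min.size < min_points:
            raise ConfigError(
                f"curve {c.label} has {c.times_min.size} points; >= {min_points} required"
            )
    return curves


def _residuals(pred: np.ndarray, obs: np.ndarray, scale: str) -> np.ndarray:
    """Fit residuals: relative (default) matches the multiplicative error
    model of the measurements; absolute is the unweighted alternative."""
    r = pred - obs
    if scale == "relative":
        return r / np.maximum(np.abs(obs), 1e-12)
    if scale == "absolute":
        return r
    raise ConfigError("residual_scale must be 'relative' or 'absolute'")


class _DryingEstimatorMixin:
    """Shared plumbing: grid/options construction and prediction."""

    def _grid(self) -> ShellGrid:
        return build_grid(self.thickness, self.n_layers)

    def _options(self) -> SolverOptions:
        # generous step budget (~250x a realistic run on the default grid);
        # pathological trial parameters are penalized instead of marched out
        return SolverOptions(
            geometry=self.geometry,
            boundary_scheme=self.boundary_scheme,
            safety=self.safety,
            max_steps=100_000,
        )

    @staticmethod
    def _m0(curve: DryingCurve) -> float:
        if curve.m0_nominal is not None:
            return float(curve.m0_nominal)
        return float(curve.m_avg[0])

    def _simulate_curve(self, curve: DryingCurve, params=None, constant_d=None):
        times_s = curve.times_min * 60.0
        return simulate(
            m0=self._m0(curve),
            params=params,
            cond=curve.condition,
            grid=self._grid(),
            t_end=float(times_s[-1]),
            output_times=times_s,
            options=self._options(),
            constant_d=constant_d,
        )

    def _params_for(self, curve: DryingCurve):
        raise NotImplementedError

    def _history(self, curve: DryingCurve) -> MoistureHistory:
        params, constant_d = self._params_for(curve)
        return self._simulate_curve(curve, params=params, constant_d=constant_d)

    def predict_curves(self, X: Sequence[DryingCurve]) -> List[np.ndarray]:
        """Predicted average-moisture series, one array per input curve."""
        self._check_fitted()
        return [
            predicted_average(self._history(c), self._m0(c))
            for c in _check_curves(X, min_points=1)
        ]

    def predict_layers(self, X: Sequence[DryingCurve]) -> List[np.ndarray]:
        """Predicted nodal moisture, one (n_times, Z+1) array per curve."""
        self._check_fitted()
        return [self._history(c).fields.copy() for c in _check_curves(X, min_points=1)]

    def predict(self, X: Sequence[DryingCurve]) -> np.ndarray:
        """Concatenated average-moisture predictions over all curves."""
        return np.concatenate(self.predict_curves(X))

    def score(self, X: Sequence[DryingCurve], y=None) -> float:
        """Pooled determination coefficient over all curves' average moisture."""
        obs = np.concatenate([c.m_avg for c in X])
        return r_squared(self.predict(X), obs, denominator=self.r2_denominator)

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise NumericalError("estimator is not fitted")

    def _build_result(self, model: str, params, X, diagnostics) -> FitResult:
        per_condition = []
        times, observed, predicted = {}, {}, {}
        for c in X:
            pred = predicted_average(self._history(c), self._m0(c))
            times[c.label] = c.times_min.copy()
            observed[c.label] = c.m_avg.copy()
            predicted[c.label] = pred
            per_condition.append(
                {
                    "condition": c.label,
                    "T_c": c.condition.temperature_c,
                    "RH": c.condition.relative_humidity,
                    "R2": r_squared(pred, c.m_avg, denominator=self.r2_denominator),
                    "RMSE": rmse(pred, c.m_avg),
                }
            )
        return FitResult(
            model=model,
            params=params,
            per_condition=per_condition,
            times_min=times,
            observed=observed,
            predicted=predicted,
            diagnostics=diagnostics,
            estimator=self,
        )


class VariableDiffusivityModel(_DryingEstimatorMixin, BaseEstimator):
    """Least-squares fit of the moisture/temperature-dependent diffusivity law.

    Minimizes the pooled sum of squared residuals between simulated and
    observed average moisture over all supplied curves inside ``bounds``.
    Global bounded derivative-free search: differential evolution with a
    Latin-hypercube initial population, followed by an optional Powell
    polish that is kept only if it improves the objective.  Deterministic
    for a given seed and configuration.

    Parameters
    ----------
    thickness, n_layers : shell grid (L [m] and Z).
    bounds : dict mapping D0/Ea/a/b to (lo, hi); defaults ``DEFAULT_BOUNDS``.
    seed : seed for the evolution (and its initial sample).
    maxiter, popsize, tol : differential-evolution controls.
    polish : run the bounded Powell refinement after the evolution.
    geometry, boundary_scheme, safety : solver scheme options.
    deff_form : "exponent" or "additive" diffusivity law.
    per_condition : fit an independent parameter set per condition.
    r2_denominator : form of the determination coefficient.

    Attributes
    ----------
    params_ : fitted :class:`DeffParams` (dict by condition if per_condition).
    result_ : :class:`FitResult` with per-condition R2/RMSE and predictions.
    converged_, n_iter_, sse_ : optimizer diagnostics.
    """

    def __init__(
        self,
        thickness: float = 2e-4,
        n_layers: int = 4,
        bounds: Optional[Dict[str, tuple]] = None,
        seed: int = 20230605,
        maxiter: int = 300,
        popsize: int = 15,
        tol: float = 1e-8,
        polish: bool = True,
        geometry: str = "planar",
        boundary_scheme: str = "paper",
        safety: float = 0.9,
        deff_form: str = "exponent",
        per_condition: bool = False,
        r2_denominator: str = "predicted_mean",
        residual_scale: str = "relative",
    ):
        self.thickness = thickness
        self.n_layers = n_layers
        self.bounds = bounds
        self.seed = seed
        self.maxiter = maxiter
        self.popsize = popsize
        self.tol = tol
        self.polish = polish
        self.geometry = geometry
        self.boundary_scheme = boundary_scheme
        self.safety = safety
        self.deff_form = deff_form
        self.per_condition = per_condition
        self.r2_denominator = r2_denominator
        self.residual_scale = residual_scale

    # -- internals ---------------------------------------------------------
    # Reparameterization: D0 and Ea are almost perfectly correlated through
    # D0*exp(-Ea/(R*T)) over the narrow temperature range of a drying study,
    # and the overall diffusivity scale spans many decades.  The search
    # therefore works in u = log10 of the Arrhenius factor at a reference
    # temperature (the mean of the fitted conditions); the box for u spans
    # the decades implied by the D0 and Ea bounds.
    def _effective_bounds(self) -> Dict[str, tuple]:
        b = dict(DEFAULT_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        d_lo, d_hi = b["D0"]
        if d_lo <= 0 or d_hi <= d_lo:
            raise ConfigError("D0 bounds must be positive and increasing")
        return b

    def _u_bounds(self, t_ref: float) -> tuple:
        b = self._effective_bounds()
        d_lo, d_hi = b["D0"]
        ea_lo, ea_hi = b["Ea"]
        scale = np.log(10.0) * R_GAS * t_ref
        return (np.log10(d_lo) - ea_hi / scale, np.log10(d_hi) - ea_lo / scale)

    def _unpack(self, u: float, ea: float, a: float, b: float, t_ref: float) -> DeffParams:
        d0 = 10.0 ** (u + ea / (np.log(10.0) * R_GAS * t_ref))
        return DeffParams(D0=d0, Ea=ea, a=a, b=b, form=self.deff_form)

    def _sse(self, params: DeffParams, curves: List[DryingCurve]) -> float:
        total = 0.0
        for c in curves:
            try:
                hist = self._simulate_curve(c, params=params)
            except NumericalError:
                return 1e30
            pred = predicted_average(hist, self._m0(c))
            total += float(np.sum(_residuals(pred, c.m_avg, self.residual_scale) ** 2))
        return total

    def _fit_one(self, curves: List[DryingCurve]):
        t_ref = float(np.mean([c.condition.temperature_k for c in curves]))
        b = self._effective_bounds()
        bounds = [self._u_bounds(t_ref), tuple(b["Ea"]), tuple(b["a"]), tuple(b["b"])]

        def objective(z):
            return self._sse(self._unpack(z[0], z[1], z[2], z[3], t_ref), curves)

        res = optimize.differential_evolution(
            objective,
            bounds,
            seed=self.seed,
            init="latinhypercube",
            maxiter=self.maxiter,
            popsize=self.popsize,
            tol=self.tol,
            polish=False,
        )
        x, fun, nfev, nit = res.x, float(res.fun), int(res.nfev), int(res.nit)
        converged = bool(res.success) or fun <= self.tol
        if self.polish:
            pol = optimize.minimize(
                objective,
                x,
                method="Powell",
                bounds=bounds,
                options={"maxfev": 2000, "xtol": 1e-8, "ftol": 1e-12},
            )
            nfev += int(pol.nfev)
            if pol.fun < fun:  # keep the polish only when it actually helps
                x, fun = pol.x, float(pol.fun)
                converged = converged or bool(pol.success)
        params = self._unpack(x[0], x[1], x[2], x[3], t_ref)
        diag = {
            "converged": converged,
            "n_fev": nfev,
            "n_iter": nit,
            "sse": fun,
            "seed": int(self.seed),
            "popsize": int(self.popsize),
        }
        return params, diag

    def _params_for(self, curve: DryingCurve):
        if isinstance(self.params_, dict):
            return self.params_[curve.label], None
        return self.params_, None

    # -- API ---------------------------------------------------------------
    def fit(self, X: Sequence[DryingCurve], y=None) -> "VariableDiffusivityModel":
        curves = _check_curves(X)
        if self.per_condition:
            params: Any = {}
            diag: Dict[str, Any] = {"per_condition": {}, "converged": True}
            for c in curves:
                p, d = self._fit_one([c])
                params[c.label] = p
                diag["per_condition"][c.label] = d
                diag["converged"] = diag["converged"] and d["converged"]
            diag["sse"] = float(
                sum(d["sse"] for d in diag["per_condition"].values())
            )
        else:
            params, diag = self._fit_one(curves)
        self.params_ = params
        self.converged_ = bool(diag["converged"])
        self.n_iter_ = int(diag.get("n_iter", 0))
        self.sse_ = float(diag["sse"])
        self.result_ = self._build_result("variable", params, curves, diag)
        if not self.converged_:
            self.result_.diagnostics["warning"] = "optimizer did not report convergence"
        return self


class ConstantDiffusivityModel(_DryingEstimatorMixin, BaseEstimator):
    """One constant diffusivity per drying condition, bounded scalar search.

    Curves sharing a condition label are pooled.  Fitted attribute
    ``d_per_condition_`` maps condition label to the scalar D [m^2 s^-1].
    """

    def __init__(
        self,
        thickness: float = 2e-4,
        n_layers: int = 4,
        d_bounds: tuple = (1e-14, 1e-2),
        geometry: str = "planar",
        boundary_scheme: str = "paper",
        safety: float = 0.9,
        r2_denominator: str = "predicted_mean",
        residual_scale: str = "relative",
        xatol: float = 1e-10,
    ):
        self.thickness = thickness
        self.n_layers = n_layers
        self.d_bounds = d_bounds
        self.geometry = geometry
        self.boundary_scheme = boundary_scheme
        self.safety = safety
        self.r2_denominator = r2_denominator
        self.residual_scale = residual_scale
        self.xatol = xatol

    def _sse_scalar(self, d_eff: float, curves: List[DryingCurve]) -> float:
        total = 0.0
        for c in curves:
            try:
                hist = self._simulate_curve(c, constant_d=d_eff)
            except NumericalError:
                return 1e30
            pred = predicted_average(hist, self._m0(c))
            total += float(np.sum(_residuals(pred, c.m_avg, self.residual_scale) ** 2))
        return total

    def _params_for(self, curve: DryingCurve):
        return None, self.d_per_condition_[curve.label]

    def fit(self, X: Sequence[DryingCurve], y=None) -> "ConstantDiffusivityModel":
        curves = _check_curves(X)
        lo, hi = self.d_bounds
        if lo <= 0 or hi <= lo:
            raise ConfigError("d_bounds must be positive and increasing")
        groups: Dict[str, List[DryingCurve]] = {}
        for c in curves:
            groups.setdefault(c.label, []).append(c)
        d_map: Dict[str, float] = {}
        diag: Dict[str, Any] = {"converged": True, "per_condition": {}}
        sse = 0.0
        for label, grp in groups.items():
            # SSE(log D) is flat in the instant-dry and no-dry regimes, so a
            # half-decade scan brackets the basin before the bounded refine
            lg_grid = np.arange(np.log10(lo), np.log10(hi) + 0.25, 0.5)
            scores = [self._sse_scalar(10.0**lg, grp) for lg in lg_grid]
            i = int(np.argmin(scores))
            res = optimize.minimize_scalar(
                lambda lg: self._sse_scalar(10.0**lg, grp),
                bounds=(lg_grid[max(i - 1, 0)], lg_grid[min(i + 1, lg_grid.size - 1)]),
                method="bounded",
                options={"xatol": self.xatol},
            )
            d_map[label] = float(10.0**res.x)
            diag["per_condition"][label] = {
                "converged": bool(res.success),
                "n_fev": int(res.nfev),
                "sse": float(res.fun),
            }
            diag["converged"] = diag["converged"] and bool(res.success)
            sse += float(res.fun)
        diag["sse"] = sse
        self.d_per_condition_ = d_map
        self.converged_ = bool(diag["converged"])
        self.sse_ = sse
        self.result_ = self._build_result("constant", dict(d_map), curves, diag)
        return self


@dataclass
class FitConfig:
    """Bundled configuration for the module-level fit wrappers."""

    bounds: Optional[Dict[str, tuple]] = None
    seed: int = 20230605
    maxiter: int = 300
    popsize: int = 15
    tol: float = 1e-8
    polish: bool = True
    geometry: str = "planar"
    boundary_scheme: str = "paper"
    safety: float = 0.9
    deff_form: str = "exponent"
    per_condition: bool = False
    r2_denominator: str = "predicted_mean"
    residual_scale: str = "relative"
    d_bounds: tuple = (1e-14, 1e-2)


def fit_variable(
    curves: Sequence[DryingCurve],
    grid: Optional[ShellGrid] = None,
    fit_config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit the variable-diffusivity law to the curves; see the estimator."""
    cfg = fit_config or FitConfig()
    grid = grid or build_grid(2e-4, 4)
    model = VariableDiffusivityModel(
        thickness=grid.thickness,
        n_layers=grid.n_layers,
        bounds=cfg.bounds,
        seed=cfg.seed,
        maxiter=cfg.maxiter,
        popsize=cfg.popsize,
        tol=cfg.tol,
        polish=cfg.polish,
        geometry=cfg.geometry,
        boundary_scheme=cfg.boundary_scheme,
        safety=cfg.safety,
        deff_form=cfg.deff_form,
        per_condition=cfg.per_condition,
        r2_denominator=cfg.r2_denominator,
        residual_scale=cfg.residual_scale,
    )
    return model.fit(curves).result_


def fit_constant(
    curves: Sequence[DryingCurve],
    grid: Optional[ShellGrid] = None,
    fit_config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one constant diffusivity per condition; see the estimator."""
    cfg = fit_config or FitConfig()
    grid = grid or build_grid(2e-4, 4)
    model = ConstantDiffusivityModel(
        thickness=grid.thickness,
        n_layers=grid.n_layers,
        d_bounds=cfg.d_bounds,
        geometry=cfg.geometry,
        boundary_scheme=cfg.boundary_scheme,
        safety=cfg.safety,
        r2_denominator=cfg.r2_denominator,
        residual_scale=cfg.residual_scale,
    )
    return model.fit(curves).result_


@dataclass
class ModelComparison:
    """Variable- vs constant-diffusivity comparison tables."""

    summary: "pd.DataFrame"
    per_time: "pd.DataFrame"


def compare_models(fit_v: FitResult, fit_c: FitResult) -> ModelComparison:
    """Tabulate per-condition score deltas and per-time relative errors.

    Both fits must have been produced on identical observations.
    """
    import pandas as pd

    if set(fit_v.observed) != set(fit_c.observed):
        raise ConfigError("fits cover different conditions")
    rows, per_time = [], []
    for label in fit_v.observed:
        if not np.array_equal(fit_v.observed[label], fit_c.observed[label]):
            raise ConfigError(f"fits were made on different observations ({label})")
        pc_v = next(d for d in fit_v.per_condition if d["condition"] == label)
        pc_c = next(d for d in fit_c.per_condition if d["condition"] == label)
        rows.append(
            {
                "condition": label,
                "R2_variable": pc_v["R2"],
                "R2_constant": pc_c["R2"],
                "delta_R2": pc_v["R2"] - pc_c["R2"],
                "RMSE_variable": pc_v["RMSE"],
                "RMSE_constant": pc_c["RMSE"],
                "delta_RMSE": pc_v["RMSE"] - pc_c["RMSE"],
            }
        )
        obs = fit_v.observed[label]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_v = np.abs(fit_v.predicted[label] - obs) / np.abs(obs)
            rel_c = np.abs(fit_c.predicted[label] - obs) / np.abs(obs)
        for i, t in enumerate(fit_v.times_min[label]):
            per_time.append(
                {
                    "condition": label,
                    "time_min": float(t),
                    "observed": float(obs[i]),
                    "pred_variable": float(fit_v.predicted[label][i]),
                    "pred_constant": float(fit_c.predicted[label][i]),
                    "rel_err_variable": float(rel_v[i]),
                    "rel_err_constant": float(rel_c[i]),
                }
            )
    return ModelComparison(
        summary=pd.DataFrame(rows).sort_values("condition").reset_index(drop=True),
        per_time=pd.DataFrame(per_time),
    )


def pooled_rmse(fit: FitResult) -> float:
    """RMSE over all conditions' points pooled together."""
    pred = np.concatenate([fit.predicted[k] for k in sorted(fit.predicted)])
    obs = np.concatenate([fit.observed[k] for k in sorted(fit.observed)])
    return rmse(pred, obs)
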