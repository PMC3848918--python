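"""Bounded nonlinear estimation of growth models against time-series data.

The central objects follow the statsmodels convention:

* :class:`GrowthCurveModel` binds one or several observed time series to a
  registered model and a box of parameter search ranges;
* :meth:`GrowthCurveModel.fit` runs multi-start bounded least squares and
  returns a :class:`GrowthCurveResults` with estimates, RMSE, diagnostics,
  and a ``summary()`` table.

Functional wrappers (``fit_model``, ``fit_aggregate``, ``compare_models``,
``manual_log_regression``) cover the scripting surface.

Estimator design
----------------
The objective is the sum of squared residuals between the observed values
and the simulated curve at the observation times, minimized over the box
defined by the parameter search ranges (scipy ``least_squares`` with the
trust-region-reflective method).  Because growth-model objectives are
multi-modal, the optimizer is restarted from ``n_starts`` points: the first
start uses the default guesses (initial-condition parameters seeded from the
data), the rest come from a seeded Latin-hypercube over the box; parameters
whose strictly positive range spans more than half a decade are sampled
log-uniformly and optimized in log10 space.  The best converged start wins;
cost ties (relative 1e-12) break toward the earlier start, so a fit is a
deterministic function of (data, specs, options).

RMSE uses denominator n, not n - p: it is a cross-model comparison baseline,
not an unbiased variance estimate, and must stay comparable between models
with different parameter counts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core import (
    Curve,
    DomainError,
    EstimationError,
    FitOptions,
    GrowthfitError,
    ParameterSpec,
    TimeSeries,
    ValidationError,
)
from .registry import Registry, get_default_registry

__all__ = [
    "rmse",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "LinearFit",
    "ComparisonTable",
    "fit_model",
    "fit_aggregate",
    "compare_models",
    "manual_log_regression",
]

#: residual magnitude substituted when a candidate parameter vector cannot be
#: simulated (invalid combination inside the box, ODE failure); keeps the
#: optimizer away without raising.
_PENALTY = 1e6

#: strictly positive parameter ranges spanning more than this many decades
#: are sampled log-uniformly and optimized in log10 space: rate coefficients
#: (e.g. the hyperbolastic delta) correlate with exponents along valleys that
#: are straight in log-space but exponentially curved in linear space.
_LOG_SAMPLING_DECADES = 0.5


def rmse(observed, predicted) -> float:
    """Root mean square error sqrt(mean((obs - pred)^2)); denominator n."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError(
            f"rmse: shape mismatch {obs.shape} vs {pred.shape}"
        )
    if obs.size == 0:
        raise ValidationError("rmse: empty sequences")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass(frozen=True)
class LinearFit:
    """Manual log-linear regression result: ln(value) ~ time on a window."""

    slope: float        # specific growth rate, 1/time on natural-log scale
    intercept: float
    window: tuple
    r_squared: float
    n_points: int


def manual_log_regression(data: TimeSeries, window: Sequence[float]) -> LinearFit:
    """OLS of ln(value) on time restricted to ``window = (t_start, t_end)``.

    The slope is the specific growth rate over the window — the traditional
    manual alternative to full-model fitting.  Raises DomainError naming the
    offending rows if the window contains non-positive values, and
    ValidationError if fewer than 2 points fall inside it.
    """
    t_start, t_end = float(window[0]), float(window[1])
    mask = (data.times >= t_start) & (data.times <= t_end)
    t = data.times[mask]
    v = data.values[mask]
    if t.size < 2:
        raise ValidationError(
            f"manual_log_regression: need >= 2 points in window "
            f"[{t_start}, {t_end}], found {t.size}"
        )
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        rows = ", ".join(f"t={t[i]:g} (value {v[i]:g})" for i in bad[:5])
        raise DomainError(
            f"manual_log_regression: non-positive values in window at {rows}"
        )
    y = np.log(v)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else 1.0 - ss_res / ss_tot
    return LinearFit(float(slope), float(intercept), (t_start, t_end),
                     float(r2), int(t.size))


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurveResults:
    """Outcome of one (possibly pooled) model fit.

    ``estimates`` includes pinned parameters; ``rmse`` is computed on the raw
    signal scale over the pooled residuals, regardless of the fitting scale.
    ``fitted_curves`` holds one simulated curve per dataset, on that
    dataset's observation times.
    """

    model_id: str
    param_names: tuple
    estimates: dict
    rmse: float
    per_dataset_rmse: tuple
    n_points: int
    converged: bool
    n_starts_used: int
    fitted_curves: tuple
    dataset_names: tuple
    scale: str
    seed: int
    cost: float = float("nan")
    start_report: tuple = field(default=(), compare=False, repr=False)

    @property
    def params(self) -> dict:
        """Alias for ``estimates`` (statsmodels naming)."""
        return self.estimates

    @property
    def n_datasets(self) -> int:
        return len(self.fitted_curves)

    @property
    def fitted_curve(self) -> Curve:
        """The fitted curve for single-dataset fits."""
        if len(self.fitted_curves) != 1:
            raise ValidationError(
                "fitted_curve is defined for single-dataset fits; "
                "use fitted_curves for pooled fits"
            )
        return self.fitted_curves[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GrowthCurveResults):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "param_names": list(self.param_names),
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "rmse": float(self.rmse),
            "per_dataset_rmse": [float(r) for r in self.per_dataset_rmse],
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
            "fitted_curves": [
                {"times": c.times.tolist(), "values": c.values.tolist()}
                for c in self.fitted_curves
            ],
            "dataset_names": list(self.dataset_names),
            "scale": self.scale,
            "seed": int(self.seed),
            "cost": float(self.cost),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowthCurveResults":
        return cls(
            model_id=d["model_id"],
            param_names=tuple(d["param_names"]),
            estimates=dict(d["estimates"]),
            rmse=float(d["rmse"]),
            per_dataset_rmse=tuple(d["per_dataset_rmse"]),
            n_points=int(d["n_points"]),
            converged=bool(d["converged"]),
            n_starts_used=int(d["n_starts_used"]),
            fitted_curves=tuple(
                Curve(np.asarray(c["times"]), np.asarray(c["values"]))
                for c in d["fitted_curves"]
            ),
            dataset_names=tuple(d["dataset_names"]),
            scale=d["scale"],
            seed=int(d["seed"]),
            cost=float(d.get("cost", float("nan"))),
        )

    def predict(self, times, *, registry: Registry | None = None) -> Curve:
        """Simulate the fitted model on an arbitrary time grid."""
        reg = registry if registry is not None else get_default_registry()
        return reg.simulate(self.model_id, self.estimates, times)

    def summary(self) -> str:
        width = 62
        lines = []
        lines.append("Growth Curve Fit Results".center(width))
        lines.append("=" * width)
        left = [
            f"Model:        {self.model_id}",
            f"Datasets:     {self.n_datasets}",
            f"Scale:        {self.scale}",
            f"Seed:         {self.seed}",
        ]
        right = [
            f"N points:   {self.n_points}",
            f"Converged:  {self.converged}",
            f"Starts:     {self.n_starts_used}",
            f"RMSE:       {self.rmse:.6g}",
        ]
        for a, b in zip(left, right):
            lines.append(f"{a:<34}{b}")
        lines.append("-" * width)
        lines.append(f"{'parameter':<16}{'estimate':>18}")
        for name in self.param_names:
            lines.append(f"{name:<16}{self.estimates[name]:>18.8g}")
        if self.n_datasets > 1:
            lines.append("-" * width)
            lines.append(f"{'dataset':<28}{'rmse':>14}")
            for name, r in zip(self.dataset_names, self.per_dataset_rmse):
                lines.append(f"{name or '(unnamed)':<28}{r:>14.6g}")
        lines.append("=" * width)
        lines.append("Note: RMSE denominator is n (no degrees-of-freedom correction).")
        return "\n".join(lines)

    def plot(self, datasets: Sequence[TimeSeries] | None = None, ax=None):
        """Plot fitted curves (and the data, if given).  Needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if datasets:
            for ds in datasets:
                ax.plot(ds.times, ds.values, "o", ms=3, alpha=0.6,
                        label=ds.name or None)
        for name, curve in zip(self.dataset_names, self.fitted_curves):
            ax.plot(curve.times, curve.values, "-",
                    label=f"{self.model_id} fit" if not name else f"fit {name}")
        ax.set_xlabel("time")
        ax.set_ylabel("signal")
        ax.legend(loc="best", fontsize="small")
        return ax


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class GrowthCurveModel:
    """A registered growth model bound to observed data and search ranges.

    Parameters
    ----------
    data : TimeSeries or sequence of TimeSeries
        One series for a single-measurement fit; several for a pooled
        (replicate-aggregated) fit minimizing the summed squared residuals
        over all points of all series.
    model : str
        Registered model id (see ``Registry.model_ids()``).
    specs : sequence of ParameterSpec or mapping, optional
        Search ranges; defaults to the registry's ranges for the model.
        Must cover every model parameter exactly.
    registry : Registry, optional
        Defaults to the shared built-in registry.
    """

    def __init__(self, data, model: str = "gompertz", specs=None,
                 registry: Registry | None = None):
        self.registry = registry if registry is not None else get_default_registry()
        self.definition = self.registry.get(model)
        self.model_id = model

        if isinstance(data, TimeSeries):
            datasets = [data]
        elif hasattr(data, "columns"):  # DataFrame
            datasets = [TimeSeries.from_dataframe(data)]
        else:
            datasets = list(data)
            if not datasets:
                raise ValidationError("need at least one dataset")
            for ds in datasets:
                if not isinstance(ds, TimeSeries):
                    raise ValidationError(
                        f"datasets must be TimeSeries, got {type(ds).__name__}"
                    )
        self.datasets: tuple = tuple(datasets)

        if specs is None:
            resolved = list(self.definition.parameters)
        elif isinstance(specs, Mapping):
            from .core import specs_from_mapping

            resolved = specs_from_mapping(specs)
        else:
            resolved = list(specs)
        by_name = {s.name: s for s in resolved}
        missing = [n for n in self.definition.param_names if n not in by_name]
        extra = [n for n in by_name if n not in self.definition.param_names]
        if missing or extra:
            raise ValidationError(
                f"specs must cover the model parameters exactly; "
                f"missing={missing}, unexpected={extra}"
            )
        # definition order is the canonical parameter order everywhere
        self.specs: tuple = tuple(by_name[n] for n in self.definition.param_names)

    @classmethod
    def from_dataframe(cls, df, model: str = "gompertz", *, time_col: str = "time",
                       value_col: str = "value", group_col: str | None = None,
                       specs=None, registry: Registry | None = None):
        """Build from a tidy DataFrame; ``group_col`` splits replicates."""
        if group_col is None:
            data = TimeSeries.from_dataframe(df, time_col, value_col)
        else:
            data = [
                TimeSeries.from_dataframe(g.sort_values(time_col), time_col,
                                          value_col, name=str(key))
                for key, g in df.groupby(group_col, sort=True)
            ]
        return cls(data, model=model, specs=specs, registry=registry)

    # -- fitting ------------------------------------------------------------

    def _default_start(self, free_specs: Sequence[ParameterSpec]) -> np.ndarray:
        first = self.datasets[0]
        out = []
        for s in free_specs:
            if s.is_initial_condition:
                guess = first.times[0] if s.name == "t0" else first.values[0]
            elif s.default_guess is not None:
                guess = s.default_guess
            else:
                guess = 0.5 * (s.lower + s.upper)
            out.append(float(np.clip(guess, s.lower, s.upper)))
        return np.asarray(out)

    @staticmethod
    def _lhs_starts(free_specs, n: int, seed: int) -> np.ndarray:
        if n <= 0:
            return np.empty((0, len(free_specs)))
        sampler = qmc.LatinHypercube(d=len(free_specs), seed=seed)
        unit = sampler.random(n)
        cols = []
        for j, s in enumerate(free_specs):
            u = unit[:, j]
            span_decades = (
                np.log10(s.upper / s.lower) if s.lower > 0 else 0.0
            )
            if s.lower > 0 and span_decades > _LOG_SAMPLING_DECADES:
                cols.append(10 ** (np.log10(s.lower) + u * span_decades))
            else:
                cols.append(s.lower + u * (s.upper - s.lower))
        return np.column_stack(cols)

    def _check_data(self, options: FitOptions, n_free: int) -> None:
        pooled = np.concatenate([ds.values for ds in self.datasets])
        if pooled.size < n_free:
            raise EstimationError(
                f"{pooled.size} data points cannot constrain {n_free} free "
                f"parameters"
            )
        if np.ptp(pooled) == 0.0:
            raise EstimationError(
                "degenerate data: all observed values are identical"
            )
        if options.scale == "log" and np.any(pooled <= 0):
            raise EstimationError(
                "log-scale fitting requires strictly positive observations"
            )

    def fit(self, options: FitOptions | None = None, **overrides) -> GrowthCurveResults:
        """Run the multi-start bounded least-squares estimation."""
        if options is None:
            options = FitOptions()
        if overrides:
            options = replace(options, **overrides)

        pinned = {k: float(v) for k, v in options.pin.items()}
        unknown_pins = [k for k in pinned if k not in self.definition.param_names]
        if unknown_pins:
            raise ValidationError(f"pinned parameters not in model: {unknown_pins}")
        free_specs = [s for s in self.specs if s.name not in pinned]
        if not free_specs:
            raise ValidationError("all parameters pinned; nothing to estimate")
        free_names = [s.name for s in free_specs]
        self._check_data(options, len(free_specs))

        # positive wide-range parameters are optimized in log10 space (same
        # rule as the start sampler); see _LOG_SAMPLING_DECADES
        log_mask = np.array([
            s.lower > 0 and np.log10(s.upper / s.lower) > _LOG_SAMPLING_DECADES
            for s in free_specs
        ])

        def to_internal(x: np.ndarray) -> np.ndarray:
            out = np.array(x, dtype=float)
            out[log_mask] = np.log10(out[log_mask])
            return out

        def to_external(z: np.ndarray) -> np.ndarray:
            out = np.array(z, dtype=float)
            out[log_mask] = 10.0 ** out[log_mask]
            return out

        lower = to_internal(np.array([s.lower for s in free_specs]))
        upper = to_internal(np.array([s.upper for s in free_specs]))
        obs = np.concatenate([ds.values for ds in self.datasets])
        log_obs = np.log(obs) if options.scale == "log" else None

        def residuals(theta: np.ndarray) -> np.ndarray:
            params = dict(zip(free_names, to_external(theta)))
            params.update(pinned)
            try:
                preds = [
                    self.registry.simulate(
                        self.model_id, params, ds.times,
                        rtol=options.rtol, atol=options.atol,
                    ).values
                    for ds in self.datasets
                ]
            except GrowthfitError:
                return np.full(obs.size, _PENALTY)
            pred = np.concatenate(preds)
            if not np.all(np.isfinite(pred)):
                return np.full(obs.size, _PENALTY)
            if options.scale == "log":
                return np.log(np.maximum(pred, 1e-300)) - log_obs
            return pred - obs

        starts = [to_internal(self._default_start(free_specs))]
        starts.extend(
            to_internal(x)
            for x in self._lhs_starts(free_specs, options.n_starts - 1, options.seed)
        )

        def improves(candidate, incumbent) -> bool:
            """Success beats failure; then a meaningfully lower cost beats an
            earlier start — cost ties (relative 1e-12) keep the earlier,
            deterministic-guess start."""
            if candidate.success != incumbent.success:
                return candidate.success
            return candidate.cost < incumbent.cost * (1.0 - 1e-12)

        best = None
        n_used = 0
        for i, x0 in enumerate(starts):
            n_used += 1
            x0 = np.clip(x0, lower, upper)
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(lower, upper),
                    method="trf",
                    x_scale="jac",
                    ftol=options.ftol,
                    xtol=options.xtol,
                    gtol=options.gtol,
                    max_nfev=options.max_nfev,
                )
            except Exception:
                continue
            if best is None or improves(res, best):
                best = res
            if (
                options.early_stop_cost is not None
                and res.success
                and res.cost <= options.early_stop_cost
            ):
                break

        if best is None:
            raise EstimationError(
                f"{self.model_id}: no optimizer start produced a result"
            )
        winner = best
        # round-trip through log10 can overshoot a bound by one ulp
        external = np.clip(
            to_external(winner.x),
            [s.lower for s in free_specs],
            [s.upper for s in free_specs],
        )
        estimates = dict(zip(free_names, (float(v) for v in external)))
        estimates.update(pinned)
        # report in canonical parameter order
        estimates = {n: estimates[n] for n in self.definition.param_names}

        fitted = tuple(
            self.registry.simulate(
                self.model_id, estimates, ds.times,
                rtol=options.rtol, atol=options.atol,
            )
            for ds in self.datasets
        )
        pooled_pred = np.concatenate([c.values for c in fitted])
        pooled_rmse = rmse(obs, pooled_pred)
        per_ds = tuple(
            rmse(ds.values, c.values) for ds, c in zip(self.datasets, fitted)
        )
        return GrowthCurveResults(
            model_id=self.model_id,
            param_names=tuple(self.definition.param_names),
            estimates=estimates,
            rmse=pooled_rmse,
            per_dataset_rmse=per_ds,
            n_points=int(obs.size),
            converged=bool(winner.success),
            n_starts_used=n_used,
            fitted_curves=fitted,
            dataset_names=tuple(ds.name for ds in self.datasets),
            scale=options.scale,
            seed=int(options.seed),
            cost=float(winner.cost),
        )


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_model(model_id: str, data: TimeSeries, specs=None,
              options: FitOptions | None = None,
              registry: Registry | None = None) -> GrowthCurveResults:
    """Fit one registered model to one time series (box-constrained)."""
    definition_estimator = (
        registry if registry is not None else get_default_registry()
    ).get(model_id).estimate_fn
    if definition_estimator is not None:
        return definition_estimator(data, specs, options)
    return GrowthCurveModel(data, model=model_id, specs=specs,
                            registry=registry).fit(options)


def fit_aggregate(model_id: str, datasets: Sequence[TimeSeries], specs=None,
                  options: FitOptions | None = None,
                  registry: Registry | None = None) -> GrowthCurveResults:
    """Pooled fit: one parameter vector against all datasets' points.

    Replicates are weighted by their point counts (the pooled sum of squared
    residuals), so a longer series contributes proportionally more.
    """
    return GrowthCurveModel(list(datasets), model=model_id, specs=specs,
                            registry=registry).fit(options)


@dataclass(frozen=True)
class ComparisonRow:
    model_id: str
    result: GrowthCurveResults | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None


@dataclass(frozen=True)
class ComparisonTable:
    """Cross-model RMSE ranking for one dataset.

    Rows are sorted: converged fits by ascending RMSE, then non-converged
    fits by ascending RMSE, then models whose fit raised an error.
    """

    rows: tuple

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i) -> ComparisonRow:
        return self.rows[i]

    @property
    def best(self) -> ComparisonRow:
        return self.rows[0]

    def to_dataframe(self):
        import pandas as pd

        records = []
        for row in self.rows:
            rec = {"model_id": row.model_id}
            if row.result is not None:
                rec.update(
                    rmse=row.result.rmse,
                    converged=row.result.converged,
                    n_points=row.result.n_points,
                    **{f"est_{k}": v for k, v in row.result.estimates.items()},
                )
            else:
                rec.update(rmse=np.nan, converged=False, error=row.error)
            records.append(rec)
        return pd.DataFrame(records)

    def __str__(self) -> str:
        lines = [f"{'model':<18}{'rmse':>14}{'converged':>12}"]
        lines.append("-" * 44)
        for row in self.rows:
            if row.result is None:
                lines.append(f"{row.model_id:<18}{'error':>14}{'-':>12}  {row.error}")
            else:
                lines.append(
                    f"{row.model_id:<18}{row.result.rmse:>14.6g}"
                    f"{str(row.result.converged):>12}"
                )
        return "\n".join(lines)


def _model_seed(base_seed: int, model_id: str) -> int:
    """Stable per-model seed so candidate order never changes a fit."""
    return (int(base_seed) + zlib.crc32(model_id.encode())) % (2**31)


def compare_models(data: TimeSeries, candidates, options: FitOptions | None = None,
                   registry: Registry | None = None) -> ComparisonTable:
    """Fit several candidate models to the same series and rank by RMSE.

    ``candidates`` is a list of model ids or (model_id, specs) pairs.  Each
    candidate is fitted with a seed derived deterministically from the base
    seed and the model id, so the table is invariant to candidate order.
    Per-model failures become table rows, never exceptions.
    """
    if options is None:
        options = FitOptions()
    normalized = []
    for cand in candidates:
        if isinstance(cand, str):
            normalized.append((cand, None))
        else:
            model_id, specs = cand
            normalized.append((model_id, specs))
    if not normalized:
        raise ValidationError("compare_models needs at least one candidate")

    rows = []
    for model_id, specs in normalized:
        per_model = replace(options, seed=_model_seed(options.seed, model_id))
        try:
            result = fit_model(model_id, data, specs, per_model, registry)
            rows.append(ComparisonRow(model_id, result))
        except GrowthfitError as exc:
            rows.append(ComparisonRow(model_id, None, error=str(exc)))

    def sort_key(row: ComparisonRow):
        if row.result is None:
            return (2, np.inf, row.model_id)
        return (0 if row.result.converged else 1, row.result.rmse, row.model_id)

    return ComparisonTable(tuple(sorted(rows, key=sort_key)))
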