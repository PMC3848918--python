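"""Shared containers: curves, time series, parameter specifications, fit options.

Everything downstream (model evaluation, estimation, storage) speaks in terms
of these light value types.  ``TimeSeries`` is the unit of fitting; ``Curve``
is a simulated trajectory aligned with a requested time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np


class GrowthfitError(Exception):
    """Base class for all package errors."""


class ValidationError(GrowthfitError, ValueError):
    """Invalid parameters or malformed inputs; lists the violated invariants."""


class DomainError(GrowthfitError, ValueError):
    """Input outside the mathematical domain of an operation."""


class UnknownModelError(GrowthfitError, KeyError):
    """Model id not present in the registry."""


class EstimationError(GrowthfitError, ValueError):
    """Data unusable for estimation (degenerate, too short, non-finite)."""


class IntegrationError(GrowthfitError, RuntimeError):
    """ODE solver failed; carries the solver diagnostic."""


class CsvImportError(GrowthfitError, ValueError):
    """Unparseable measurement file; names the offending line."""


class RepositoryError(GrowthfitError, ValueError):
    """Corrupt or incomplete on-disk repository tree."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Curve:
    """A simulated trajectory: strictly increasing times with finite values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        v = _as_float_array(self.values, "values")
        if t.size != v.size:
            raise ValidationError(
                f"times and values length mismatch: {t.size} vs {v.size}"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValidationError("curve values must all be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Curve):
            return NotImplemented
        return np.array_equal(self.times, other.times) and np.array_equal(
            self.values, other.values
        )


@dataclass(frozen=True)
class TimeSeries:
    """Observed (time, value) records — the unit of fitting.

    Times must be strictly increasing and values finite; replicate curves are
    separate ``TimeSeries`` objects, never duplicated time points.
    """

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        v = _as_float_array(self.values, "values")
        if t.size != v.size:
            raise ValidationError(
                f"times and values length mismatch: {t.size} vs {v.size}"
            )
        if t.size == 0:
            raise ValidationError("a time series needs at least one point")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise ValidationError("times must all be finite")
        if not np.all(np.isfinite(v)):
            raise ValidationError("values must all be finite (no NaN/inf)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            self.name == other.name
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time", value_col: str = "value",
                       name: str = "") -> "TimeSeries":
        return cls(df[time_col].to_numpy(float), df[value_col].to_numpy(float), name)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "value": self.values})


@dataclass(frozen=True)
class ParameterSpec:
    """Search range for one model parameter.

    ``lower``/``upper`` are the box constraints handed to the optimizer.
    ``is_initial_condition`` marks parameters that describe the state at the
    first observation (y0, P0, r0, ...); their default start value is taken
    from the data unless ``default_guess`` overrides it.
    """

    name: str
    lower: float
    upper: float
    is_initial_condition: bool = False
    default_guess: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValidationError(f"{self.name}: bounds must be finite")
        if not self.lower < self.upper:
            raise ValidationError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )
        if self.default_guess is not None and not (
            self.lower <= self.default_guess <= self.upper
        ):
            raise ValidationError(
                f"{self.name}: default_guess {self.default_guess} outside "
                f"[{self.lower}, {self.upper}]"
            )

    def scaled_around(self, center: float, span: float = 10.0) -> "ParameterSpec":
        """Return a copy whose range spans ``span``-fold around ``center``.

        Positive centers get a geometric range [c/sqrt(span), c*sqrt(span)];
        other centers get an additive range of the same total width.
        """
        if center > 0:
            half = float(np.sqrt(span))
            lower, upper = center / half, center * half
        else:
            width = max(abs(center) * (span - 1) / 2.0, 1.0)
            lower, upper = center - width, center + width
        guess = self.default_guess
        if guess is not None and not (lower <= guess <= upper):
            guess = None
        return replace(self, lower=lower, upper=upper, default_guess=guess)


@dataclass(frozen=True)
class FitOptions:
    """Estimator settings shared by every model.

    n_starts      multi-start budget (Latin hypercube over the search box)
    seed          RNG seed for the start sampler; same seed => same fit
    scale         "raw" fits signal-scale residuals, "log" fits ln-scale
    ftol/xtol/gtol  scipy.optimize.least_squares tolerances
    rtol/atol     ODE solver tolerances for differential models
    pin           mapping name -> value fixing a parameter (not optimized)
    early_stop_cost  stop the start loop once a converged start reaches this
                  cost (sum of squares / 2); None runs the full budget
    """

    n_starts: int = 20
    seed: int = 0
    scale: str = "raw"
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    rtol: float = 1e-8
    atol: float = 1e-10
    max_nfev: int | None = None
    pin: Mapping[str, float] = field(default_factory=dict)
    early_stop_cost: float | None = None

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.scale not in ("raw", "log"):
            raise ValidationError(f"scale must be 'raw' or 'log', got {self.scale!r}")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "FitOptions":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in cfg.items() if k in known}
        return cls(**kwargs)


def specs_from_mapping(cfg: Mapping[str, Mapping]) -> list[ParameterSpec]:
    """Build ParameterSpecs from a ``{name: {lower, upper, ...}}`` mapping."""
    specs = []
    for name, entry in cfg.items():
        specs.append(
            ParameterSpec(
                name=name,
                lower=float(entry["lower"]),
                upper=float(entry["upper"]),
                is_initial_condition=bool(entry.get("is_initial_condition", False)),
                default_guess=(
                    None
                    if entry.get("default_guess") is None
                    else float(entry["default_guess"])
                ),
            )
        )
    return specs


def load_fit_config(path) -> dict:
    """Read a YAML/JSON fit configuration.

    Returns ``{"options": FitOptions, "specs": list[ParameterSpec] | None}``.
    Recognized top-level keys: any FitOptions field, plus ``parameters``
    holding per-parameter ``{lower, upper, is_initial_condition,
    default_guess}`` entries.
    """
    import json

    import yaml

    text = open(path).read()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"fit config {path} must be a mapping")
    specs = None
    if "parameters" in cfg:
        specs = specs_from_mapping(cfg["parameters"])
    return {"options": FitOptions.from_mapping(cfg), "specs": specs}
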