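"""Model registry: the two-function plugin contract (simulate, estimate).

Every model — built-in or user-contributed — is a :class:`ModelDefinition`
carrying parameter metadata plus a ``simulate_fn`` and, optionally, its own
``estimate_fn``.  Models without an ``estimate_fn`` are fitted by the generic
bounded least-squares estimator.  The contract is in-process; anything that
can evaluate ``simulate_fn(params, times) -> values`` can be registered.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import models as _m
from .core import (
    Curve,
    UnknownModelError,
    ValidationError,
    specs_from_mapping,
)

SimulateFn = Callable[..., np.ndarray]


@dataclass(frozen=True)
class ModelDefinition:
    """A registered model: metadata plus the two contract functions."""

    model_id: str
    display_name: str
    equation_text: str
    parameters: tuple
    simulate_fn: SimulateFn
    estimate_fn: Callable | None = None
    is_ode: bool = False

    def __post_init__(self):
        if not self.model_id:
            raise ValidationError("model_id must be non-empty")
        if not self.parameters:
            raise ValidationError(f"{self.model_id}: parameters must be non-empty")
        object.__setattr__(self, "parameters", tuple(self.parameters))
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValidationError(f"{self.model_id}: duplicate parameter names")

    @property
    def param_names(self) -> tuple:
        return tuple(p.name for p in self.parameters)

    def probe_params(self) -> dict[str, float]:
        """Mid-range parameter values used by the contract validator."""
        out = {}
        for p in self.parameters:
            out[p.name] = (
                p.default_guess
                if p.default_guess is not None
                else 0.5 * (p.lower + p.upper)
            )
        return out

    def summary(self) -> dict:
        return {
            "model_id": self.model_id,
            "display_name": self.display_name,
            "equation_text": self.equation_text,
            "n_parameters": len(self.parameters),
            "parameters": [
                {
                    "name": p.name,
                    "lower": p.lower,
                    "upper": p.upper,
                    "is_initial_condition": p.is_initial_condition,
                    "default_guess": p.default_guess,
                }
                for p in self.parameters
            ],
            "is_ode": self.is_ode,
        }


class Registry:
    """Ordered collection of ModelDefinitions keyed by model_id."""

    def __init__(self):
        self._models: dict[str, ModelDefinition] = {}

    def register(self, definition: ModelDefinition) -> "Registry":
        if definition.model_id in self._models:
            raise ValidationError(
                f"model id {definition.model_id!r} already registered"
            )
        self._models[definition.model_id] = definition
        return self

    def get(self, model_id: str) -> ModelDefinition:
        try:
            return self._models[model_id]
        except KeyError:
            raise UnknownModelError(
                f"unknown model {model_id!r}; available: {sorted(self._models)}"
            ) from None

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._models

    def __len__(self) -> int:
        return len(self._models)

    def model_ids(self) -> list[str]:
        return list(self._models)  # registration order

    def list_models(self) -> list[dict]:
        """Summaries in registration order (deterministic)."""
        return [d.summary() for d in self._models.values()]

    def simulate(self, model_id: str, params, times, *, rtol: float = 1e-8,
                 atol: float = 1e-10) -> Curve:
        """Dispatch to the model's simulate function; returns a Curve aligned
        1:1 with the requested times."""
        definition = self.get(model_id)
        pdict = params.as_dict() if hasattr(params, "as_dict") else dict(params)
        t = np.asarray(times, dtype=float)
        if definition.is_ode:
            values = definition.simulate_fn(pdict, t, rtol=rtol, atol=atol)
        else:
            values = definition.simulate_fn(pdict, t)
        values = np.asarray(values, dtype=float)
        if values.shape != t.shape:
            raise ValidationError(
                f"{model_id}: simulate_fn returned shape {values.shape} "
                f"for {t.shape} times"
            )
        return Curve(t, values)


def register_model(registry: Registry, definition: ModelDefinition) -> Registry:
    """Functional alias for :meth:`Registry.register`."""
    return registry.register(definition)


def list_models(registry: Registry) -> list[dict]:
    return registry.list_models()


# ---------------------------------------------------------------------------
# Built-in model wiring
# ---------------------------------------------------------------------------

def _closed_form(param_class, value_fn):
    def simulate(params: Mapping[str, float], times):
        return value_fn(param_class(**params), times)

    return simulate


def _poly_simulate(params: Mapping[str, float], times):
    order = len(params)
    coeffs = [params[f"c{i}"] for i in range(order)]
    return _m.polynomial_value(_m.PolynomialParams(tuple(coeffs)), times)


def _lcf_simulate(params: Mapping[str, float], times, *, rtol=1e-8, atol=1e-10):
    p = _m.LiveCellFractionParams(**params)
    return _m.lcf_simulate(p, times, rtol=rtol, atol=atol).values


def _load_default_ranges() -> dict:
    ref = importlib.resources.files("growthfit").joinpath("data/model_ranges.yaml")
    return yaml.safe_load(ref.read_text())


_BUILTIN_SIMULATORS: dict[str, tuple[SimulateFn, bool]] = {
    "gompertz": (_closed_form(_m.GompertzParams, _m.gompertz_value), False),
    "logistic": (_closed_form(_m.LogisticParams, _m.logistic_value), False),
    "richards": (_closed_form(_m.RichardsParams, _m.richards_value), False),
    "baranyi": (_closed_form(_m.BaranyiParams, _m.baranyi_value), False),
    "baranyi_classic": (
        _closed_form(_m.BaranyiParams, _m.baranyi_classic_value),
        False,
    ),
    "h3": (_closed_form(_m.H3Params, _m.h3_value), False),
    "lcf": (_lcf_simulate, True),
    "poly1": (_poly_simulate, False),
    "poly2": (_poly_simulate, False),
    "exp_decay": (_closed_form(_m.ExpDecayParams, _m.exp_decay_value), False),
}


def builtin_registry() -> Registry:
    """A fresh registry preloaded with every built-in model."""
    meta = _load_default_ranges()
    reg = Registry()
    for model_id, (sim_fn, is_ode) in _BUILTIN_SIMULATORS.items():
        entry = meta[model_id]
        ordered = specs_from_mapping(entry["parameters"])
        reg.register(
            ModelDefinition(
                model_id=model_id,
                display_name=entry["display_name"],
                equation_text=entry["equation_text"],
                parameters=tuple(ordered),
                simulate_fn=sim_fn,
                is_ode=is_ode,
            )
        )
    return reg


_default_registry: Registry | None = None


def get_default_registry() -> Registry:
    """Shared read-only registry of built-ins used by convenience functions."""
    global _default_registry
    if _default_registry is None:
        _default_registry = builtin_registry()
    return _default_registry


def simulate(model_id: str, params, times, *, registry: Registry | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Curve:
    """Simulate a registered model on a time grid (module-level dispatch)."""
    reg = registry if registry is not None else get_default_registry()
    return reg.simulate(model_id, params, times, rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# Contract validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContractClause:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ContractReport:
    model_id: str
    clauses: tuple

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.clauses)

    def __str__(self) -> str:
        lines = [f"contract report for {self.model_id!r}:"]
        for c in self.clauses:
            mark = "PASS" if c.passed else "FAIL"
            lines.append(f"  [{mark}] {c.name}" + (f" — {c.detail}" if c.detail else ""))
        return "\n".join(lines)


def validate_contract(definition: ModelDefinition, *,
                      probe_times: Sequence[float] | None = None) -> ContractReport:
    """Exercise a model definition against the plugin contract.

    Checks, in order: simulate runs on a probe grid with mid-range
    parameters; output length matches the grid; outputs are finite; and, if
    the model ships its own estimator, that estimates on self-simulated data
    respect the declared bounds.  Failures become report entries, never
    exceptions.
    """
    clauses: list[ContractClause] = []
    t = np.asarray(
        probe_times if probe_times is not None else np.linspace(0.0, 10.0, 21),
        dtype=float,
    )
    params = definition.probe_params()

    values = None
    try:
        raw = definition.simulate_fn(params, t)
        values = np.asarray(raw, dtype=float)
        clauses.append(ContractClause("simulate_runs", True))
    except Exception as exc:  # report, don't raise
        clauses.append(ContractClause("simulate_runs", False, repr(exc)))

    if values is not None:
        ok_len = values.shape == t.shape
        clauses.append(
            ContractClause(
                "simulate_length",
                ok_len,
                "" if ok_len else f"returned {values.shape} for {t.shape} times",
            )
        )
        finite = bool(np.all(np.isfinite(values)))
        clauses.append(
            ContractClause(
                "simulate_finite",
                finite,
                "" if finite else "non-finite values in simulated curve",
            )
        )

    if definition.estimate_fn is None:
        clauses.append(
            ContractClause(
                "estimate_within_bounds", True, "generic estimator (no estimate_fn)"
            )
        )
    elif values is not None and values.shape == t.shape:
        from .core import TimeSeries

        try:
            data = TimeSeries(t, values, name="contract-probe")
            result = definition.estimate_fn(data, list(definition.parameters), None)
            bad = [
                name
                for spec in definition.parameters
                for name in [spec.name]
                if not (
                    spec.lower - 1e-12
                    <= result.estimates[name]
                    <= spec.upper + 1e-12
                )
            ]
            clauses.append(
                ContractClause(
                    "estimate_within_bounds",
                    not bad,
                    "" if not bad else f"out of range: {bad}",
                )
            )
        except Exception as exc:
            clauses.append(ContractClause("estimate_within_bounds", False, repr(exc)))
    else:
        clauses.append(
            ContractClause(
                "estimate_within_bounds", False, "simulate failed; estimator not probed"
            )
        )

    return ContractReport(definition.model_id, tuple(clauses))
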