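"""Built-in growth models: closed-form sigmoids, tumor models, and baselines.

Each model is a parameter dataclass plus a vectorized value function
``<model>_value(params, t)``; the Live Cell Fraction model is an ODE and
exposes ``lcf_simulate`` instead.  All sigmoids use the Zwietering-style
reparameterization in (A, mu_max, lambda) so the fitted numbers are the
quantities microbiologists report: asymptotic maximum A, maximum specific
growth rate mu_max, and lag time lambda.

Numerical conventions
---------------------
* Every exp() argument is clamped to +/-700 (``EXP_CLAMP``) so extreme
  parameter/time combinations saturate at the model's asymptote instead of
  overflowing.
* The Baranyi correction term is evaluated with log-sum-exp so it is stable
  arbitrarily deep into stationary phase.
* ODE integration uses an adaptive Runge-Kutta solver at rtol=1e-8,
  atol=1e-10 by default — tight enough that fitting error dominates solver
  error; both are overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import Curve, DomainError, IntegrationError, ValidationError

#: exp() argument clamp; exp(700) ~ 1e304 is still a finite float64.
EXP_CLAMP = 700.0


def _cexp(x):
    """exp with the argument clamped to +/-EXP_CLAMP."""
    return np.exp(np.clip(x, -EXP_CLAMP, EXP_CLAMP))


class _ParamBase:
    """Validation shared by all parameter dataclasses."""

    def validate(self) -> None:
        problems = self._invariant_violations()
        if problems:
            raise ValidationError(
                f"invalid {type(self).__name__}: " + "; ".join(problems)
            )

    def _invariant_violations(self) -> list[str]:  # pragma: no cover - abstract
        return []

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class GompertzParams(_ParamBase):
    A: float          # asymptotic maximum (signal units)
    mu_max: float     # maximum specific growth rate (1/time)
    lambda_: float    # lag time (time units); may be 0 or negative

    def _invariant_violations(self):
        out = []
        if not self.A > 0:
            out.append(f"A must be > 0 (got {self.A})")
        if not self.mu_max > 0:
            out.append(f"mu_max must be > 0 (got {self.mu_max})")
        if not np.isfinite(self.lambda_):
            out.append("lambda_ must be finite")
        return out


@dataclass(frozen=True)
class LogisticParams(_ParamBase):
    A: float
    mu_max: float
    lambda_: float

    def _invariant_violations(self):
        out = []
        if not self.A > 0:
            out.append(f"A must be > 0 (got {self.A})")
        if not self.mu_max > 0:
            out.append(f"mu_max must be > 0 (got {self.mu_max})")
        return out


@dataclass(frozen=True)
class RichardsParams(_ParamBase):
    A: float
    mu_max: float
    lambda_: float
    v: float          # shape parameter; v=1 recovers the logistic

    def _invariant_violations(self):
        out = []
        if not self.A > 0:
            out.append(f"A must be > 0 (got {self.A})")
        if not self.mu_max > 0:
            out.append(f"mu_max must be > 0 (got {self.mu_max})")
        if not self.v > 0:
            out.append(f"v must be > 0 (got {self.v})")
        return out


@dataclass(frozen=True)
class BaranyiParams(_ParamBase):
    """Baranyi-Roberts model with explicit adaptation function.

    y is log-population; h0 encodes the initial physiological state (lag is
    roughly h0 / v_rate), m_curv the curvature of the approach to stationary
    phase (m_curv=1 gives the logistic-type transition).
    """

    y0: float         # initial log-population
    y_max: float      # asymptotic log-population
    mu_max: float     # maximum specific growth rate (1/time)
    v_rate: float     # adaptation rate (1/time)
    h0: float         # initial physiological state (dimensionless)
    m_curv: float     # stationary-phase curvature (dimensionless)

    def _invariant_violations(self):
        out = []
        if not self.y_max > self.y0:
            out.append(f"y_max ({self.y_max}) must exceed y0 ({self.y0})")
        if not self.mu_max > 0:
            out.append(f"mu_max must be > 0 (got {self.mu_max})")
        if not self.v_rate > 0:
            out.append(f"v_rate must be > 0 (got {self.v_rate})")
        if not self.h0 >= 0:
            out.append(f"h0 must be >= 0 (got {self.h0})")
        if not self.m_curv > 0:
            out.append(f"m_curv must be > 0 (got {self.m_curv})")
        return out


@dataclass(frozen=True)
class H3Params(_ParamBase):
    """Hyperbolastic growth model of type III.

    P(t) = M - alpha * exp(-delta*t^gamma - arcsinh(theta*t)) with
    alpha = (M - P0) * exp(delta*t0^gamma + arcsinh(theta*t0)) recomputed
    from (M, P0, t0) so P(t0) = P0 holds identically.
    """

    M: float          # limiting size (signal units)
    delta: float      # rate coefficient (1/time^gamma)
    gamma: float      # time exponent (dimensionless)
    theta: float      # arcsinh rate (1/time)
    P0: float         # initial size at t0 (signal units)
    t0: float = 0.0   # initial time

    def _invariant_violations(self):
        out = []
        if not self.P0 > 0:
            out.append(f"P0 must be > 0 (got {self.P0})")
        if not self.M > self.P0:
            out.append(f"M ({self.M}) must exceed P0 ({self.P0})")
        if not self.gamma > 0:
            out.append(f"gamma must be > 0 (got {self.gamma})")
        if not self.theta >= 0:
            out.append(f"theta must be >= 0 (got {self.theta})")
        return out

    @property
    def alpha(self) -> float:
        """Derived amplitude; never stored independently of (M, P0, t0)."""
        return (self.M - self.P0) * float(
            _cexp(self.delta * self.t0 ** self.gamma + np.arcsinh(self.theta * self.t0))
        )


@dataclass(frozen=True)
class LiveCellFractionParams(_ParamBase):
    """Tumor-spheroid radius model: only a rim of depth lambda proliferates.

    dr/dt = r/3 * ( (alpha+delta) * 3*lambda / (3*lambda + r) - delta )
    has the stable fixed point r* = 3*lambda*alpha/delta.
    """

    alpha: float         # proliferation rate (1/time)
    delta: float         # death rate (1/time)
    lambda_depth: float  # viable-rim depth (length units)
    r0: float            # initial radius (length units)

    def _invariant_violations(self):
        out = []
        if not self.alpha > 0:
            out.append(f"alpha must be > 0 (got {self.alpha})")
        if not self.delta > 0:
            out.append(f"delta must be > 0 (got {self.delta})")
        if not self.lambda_depth > 0:
            out.append(f"lambda_depth must be > 0 (got {self.lambda_depth})")
        if not self.r0 > 0:
            out.append(f"r0 must be > 0 (got {self.r0})")
        return out

    @property
    def fixed_point(self) -> float:
        return 3.0 * self.lambda_depth * self.alpha / self.delta


@dataclass(frozen=True)
class PolynomialParams(_ParamBase):
    """First- or second-order polynomial, constant term first."""

    coefficients: tuple

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def _invariant_violations(self):
        if len(self.coefficients) not in (2, 3):
            return [f"need 2 or 3 coefficients, got {len(self.coefficients)}"]
        return []


@dataclass(frozen=True)
class ExpDecayParams(_ParamBase):
    y0: float   # initial value (signal units)
    k: float    # decay rate (1/time)
    c: float    # asymptotic offset (signal units)

    def _invariant_violations(self):
        if not self.k > 0:
            return [f"k must be > 0 (got {self.k})"]
        return []


# ---------------------------------------------------------------------------
# Value functions
# ---------------------------------------------------------------------------

def gompertz_value(p: GompertzParams, t):
    """Modified Gompertz: y(t) = A * exp(-exp((mu_max*e/A)*(lambda-t) + 1))."""
    p.validate()
    t = np.asarray(t, dtype=float)
    inner = _cexp((p.mu_max * np.e / p.A) * (p.lambda_ - t) + 1.0)
    return p.A * np.exp(-inner)


def logistic_value(p: LogisticParams, t):
    """Logistic: y(t) = A / (1 + exp(4*mu_max*(lambda-t)/A + 2))."""
    p.validate()
    t = np.asarray(t, dtype=float)
    return p.A / (1.0 + _cexp(4.0 * p.mu_max * (p.lambda_ - t) / p.A + 2.0))


def richards_value(p: RichardsParams, t):
    """Richards: A*[1 + v*exp(1+v)*exp((mu/A)*(1+v)^(1+1/v)*(lambda-t))]^(-1/v)."""
    p.validate()
    t = np.asarray(t, dtype=float)
    b = 1.0 + p.v
    expo = (p.mu_max / p.A) * b ** (1.0 + 1.0 / p.v) * (p.lambda_ - t)
    # v*exp(1+v)*exp(expo) merged into one clamped exponential
    bracket = 1.0 + p.v * _cexp(b + expo)
    return p.A * bracket ** (-1.0 / p.v)


def _baranyi_adjustment(t, mu_max, v_rate, h0, rate_scale):
    """Adaptation function A(t) = t + (1/rate_scale)*ln(e^-vt + e^-h0 - e^-vt-h0)."""
    evt = np.exp(-np.clip(v_rate * t, 0.0, EXP_CLAMP))
    arg = evt + np.exp(-h0) * (1.0 - evt)  # algebraically identical, stays in (0, 1]
    return t + np.log(arg) / rate_scale


def baranyi_value(p: BaranyiParams, t, *, classic: bool = False):
    """Baranyi-Roberts log-population curve.

    By default the adaptation function divides by mu_max; ``classic=True``
    uses the adaptation rate v_rate instead (the original formulation).
    The stationary-phase correction is computed via log-sum-exp:
    (1/m)*ln((1 - e^-D) + e^(m*mu*A(t) - D)) with D = m*(y_max - y0).
    """
    p.validate()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("baranyi_value requires t >= 0")
    rate_scale = p.v_rate if classic else p.mu_max
    a_t = _baranyi_adjustment(t, p.mu_max, p.v_rate, p.h0, rate_scale)
    d = p.m_curv * (p.y_max - p.y0)
    q = p.m_curv * p.mu_max * a_t
    log_a = np.log1p(-np.exp(-d)) if d < EXP_CLAMP else 0.0
    correction = np.logaddexp(log_a, q - d) / p.m_curv
    return p.y0 + p.mu_max * a_t - correction


def baranyi_classic_value(p: BaranyiParams, t):
    """Baranyi with the adaptation function scaled by 1/v_rate."""
    return baranyi_value(p, t, classic=True)


def h3_value(p: H3Params, t):
    """Hyperbolastic type III: P(t) = M - alpha*exp(-delta*t^gamma - arcsinh(theta*t))."""
    p.validate()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) and not float(p.gamma).is_integer():
        raise DomainError("h3_value: t < 0 undefined for non-integer gamma")
    return p.M - p.alpha * _cexp(-p.delta * t ** p.gamma - np.arcsinh(p.theta * t))


def polynomial_value(p: PolynomialParams, t):
    p.validate()
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c in reversed(p.coefficients):  # Horner, constant term first in storage
        out = out * t + c
    return out


def exp_decay_value(p: ExpDecayParams, t):
    """Exponential decay toward an offset: y(t) = c + (y0 - c)*exp(-k*t)."""
    p.validate()
    t = np.asarray(t, dtype=float)
    return p.c + (p.y0 - p.c) * _cexp(-p.k * t)


def lcf_rhs(t, r, alpha, delta, lambda_depth):
    """Right-hand side of the Live Cell Fraction radius ODE."""
    three_lambda = 3.0 * lambda_depth
    return r / 3.0 * ((alpha + delta) * three_lambda / (three_lambda + r) - delta)


def lcf_simulate(p: LiveCellFractionParams, times: Sequence[float], *,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 method: str = "RK45") -> Curve:
    """Integrate the Live Cell Fraction ODE from r(times[0]) = r0.

    times must be strictly increasing; the first entry is the
    initial-condition time.  Raises IntegrationError with the solver message
    if the adaptive stepper fails.
    """
    p.validate()
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("times must be strictly increasing")
    if t.size == 1:
        return Curve(t, np.array([p.r0]))
    sol = solve_ivp(
        lcf_rhs,
        (t[0], t[-1]),
        [p.r0],
        t_eval=t,
        args=(p.alpha, p.delta, p.lambda_depth),
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"LCF integration failed: {sol.message}")
    return Curve(t, sol.y[0])
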