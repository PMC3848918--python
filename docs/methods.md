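# Methods

## Models

The catalogue covers the standard sigmoid growth laws in the Zwietering
reparameterization — Gompertz, logistic and Richards in (A, μmax, λ[, v]) —
plus the Baranyi–Roberts model, the hyperbolastic type III (H3) tumor model,
the Live Cell Fraction (LCF) spheroid ODE, and three baselines (first/second
order polynomials, exponential decay toward an offset, chosen as
c + (y0 − c)e^(−kt)). Parameters are biologically interpretable throughout:
A is the asymptotic maximum signal, μmax the maximum specific growth rate
(1/time), λ the lag time (time units; zero or negative means no lag).

Two Baranyi variants are registered because the literature is ambiguous
about the scaling of the adaptation function
A(t) = t + (1/r)·ln(e^(−vt) + e^(−h0) − e^(−vt−h0)): `baranyi` uses
r = μmax, `baranyi_classic` uses r = v (the original formulation). They
coincide when v = μmax. A consequence worth knowing: the μmax-scaled
variant is *not* monotone when v > μmax — its initial slope is
1 − (v/μ)(1 − e^(−h0)), so the curve dips below y0 before growth starts.
The classic variant's initial slope is e^(−h0) ≥ 0 and it is monotone for
all valid parameters. The monotonicity property test is scoped accordingly.

H3 stores (M, δ, γ, θ, P0, t0) and always recomputes the amplitude
α = (M − P0)·exp(δ·t0^γ + arcsinh(θ·t0)), so P(t0) = P0 holds identically
rather than approximately. With θ = 0, γ = 1 the model degenerates to plain
exponential saturation; this is permitted, not special-cased. Negative
times with non-integer γ are a domain error.

The LCF ODE dr/dt = r/3·((α+δ)·3λ/(3λ+r) − δ) has the stable fixed point
r* = 3λα/δ; for r ≪ 3λ it reduces to exponential growth at rate α/3. Both
limits are exercised in tests.

## Numerical conventions

- Every exp() argument is clamped to ±700, so extreme parameter/time
  combinations saturate at the model's asymptote instead of overflowing
  (exp(700) is still a finite float64).
- The Baranyi stationary-phase correction is computed as
  (1/m)·logaddexp(log1p(−e^(−D)), q − D) with D = m(ymax − y0) and
  q = m·μmax·A(t), which is exact at t = 0 and stable arbitrarily deep into
  stationary phase.
- ODE integration uses adaptive Runge–Kutta (RK45) at rtol 1e-8,
  atol 1e-10, overridable per call; a solve at 100× tighter tolerance
  agrees within 1e-6 absolute over a 40-time-unit horizon, so solver error
  is far below any realistic fitting error. An LSODA integration serves as
  an independent cross-check in the tests.

## Estimation

The objective is the pooled sum of squared residuals between observations
and the simulated curve at the observation times, minimized over the box
defined by per-parameter search ranges with scipy's trust-region-reflective
`least_squares`. Design choices:

- **Multi-start.** Growth-model objectives are multi-modal, so the
  optimizer restarts from `n_starts` points (default 20): start 0 uses the
  default guesses (initial-condition parameters seeded from the first
  observation; a parameter named `t0` from the first time), the rest come
  from a Latin hypercube over the box seeded by `seed`. All starts in the
  budget are run; an optional early-stop cost threshold exists but is off
  by default, because an optimizer "success" at a local minimum must not
  end the search. The best successful start wins; cost ties (relative
  1e-12) resolve to the earlier start, making the fit a deterministic
  function of (data, specs, options) and immune to floating-point cost
  noise between equivalent optima.
- **Log-space internals.** A strictly positive range spanning more than
  half a decade is sampled log-uniformly and optimized in log10 space.
  This matters for rate coefficients that multiply a power of time: in the
  H3 model, δ and γ trade off along the valley ln δ + γ·ln t ≈ const,
  which is straight in (log δ, γ) but exponentially curved in (δ, γ);
  linear-space optimization stalls partway down that valley.
- **Scale.** Residuals are computed on the raw signal scale by default; a
  `scale="log"` option fits ln-residuals instead (microbiology practice
  varies). Reported RMSE is always on the raw scale, with denominator n —
  it is a cross-model comparison baseline, not an unbiased variance
  estimate, so no degrees-of-freedom correction is applied.
- **Constraints and pinning.** Estimates can never leave their box (the
  optimizer is interior; a one-ulp log-round-trip overshoot is clipped).
  Any parameter can be pinned to a fixed value via `FitOptions.pin`; the
  natural use is pinning H3's t0 to the first observation time.
- **Degenerate input.** Non-finite values are rejected at container
  construction; constant series and series with fewer points than free
  parameters are estimation errors, not silent misfits. Parameter vectors
  inside the box that are nonetheless invalid (e.g. y0 ≥ ymax in a Baranyi
  box that allows overlap) or that break the ODE solver yield a large
  penalty residual instead of an exception, steering the optimizer away.
- **Tolerances.** ftol = xtol = gtol = 1e-12 by default. This is tight
  enough that a first-order polynomial fit agrees with the closed-form OLS
  solution to ~1e-12 from the default start.

`compare_models` derives each candidate's seed deterministically from the
base seed and the model id (CRC32), so the comparison table is invariant to
candidate order; per-model failures become flagged rows rather than
aborting the table. Non-converged fits sort after converged ones.
`fit_aggregate` pools replicates by concatenating residuals, i.e. weights
replicates by point count; an equal-weight scheme was considered and
rejected because the pooled sum of squares is the natural "average model"
objective and the only one that makes the single-replicate case an exact
identity.

The manual log-linear regression (ln value vs time on a user window) uses
ordinary least squares; its slope is the specific growth rate. r² is
defined as 1 when the window is fitted exactly (including constant data).

## Synthetic data

The `fixtures` module is the only data source used by tests and examples.
It simulates a truth parameter set on a dense grid and applies one of two
noise models per replicate: additive Gaussian (plate-reader style signal
noise) or multiplicative lognormal value·exp(N(0, σ²)), which preserves
positivity for log-scale fitting. Noise is applied to values only, never
times; replicate draws come from independent substreams spawned from the
seed, so generation is bit-reproducible.

Default scenarios fix the study conditions: OD-like sigmoids over 48 h
sampled every 0.5 h (97 points) with σ = 0.02; a Baranyi log-CFU curve
(y0 = 2, ymax = 9) over 24 h; a tumor-weight H3 series at the reported fit
(M = 7.547 g, δ = 5.103e-9, γ = 4.630, θ = 0.004) with P0 = 0.2 g at
t0 = 0 over 80 d and σ = 0.066 (the reported residual level); an LCF
radius series (α = 0.2, δ = 0.05, λ = 1, r0 = 0.5) over 40 time units.
These sizes keep the full test suite and the acceptance script at around
half a minute on one CPU while leaving every estimate's sampling error well
inside the asserted tolerances.

What the generator does *not* emulate: plate-reader artifacts such as
evaporation drift, edge effects, heteroscedastic noise, or calibration
nonlinearity. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise models, not robustness to instrument
systematics.

The tumor-growth benchmark deserves emphasis: the real weight series of the
solid Ehrlich carcinoma experiment is not distributed with this package, so
the benchmark dataset is **synthetic** — generated from the published fit
parameters at the published residual level — and the test checks that the
full pipeline refits those parameters to within the uncertainty that noise
level implies (≤10 % on M and γ, RMSE within 25 % of 0.066). It validates
the estimation machinery end to end, not agreement with the original
measurements.

## Data store

Persistence is plain files (CSV for measurements, JSON for metadata and fit
results) in a directory tree mirroring project → experiment → measurement;
there is no database. Floats are written with `repr`, so save/load and
import/export round-trips are bit-exact. Measurement CSVs may carry a third
numeric column and a free-text annotation; both are stored verbatim and
proven inert to fitting by test. Duplicate time points are rejected on
import — replicates belong in separate measurements, which is what the
pooled fit consumes. The delimiter is auto-detected among comma, semicolon
and tab; the decimal separator is always ".".

## Plugin contract

A model is a `ModelDefinition`: id, display metadata, ordered parameter
specs with default search ranges (shipped in `data/model_ranges.yaml`), a
`simulate_fn(params, times) -> values`, and optionally its own
`estimate_fn`; models without one are fitted by the generic estimator. The
contract is in-process by design — a transport layer could wrap the same
two functions without changing any signature. `validate_contract` probes a
definition on a mid-range parameter set and reports per-clause pass/fail
(simulate runs, output length, finiteness, estimates within bounds) instead
of raising.

## Known limitations

- No parameter uncertainty: confidence intervals and bootstrap are out of
  scope; RMSE ranking is the only model-selection criterion (no AIC/BIC).
- RMSE with denominator n mildly favors models with more parameters on
  small n; this is deliberate and documented above.
- The printed-form Baranyi variant can be non-monotone (see Models); users
  fitting lag-dominated data should prefer `baranyi_classic` if
  monotonicity is a modeling requirement.
- Weighted or heteroscedastic regression is not supported.
- Time stamps are arbitrary reals; no date/unit handling.
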