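# growthfit

Management and automated fitting of biological growth curves.

Microbiologists routinely need the lag time λ, the maximum specific growth
rate μ<sub>max</sub> and the asymptotic maximum *A* of an optical-density
growth curve; oncologists need limiting tumor size and growth kinetics from
weight or radius series. `growthfit` is a desk-scale toolkit for exactly
that workflow: organize measurements into projects and experiments, fit any
model from an extensible catalogue with bounded multi-start nonlinear least
squares, compare candidate models by RMSE, pool replicates into a single
average fit, and export everything as CSV.

## Model catalogue

All sigmoids use the (A, μ<sub>max</sub>, λ) reparameterization so the
fitted numbers are directly the quantities reported in growth studies:

| id | model |
|----|-------|
| `gompertz` | y(t) = A·exp(−exp((μ<sub>max</sub>·e/A)(λ−t) + 1)) |
| `logistic` | y(t) = A / (1 + exp(4μ<sub>max</sub>(λ−t)/A + 2)) |
| `richards` | y(t) = A·[1 + v·e<sup>1+v</sup>·exp((μ<sub>max</sub>/A)(1+v)<sup>1+1/v</sup>(λ−t))]<sup>−1/v</sup> |
| `baranyi`, `baranyi_classic` | y(t) = y₀ + μ<sub>max</sub>A(t) − (1/m)·ln(1 + (e<sup>m·μmax·A(t)</sup> − 1)/e<sup>m(ymax−y0)</sup>) with adaptation A(t); the two variants scale A(t) by 1/μ<sub>max</sub> and 1/v respectively |
| `h3` | hyperbolastic type III: P(t) = M − α·exp(−δt<sup>γ</sup> − arcsinh(θt)), α = (M−P₀)·exp(δt₀<sup>γ</sup> + arcsinh(θt₀)) |
| `lcf` | Live Cell Fraction spheroid ODE: dr/dt = r/3·((α+δ)·3λ/(3λ+r) − δ), fixed point r* = 3λα/δ |
| `poly1`, `poly2`, `exp_decay` | baselines: linear/quadratic regression, c + (y₀−c)e<sup>−kt</sup> |

The estimator is generic: any model exposing the two-function contract
(*simulate* a curve from parameters; optionally *estimate* parameters from
data) can be registered and immediately participates in fitting, comparison
and the CLI. Fitting minimizes the sum of squared residuals over the
user-supplied per-parameter search box (trust-region-reflective least
squares) from Latin-hypercube multi-starts; the search is a deterministic
function of the seed.

## Worked example

Generate a noisy Gompertz curve (A=1, μ<sub>max</sub>=0.2 h⁻¹, λ=5 h,
σ=0.02 OD) and fit it back:

```bash
growthfit generate --model gompertz --noise 0.02 --out-dir data --seed 1
growthfit fit --model gompertz --input data/gompertz_rep1.csv --ranges ranges.yaml
```

with `ranges.yaml`:

```yaml
n_starts: 10
seed: 1
parameters:
  A:       {lower: 0.3, upper: 3.0}
  mu_max:  {lower: 0.05, upper: 0.8}
  lambda_: {lower: 0.5, upper: 20.0}
```

prints

```
                   Growth Curve Fit Results
==============================================================
Model:        gompertz            N points:   97
Datasets:     1                   Converged:  True
Scale:        raw                 Starts:     10
Seed:         1                   RMSE:       0.0190449
--------------------------------------------------------------
parameter                 estimate
A                       0.99856677
mu_max                  0.20021667
lambda_                  5.0368168
==============================================================
Note: RMSE denominator is n (no degrees-of-freedom correction).
```

The estimates recover the generating parameters to well under 2 % and the
RMSE (0.019) sits at the injected noise level (0.02). Comparing models on
the same curve ranks them by fit quality:

```bash
growthfit compare --input data/gompertz_rep1.csv -m gompertz -m logistic -m poly1 --starts 8 --seed 1
```

```
model                       rmse   converged
--------------------------------------------
gompertz               0.0190449        True
logistic               0.0227156        True
poly1                   0.238602        True
```

The same operations are available as a library, statsmodels-style:

```python
from growthfit import GrowthCurveModel, FitOptions
model = GrowthCurveModel(series, model="gompertz", specs=my_ranges)
result = model.fit(FitOptions(n_starts=10, seed=1))
print(result.summary())        # estimates, RMSE, convergence
curve = result.predict([0, 6, 12, 24])
```

Replicates pool into one fit with `fit_aggregate` /
`growthfit fit-experiment`, and the `datastore` module persists a
project → experiment → measurement hierarchy with lossless CSV/JSON
round-trips.

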