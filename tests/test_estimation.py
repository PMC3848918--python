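"""Estimation: RMSE, bounded multi-start fitting, pooling, model comparison."""

import numpy as np
import pytest

from growthfit import (
    DomainError,
    EstimationError,
    FitOptions,
    GrowthCurveModel,
    ParameterSpec,
    TimeSeries,
    ValidationError,
    compare_models,
    fit_aggregate,
    fit_model,
    manual_log_regression,
    rmse,
)
from growthfit.fixtures import GenerationSpec, default_spec, generate_curve


def specs_around(registry, model_id, truth, span=10.0, skip=()):
    """Search ranges spanning ``span``-fold around the generating truth."""
    out = []
    for s in registry.get(model_id).parameters:
        if s.name in skip or truth.get(s.name) in (None,):
            out.append(s)
        elif truth[s.name] == 0:
            out.append(s)
        else:
            out.append(s.scaled_around(truth[s.name], span))
    return out


def noiseless(model_id, seed=0):
    spec = default_spec(model_id, seed=seed)
    (ts,), _ = generate_curve(spec)
    return ts, spec.truth


class TestRmse:
    def test_identical_sequences_give_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_symmetric_unit_residuals(self):
        assert rmse([1.0, 3.0], [2.0, 2.0]) == pytest.approx(1.0)

    def test_single_residual_denominator_is_n(self):
        assert rmse([0.0, 0.0, 0.0], [3.0, 0.0, 0.0]) == pytest.approx(np.sqrt(3.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rmse([1.0], [1.0, 2.0])


class TestManualLogRegression:
    def test_exact_exponential_recovers_rate(self):
        t = np.linspace(0.0, 10.0, 21)
        ts = TimeSeries(t, 0.05 * np.exp(0.3 * t))
        fit = manual_log_regression(ts, (0.0, 10.0))
        assert fit.slope == pytest.approx(0.3, rel=1e-12)
        assert fit.intercept == pytest.approx(np.log(0.05), rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_data_has_zero_slope(self):
        ts = TimeSeries(np.arange(5.0), np.full(5, 2.5))
        fit = manual_log_regression(ts, (0.0, 4.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_matches_closed_form_ols_on_noisy_data(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 5.0, 20)
        lny = np.log(0.1) + 0.4 * t + rng.normal(0.0, 0.01, 20)
        ts = TimeSeries(t, np.exp(lny))
        fit = manual_log_regression(ts, (0.0, 5.0))
        # independent closed-form OLS on the same transformed points
        tbar, ybar = t.mean(), lny.mean()
        slope = np.sum((t - tbar) * (lny - ybar)) / np.sum((t - tbar) ** 2)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(ybar - slope * tbar, abs=1e-12)

    def test_window_restricts_the_fit(self):
        t = np.arange(0.0, 10.0)
        v = np.where(t < 5, np.exp(0.5 * t), np.exp(2.5) * np.exp(0.1 * (t - 5)))
        fit = manual_log_regression(TimeSeries(t, v), (0.0, 4.0))
        assert fit.slope == pytest.approx(0.5, rel=1e-10)

    def test_nonpositive_values_name_offending_rows(self):
        ts = TimeSeries([0.0, 1.0, 2.0], [1.0, -0.5, 2.0])
        with pytest.raises(DomainError, match="t=1"):
            manual_log_regression(ts, (0.0, 2.0))

    def test_too_few_points_in_window(self):
        ts = TimeSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            manual_log_regression(ts, (0.4, 0.6))


class TestFitModel:
    def test_line_through_two_points_is_exact(self):
        res = fit_model("poly1", TimeSeries([0.0, 2.0], [1.0, 5.0]),
                        options=FitOptions(n_starts=3))
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.estimates["c0"] == pytest.approx(1.0, abs=1e-9)
        assert res.estimates["c1"] == pytest.approx(2.0, abs=1e-9)

    def test_first_order_polynomial_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 10.0, 30)
        y = 0.4 + 0.3 * t + rng.normal(0.0, 0.1, 30)
        res = fit_model("poly1", TimeSeries(t, y), options=FitOptions(n_starts=10, seed=1))
        c1, c0 = np.polyfit(t, y, 1)
        assert res.estimates["c0"] == pytest.approx(c0, abs=1e-10)
        assert res.estimates["c1"] == pytest.approx(c1, abs=1e-10)

    def test_noiseless_gompertz_recovery_within_one_percent(self, registry):
        ts, truth = noiseless("gompertz")
        specs = specs_around(registry, "gompertz", truth)
        res = fit_model("gompertz", ts, specs, FitOptions(n_starts=10, seed=2))
        assert res.converged
        for name, value in truth.items():
            assert res.estimates[name] == pytest.approx(value, rel=0.01)

    def test_noiseless_lcf_recovery_within_five_percent(self, registry):
        ts, truth = noiseless("lcf")
        specs = specs_around(registry, "lcf", truth)
        res = fit_model("lcf", ts, specs, FitOptions(n_starts=20, seed=3))
        assert res.converged
        for name in ("alpha", "delta", "lambda_depth"):
            assert res.estimates[name] == pytest.approx(truth[name], rel=0.05)

    def test_rmse_equals_independent_recomputation(self, registry):
        spec = default_spec("gompertz", noise=True, seed=9)
        (ts,), _ = generate_curve(spec)
        res = fit_model("gompertz", ts, specs_around(registry, "gompertz", spec.truth),
                        FitOptions(n_starts=5, seed=4))
        assert res.rmse == rmse(ts.values, res.fitted_curve.values)

    def test_identical_inputs_and_seed_give_identical_results(self, registry):
        spec = default_spec("gompertz", noise=True, seed=12)
        (ts,), _ = generate_curve(spec)
        specs = specs_around(registry, "gompertz", spec.truth)
        opts = FitOptions(n_starts=8, seed=77)
        a = fit_model("gompertz", ts, specs, opts)
        b = fit_model("gompertz", ts, specs, opts)
        assert a == b
        assert np.array_equal(a.fitted_curve.values, b.fitted_curve.values)

    def test_estimates_respect_bounds_when_truth_sits_on_boundary(self):
        ts, truth = noiseless("gompertz")
        # box whose upper A edge equals the true asymptote
        specs = [
            ParameterSpec("A", 0.2, 1.0),
            ParameterSpec("mu_max", 0.02, 2.0),
            ParameterSpec("lambda_", 0.5, 50.0),
        ]
        res = fit_model("gompertz", ts, specs, FitOptions(n_starts=8, seed=5))
        for s in specs:
            assert s.lower <= res.estimates[s.name] <= s.upper

    def test_pinned_parameters_are_fixed_and_reported(self, registry):
        ts, truth = noiseless("h3")
        specs = specs_around(registry, "h3", truth, skip=("t0",))
        res = fit_model("h3", ts, specs,
                        FitOptions(n_starts=10, seed=6, pin={"t0": 0.0}))
        assert res.estimates["t0"] == 0.0
        assert res.estimates["M"] == pytest.approx(truth["M"], rel=0.01)

    def test_log_scale_fit_recovers_exponential_phase_model(self, registry):
        ts, truth = noiseless("baranyi")
        specs = specs_around(registry, "baranyi", truth)
        res = fit_model("baranyi", ts, specs,
                        FitOptions(n_starts=10, seed=8, scale="log"))
        assert res.converged
        assert res.estimates["mu_max"] == pytest.approx(truth["mu_max"], rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(EstimationError, match="points"):
            fit_model("gompertz", TimeSeries([0.0, 1.0], [0.1, 0.2]))

    def test_constant_data_rejected(self):
        with pytest.raises(EstimationError, match="degenerate"):
            fit_model("poly1", TimeSeries(np.arange(5.0), np.full(5, 1.0)))

    def test_log_scale_requires_positive_observations(self):
        ts = TimeSeries(np.arange(5.0), [1.0, 2.0, -0.1, 3.0, 4.0])
        with pytest.raises(EstimationError, match="positive"):
            fit_model("poly1", ts, options=FitOptions(scale="log"))

    def test_specs_must_cover_parameters_exactly(self):
        ts, _ = noiseless("gompertz")
        with pytest.raises(ValidationError, match="missing"):
            GrowthCurveModel(ts, "gompertz", [ParameterSpec("A", 0.1, 2.0)])


class TestAggregate:
    def test_single_dataset_pooling_identity(self, registry):
        ts, truth = noiseless("gompertz")
        specs = specs_around(registry, "gompertz", truth)
        opts = FitOptions(n_starts=6, seed=11)
        single = fit_model("gompertz", ts, specs, opts)
        pooled = fit_aggregate("gompertz", [ts], specs, opts)
        assert pooled.estimates == single.estimates
        assert pooled.rmse == single.rmse

    def test_three_noiseless_replicates_recover_truth(self, registry):
        spec = default_spec("gompertz", n_replicates=3)
        replicates, _ = generate_curve(spec)
        specs = specs_around(registry, "gompertz", spec.truth)
        res = fit_aggregate("gompertz", replicates, specs, FitOptions(n_starts=6, seed=13))
        for name, value in spec.truth.items():
            assert res.estimates[name] == pytest.approx(value, rel=0.01)
        assert res.n_points == 3 * len(replicates[0])

    def test_pooled_asymptote_lies_between_replicate_truths(self, registry):
        base = {"mu_max": 0.2, "lambda_": 5.0}
        reps = []
        for a in (1.0, 1.2):
            spec = GenerationSpec("gompertz", {"A": a, **base}, (0.0, 48.0, 0.5))
            (ts,), _ = generate_curve(spec)
            reps.append(ts)
        specs = specs_around(registry, "gompertz", {"A": 1.1, **base})
        res = fit_aggregate("gompertz", reps, specs, FitOptions(n_starts=8, seed=17))
        assert 1.0 < res.estimates["A"] < 1.2

    def test_pooled_fit_matches_profile_grid_search_on_asymptote(self, registry):
        """Brute-force oracle: grid A, minimize pooled SSR over (mu, lambda)
        per grid point with Nelder-Mead, then compare the fitted A."""
        from scipy.optimize import minimize

        from growthfit.models import GompertzParams, gompertz_value

        base = {"mu_max": 0.2, "lambda_": 5.0}
        reps = []
        for a in (1.0, 1.2):
            spec = GenerationSpec("gompertz", {"A": a, **base}, (0.0, 48.0, 0.5))
            (ts,), _ = generate_curve(spec)
            reps.append(ts)
        t = reps[0].times
        obs = np.concatenate([r.values for r in reps])

        def pooled_ssr_at(a):
            def ssr(x):
                pred = gompertz_value(GompertzParams(a, x[0], x[1]), t)
                return float(np.sum((np.tile(pred, 2) - obs) ** 2))
            out = minimize(ssr, [0.2, 5.0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            return out.fun

        grid = np.arange(1.0, 1.2001, 0.002)
        ssr_grid = [pooled_ssr_at(a) for a in grid]
        a_grid = grid[int(np.argmin(ssr_grid))]

        specs = specs_around(registry, "gompertz", {"A": 1.1, **base})
        res = fit_aggregate("gompertz", reps, specs, FitOptions(n_starts=8, seed=19))
        assert abs(res.estimates["A"] - a_grid) <= 0.002


class TestCompareModels:
    def test_sigmoid_data_ranks_gompertz_above_line(self, registry):
        spec = default_spec("gompertz", noise=True, seed=21)
        (ts,), _ = generate_curve(spec)
        specs = specs_around(registry, "gompertz", spec.truth)
        table = compare_models(ts, [("gompertz", specs), ("poly1", None)],
                               FitOptions(n_starts=6, seed=23))
        assert table.best.model_id == "gompertz"
        rmses = [row.result.rmse for row in table if row.ok]
        assert rmses == sorted(rmses)

    def test_single_candidate_equals_fit_model(self, registry):
        ts, truth = noiseless("gompertz")
        specs = specs_around(registry, "gompertz", truth)
        table = compare_models(ts, [("gompertz", specs)], FitOptions(n_starts=5, seed=29))
        assert len(table) == 1
        direct_seed = table.best.result.seed
        direct = fit_model("gompertz", ts, specs, FitOptions(n_starts=5, seed=direct_seed))
        assert table.best.result == direct

    def test_candidate_order_does_not_change_the_table(self, registry):
        spec = default_spec("gompertz", noise=True, seed=31)
        (ts,), _ = generate_curve(spec)
        specs = specs_around(registry, "gompertz", spec.truth)
        cands = [("gompertz", specs), ("poly1", None), ("poly2", None)]
        t1 = compare_models(ts, cands, FitOptions(n_starts=4, seed=37))
        t2 = compare_models(ts, cands[::-1], FitOptions(n_starts=4, seed=37))
        assert [r.model_id for r in t1] == [r.model_id for r in t2]
        for a, b in zip(t1, t2):
            assert a.result == b.result

    def test_per_model_failure_is_a_row_not_an_exception(self, registry):
        ts, truth = noiseless("gompertz")
        bad_specs = [ParameterSpec("A", 0.1, 2.0)]  # incomplete on purpose
        table = compare_models(ts, [("poly1", None), ("gompertz", bad_specs)])
        failed = [r for r in table if not r.ok]
        assert len(failed) == 1 and failed[0].model_id == "gompertz"
        assert table.rows[-1] is failed[0]

    def test_summary_and_dataframe_render(self, registry):
        ts, truth = noiseless("gompertz")
        specs = specs_around(registry, "gompertz", truth)
        res = fit_model("gompertz", ts, specs, FitOptions(n_starts=4, seed=41))
        text = res.summary()
        assert "gompertz" in text and "RMSE" in text
        table = compare_models(ts, [("gompertz", specs), ("poly1", None)],
                               FitOptions(n_starts=4, seed=43))
        df = table.to_dataframe()
        assert list(df["model_id"]) == [r.model_id for r in table]
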