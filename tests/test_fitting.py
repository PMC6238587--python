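"""Nonlinear fitting, runs-test model selection and model integration."""

import numpy as np
import pytest

from oxykin.fitting import (KineticRateRegressor, default_candidates,
                            fit_trace, integrate_model, runs_test,
                            select_model)
from oxykin.models import KineticParameters, ModelSpec, observed_rate
from oxykin.pipeline import analyze_trace
from oxykin.presets import ERO1A_PDI, ERO1B_PDI, ERV1P
from oxykin.preprocess import differentiate
from oxykin.simulate import SimulationConfig, simulate_trace
from oxykin.trace import AssayMetadata, OxygenTrace, RateSeries


class TestRunsTest:
    def test_alternating_signs_rejected(self):
        r = np.tile([1.0, -1.0], 50)
        assert runs_test(r) < 1e-6

    def test_two_runs_rejected(self):
        # 50 positive then 50 negative residuals: exact null probability of
        # observing <= 2 runs is 2/C(100,50) ~ 2e-29, far below any alpha
        r = np.concatenate([np.ones(50), -np.ones(50)])
        assert runs_test(r) < 1e-6

    def test_all_same_sign_returns_zero(self):
        assert runs_test(np.ones(30)) == 0.0

    def test_uniform_size_under_null(self):
        # rejection rate at the 5% level stays within a percent of nominal
        rng = np.random.default_rng(123)
        rejections = sum(runs_test(rng.standard_normal(200)) < 0.05
                         for _ in range(10_000))
        assert abs(rejections / 10_000 - 0.05) <= 0.01

    def test_agrees_with_statsmodels(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp
        rng = np.random.default_rng(5)
        r = rng.standard_normal(500)
        _, p_sm = runstest_1samp(r, cutoff=0, correction=False)
        assert runs_test(r) == pytest.approx(p_sm, abs=1e-9)

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            runs_test(np.ones(5))


def _pipeline_series(trace, **kw):
    from oxykin.preprocess import estimate_background, normalize_trace, \
        smooth_binomial
    proc = smooth_binomial(normalize_trace(trace), order=4, passes=25)
    return differentiate(proc), estimate_background(proc)


class TestFitTrace:
    def test_noise_free_recovery_within_a_tenth_percent(self, ero1a_clean_trace):
        # light smoothing: on noise-free data the kernel only distorts
        res = analyze_trace(ero1a_clean_trace, spec=ERO1A_PDI.spec,
                            normalize_method="none", smoothing_passes=1,
                            n_starts=3)
        truth = ERO1A_PDI.params
        for name in ("vmax", "km", "n", "k1", "k2"):
            fitted = getattr(res.params, name)
            assert fitted == pytest.approx(getattr(truth, name), rel=1e-3), name

    def test_noisy_vmax_within_three_stderr(self, ero1a_noisy_trace):
        res = analyze_trace(ero1a_noisy_trace, spec=ERO1A_PDI.spec, n_starts=3)
        assert res.converged
        se = res.stderrs["vmax"]
        assert se is not None and se > 0
        assert abs(res.params.vmax - ERO1A_PDI.params.vmax) < 3 * se

    def test_pure_background_flagged_no_signal(self):
        t = np.arange(0.0, 1200.0, 0.5)
        x = 2e-5
        oxy = 250.0 * np.exp(-x * t)
        tr = OxygenTrace(times=t, oxygen=oxy,
                         metadata=AssayMetadata(enzyme_conc=1.0,
                                                injection_time=240.0,
                                                sample_interval=0.5))
        series = differentiate(tr)
        res = fit_trace(series, ModelSpec("none"), x=x, n_starts=2)
        assert res.params.vmax < 1e-3 or "no enzymatic signal" in res.flags
        assert "no enzymatic signal" in res.flags

    def test_time_origin_shift_invariance(self, ero1b_noisy_trace):
        res = analyze_trace(ero1b_noisy_trace, spec=ERO1B_PDI.spec, n_starts=2)
        shifted = OxygenTrace(
            times=ero1b_noisy_trace.times + 100.0,
            oxygen=ero1b_noisy_trace.oxygen.copy(),
            metadata=AssayMetadata(
                enzyme_conc=1.0, injection_time=340.0, sample_interval=0.1))
        res2 = analyze_trace(shifted, spec=ERO1B_PDI.spec, n_starts=2)
        for name in ("vmax", "km", "n", "k1"):
            assert getattr(res2.params, name) == pytest.approx(
                getattr(res.params, name), rel=1e-3), name

    def test_regressor_sklearn_contract(self):
        from sklearn.base import clone
        reg = KineticRateRegressor(activation="one_step", n_starts=2)
        params = reg.get_params()
        assert params["activation"] == "one_step"
        clone(reg)  # get_params/set_params round trip
        with pytest.raises(Exception):
            reg.predict(np.zeros((3, 2)))  # not fitted yet


class TestSelectModel:
    def test_one_step_data_selects_one_step(self, ero1b_noisy_trace):
        res = analyze_trace(ero1b_noisy_trace, n_starts=3)
        assert res.spec.activation == "one_step"
        assert not res.spec.inactivation
        assert res.runs_test_p > 0.05

    def test_no_lag_enzyme_fits_hill_coefficient_of_one(self, erv1p_noisy_trace):
        res = analyze_trace(erv1p_noisy_trace, spec=ERV1P.spec, n_starts=3)
        assert res.params.n == pytest.approx(1.0, abs=0.15)
        assert res.params.km == pytest.approx(89.0, rel=0.15)

    def test_hill_fixed_on_cooperative_data_fails_runs_test(self):
        cfg = SimulationConfig(params=ERO1A_PDI.params, spec=ERO1A_PDI.spec,
                               total_duration=2800.0, noise_sd=0.2, seed=21)
        res = analyze_trace(simulate_trace(cfg),
                            spec=ModelSpec("two_step", hill_fixed_to_one=True),
                            n_starts=3)
        assert res.runs_test_p < 0.05

    def test_empty_candidate_list_rejected(self, ero1b_noisy_trace):
        series, x = _pipeline_series(ero1b_noisy_trace)
        with pytest.raises(ValueError, match="empty"):
            select_model(series, candidates=[], x=x)

    def test_generating_model_wins_aic_on_one_step_data(self):
        wins = 0
        for seed in range(1, 7):
            cfg = SimulationConfig(params=ERO1B_PDI.params, spec=ERO1B_PDI.spec,
                                   total_duration=1900.0, seed=seed)
            series, x = _pipeline_series(simulate_trace(cfg))
            one = fit_trace(series, ModelSpec("one_step"), x=x, n_starts=2,
                            random_state=seed)
            two = fit_trace(series, ModelSpec("two_step"), x=x, n_starts=2,
                            random_state=seed)
            wins += one.aic <= two.aic
        assert wins >= 5

    def test_candidate_ordering_simplest_first(self):
        cands = default_candidates()
        n_free = [c.n_kinetic_constants for c in cands]
        assert n_free == sorted(n_free)


class TestIntegrateModel:
    def test_background_only_exponential_decay(self):
        p = KineticParameters(vmax=0.0, km=5.0, n=1.0, x=1e-4, ti=0.0)
        t = np.linspace(0.0, 5000.0, 501)
        out = integrate_model(p, ModelSpec("none"), O2_start=250.0, t_span=t)
        np.testing.assert_allclose(out.oxygen, 250.0 * np.exp(-1e-4 * t),
                                   rtol=1e-6)

    def test_michaelis_menten_implicit_progress_curve(self):
        # x=0, n=1, no lag: KM ln(S0/S) + (S0-S) = Vmax t along the solution
        vmax, km, S0 = 0.5, 20.0, 200.0
        p = KineticParameters(vmax=vmax, km=km, n=1.0, x=0.0, ti=0.0)
        t = np.linspace(0.0, 600.0, 301)
        out = integrate_model(p, ModelSpec("none"), O2_start=S0, t_span=t)
        S = np.clip(out.oxygen, 1e-9, None)
        lhs = km * np.log(S0 / S) + (S0 - S)
        np.testing.assert_allclose(lhs, vmax * t, rtol=1e-5, atol=1e-4)

    def test_output_monotone_non_increasing(self):
        p = ERO1A_PDI.params.replace(ti=0.0)
        t = np.linspace(0.0, 1500.0, 1501)
        out = integrate_model(p, ERO1A_PDI.spec, O2_start=250.0, t_span=t)
        assert np.all(np.diff(out.oxygen) <= 1e-12)
        assert np.all(out.oxygen >= 0.0)


class TestFitResultContract:
    def test_derived_quantities_recomputable(self, ero1b_noisy_trace):
        res = analyze_trace(ero1b_noisy_trace, spec=ERO1B_PDI.spec, n_starts=2)
        from oxykin.models import halftime_of_activation, kcat_from_vmax
        assert res.derived["kcat"] == pytest.approx(
            kcat_from_vmax(res.params.vmax, 1.0))
        assert res.derived["halftime"] == pytest.approx(
            halftime_of_activation(res.params, res.spec))
        assert res.n_points > 10 * len([k for k, v in res.stderrs.items()
                                        if v is not None])
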