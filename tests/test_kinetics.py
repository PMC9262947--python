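"""Sigmoid expression model: evaluation, derived quantities, fitting,
aggregation and the Welch test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from minwaves.kinetics import (
    FitDomainError,
    SigmoidExpressionModel,
    SigmoidFit,
    aggregate_replicates,
    derived_quantities,
    fit_kinetics_dataset,
    fit_sigmoid,
    sigmoid_eval,
    welch_t_test,
)
from minwaves.synth import KineticsSimParams, simulate_kinetics

params_strategy = st.tuples(
    st.floats(0.0, 2.0),       # k'
    st.floats(0.1, 10.0),      # k
    st.floats(5.0, 300.0),     # K
    st.floats(0.3, 10.0),      # n
)


class TestSigmoidEval:
    def test_half_max_at_K_and_offset_at_zero(self):
        assert sigmoid_eval(60.0, 0.2, 1.5, 60.0, 3.0) == pytest.approx(0.95)
        assert sigmoid_eval(0.0, 0.2, 1.5, 60.0, 3.0) == pytest.approx(0.2)

    def test_worked_value(self):
        assert sigmoid_eval(100.0, 0.0, 3.2, 100.0, 2.0) == pytest.approx(1.6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_eval(10.0, 0.0, 1.0, -5.0, 2.0)
        with pytest.raises(ValueError):
            sigmoid_eval(-1.0, 0.0, 1.0, 5.0, 2.0)

    @settings(deadline=None, max_examples=50)
    @given(params_strategy)
    def test_monotone_nondecreasing_in_time(self, p):
        k_prime, k, K, n = p
        t = np.linspace(0, 4 * K, 200)
        y = sigmoid_eval(t, k_prime, k, K, n)
        assert np.all(np.diff(y) >= -1e-12)


class TestDerivedQuantities:
    def test_plateau_and_rate_formulas(self):
        t_plateau, v = derived_quantities(k=3.2, K=100.0, n=2.0)
        assert t_plateau == pytest.approx(200.0)
        assert v == pytest.approx(0.016)

    def test_rate_equals_slope_at_half_rise(self):
        """kn/4K must equal the numerical dy/dt at t = K."""
        k_prime, k, K, n = 0.1, 2.5, 80.0, 3.3
        _, v = derived_quantities(k, K, n)
        h = 1e-5 * K
        slope = (
            sigmoid_eval(K + h, k_prime, k, K, n) - sigmoid_eval(K - h, k_prime, k, K, n)
        ) / (2 * h)
        assert v == pytest.approx(slope, rel=1e-6)

    @settings(deadline=None, max_examples=100)
    @given(params_strategy)
    def test_rate_identity_on_random_parameters(self, p):
        k_prime, k, K, n = p
        _, v = derived_quantities(k, K, n)
        h = 1e-6 * K
        slope = (
            sigmoid_eval(K + h, k_prime, k, K, n) - sigmoid_eval(K - h, k_prime, k, K, n)
        ) / (2 * h)
        assert v == pytest.approx(slope, rel=1e-5)


class TestFitSigmoid:
    def test_noiseless_curve_recovered(self):
        t = np.arange(0.0, 361.0, 30.0)
        y = sigmoid_eval(t, 0.0, 1.5, 60.0, 3.0)
        f = fit_sigmoid(t, y)
        assert f.converged
        assert f.k == pytest.approx(1.5, rel=1e-4)
        assert f.K == pytest.approx(60.0, rel=1e-4)
        assert f.n == pytest.approx(3.0, rel=1e-3)
        assert f.t_plateau == pytest.approx(2 * f.K / f.n + f.K)
        assert f.v_translation == pytest.approx(f.k * f.n / (4 * f.K))

    def test_constant_data_rejected(self):
        with pytest.raises(FitDomainError):
            fit_sigmoid(np.arange(8.0), np.full(8, 1.0))

    def test_decreasing_data_rejected(self):
        with pytest.raises(FitDomainError):
            fit_sigmoid(np.arange(8.0), np.linspace(5, 1, 8))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(FitDomainError):
            fit_sigmoid(np.array([0.0, 10, 20]), np.array([0.0, 1, 2]))

    def test_unit_coherence(self):
        """Scaling y scales k', k, v and leaves K, n; scaling t scales K and
        T_plateau and divides v."""
        t = np.arange(0.0, 361.0, 30.0)
        y = sigmoid_eval(t, 0.1, 1.5, 60.0, 3.0)
        base = fit_sigmoid(t, y)
        fy = fit_sigmoid(t, 4.0 * y)
        assert fy.k == pytest.approx(4 * base.k, rel=1e-3)
        assert fy.k_prime == pytest.approx(4 * base.k_prime, rel=1e-2, abs=1e-4)
        assert fy.K == pytest.approx(base.K, rel=1e-3)
        assert fy.n == pytest.approx(base.n, rel=1e-3)
        assert fy.v_translation == pytest.approx(4 * base.v_translation, rel=1e-3)
        ft = fit_sigmoid(2.0 * t, y)
        assert ft.K == pytest.approx(2 * base.K, rel=1e-3)
        assert ft.t_plateau == pytest.approx(2 * base.t_plateau, rel=1e-3)
        assert ft.v_translation == pytest.approx(base.v_translation / 2, rel=1e-3)

    def test_bias_vanishes_with_noise(self):
        t = np.linspace(0, 360, 13)
        errs = []
        for noise in (0.2, 0.02):
            ks = []
            for seed in range(20):
                y = sigmoid_eval(t, 0.0, 1.5, 60.0, 3.0)
                y = np.clip(y + np.random.default_rng(seed).normal(0, noise, t.shape), 0, None)
                ks.append(fit_sigmoid(t, y).k)
            errs.append(abs(np.mean(ks) - 1.5))
        assert errs[1] < errs[0]

    def test_estimator_api_round_trip(self):
        t = np.arange(0.0, 361.0, 30.0)
        y = sigmoid_eval(t, 0.0, 1.5, 60.0, 3.0)
        m = SigmoidExpressionModel().fit(t, y)
        np.testing.assert_allclose(m.predict(t), y, atol=1e-6)
        assert set(m.get_params()) == {"xtol", "max_nfev"}


class TestAggregateReplicates:
    def _fit(self, **kw) -> SigmoidFit:
        base = dict(
            k_prime=0.0, k=1.5, K=60.0, n=3.0, t_plateau=100.0,
            v_translation=0.016, rmse=0.01, converged=True,
        )
        base.update(kw)
        return SigmoidFit(**base)

    def test_identical_fits_have_zero_sd(self):
        agg = aggregate_replicates([self._fit()] * 3)
        assert agg.n_replicates == 3
        assert all(sd == 0 for sd in agg.sd.values())

    def test_mean_and_sample_sd(self):
        fits = [self._fit(v_translation=v) for v in (0.016, 0.018, 0.020)]
        agg = aggregate_replicates(fits)
        assert agg.mean["v_translation"] == pytest.approx(0.018)
        assert agg.sd["v_translation"] == pytest.approx(0.002)

    def test_single_fit_and_nonconverged_exclusion(self):
        good, bad = self._fit(), self._fit(converged=False, replicate="r2")
        agg = aggregate_replicates([good, bad])
        assert agg.n_replicates == 1
        assert agg.sd["k"] == 0.0
        assert agg.excluded == ["r2"]
        with pytest.raises(ValueError):
            aggregate_replicates([bad])


class TestWelch:
    def test_identical_samples_give_p_one(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_two_tailed == pytest.approx(1.0)
        assert not r.significant_at_0_05

    def test_separated_samples_agree_with_reference(self):
        a, b = [10, 11, 12, 13], [20, 21, 22, 23]
        r = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.t_stat == pytest.approx(ref.statistic)
        assert r.p_two_tailed == pytest.approx(ref.pvalue)
        assert r.p_two_tailed < 0.001 and r.significant_at_0_05

    def test_swapping_samples_flips_sign_only(self):
        r1 = welch_t_test([1.0, 2, 3, 5], [4.0, 6, 7, 9])
        r2 = welch_t_test([4.0, 6, 7, 9], [1.0, 2, 3, 5])
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestDatasetFitting:
    def test_generator_round_trip_per_replicate(self):
        params = KineticsSimParams(noise_sd_uM=0.0, n_replicates=2)
        fits, agg = fit_kinetics_dataset(simulate_kinetics(params))
        assert len(fits) == 2 * len(params.proteins)
        for protein, (k_prime, k, K, n) in params.proteins.items():
            assert agg[protein].mean["k"] == pytest.approx(k, rel=1e-3)
            assert agg[protein].mean["K"] == pytest.approx(K, rel=1e-3)
            assert agg[protein].sd["k"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            fit_kinetics_dataset(pd.DataFrame({"protein": [], "time_min": []}))
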