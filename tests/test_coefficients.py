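import numpy as np
import pytest

from mrtau import (
    DegenerateDataError,
    TrialArray,
    ValidationError,
    coefficients,
    rk_naive,
    rk_stationarymean,
    rk_trialseparated,
)


# ---------------------------------------------------------------------------
# brute-force oracles: literal double-loop evaluation of the estimators


def oracle_naive(trial, k):
    T = len(trial)
    x = [trial[t] for t in range(T - k)]
    y = [trial[t + k] for t in range(T - k)]
    xbar = sum(x) / len(x)
    ybar = sum(y) / len(y)
    num = sum((x[t] - xbar) * (y[t] - ybar) for t in range(T - k))
    den = sum((x[t] - xbar) ** 2 for t in range(T - k))
    return num / den


def oracle_trialseparated(values, k):
    return sum(oracle_naive(row, k) for row in values) / len(values)


def oracle_stationarymean(values, k):
    N, T = len(values), len(values[0])
    xbar = sum(values[i][t] for i in range(N) for t in range(T - k)) / (N * (T - k))
    ybar = sum(values[i][t + k] for i in range(N) for t in range(T - k)) / (N * (T - k))
    num = sum(
        (1.0 / (T - k))
        * sum((values[i][t] - xbar) * (values[i][t + k] - ybar) for t in range(T - k))
        for i in range(N)
    )
    den = sum(
        (1.0 / T) * sum((values[i][t] - xbar) ** 2 for t in range(T))
        for i in range(N)
    )
    return num / den


class TestHandComputedExamples:
    def test_perfect_ramp_has_unit_slope(self):
        assert rk_naive([0, 1, 2, 3], 1) == pytest.approx(1.0)

    def test_alternating_sequence_has_slope_minus_one(self):
        assert rk_naive([1, 0, 1, 0], 1) == pytest.approx(-1.0)

    def test_constant_trial_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rk_naive([5, 5, 5, 5], 1)

    def test_trialseparated_averages_per_trial_slopes(self):
        r, r_ik = rk_trialseparated(TrialArray(np.array([[0, 1, 2, 3], [1, 0, 1, 0]])), 1)
        np.testing.assert_allclose(r_ik, [1.0, -1.0])
        assert r == pytest.approx(0.0)

    def test_trialseparated_identical_trials_equal_single(self):
        single = rk_naive([0, 1, 2, 3], 1)
        r, _ = rk_trialseparated(TrialArray(np.array([[0, 1, 2, 3], [0, 1, 2, 3]])), 1)
        assert r == pytest.approx(single)

    def test_stationarymean_two_ramps(self):
        values = [[0, 1, 2, 3], [0, 1, 2, 3]]
        r = rk_stationarymean(TrialArray(np.array(values)), 1)
        assert r == pytest.approx(4.0 / 9.0)
        assert r == pytest.approx(oracle_stationarymean(values, 1))

    def test_degenerate_trial_named_in_error(self):
        values = np.array([[0.0, 1, 2, 3], [7.0, 7, 7, 7]])
        with pytest.raises(DegenerateDataError, match="trial 1"):
            rk_trialseparated(TrialArray(values), 1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_all_methods_match_double_loop_on_random_integers(self, rng, k):
        values = rng.integers(0, 20, size=(5, 20)).astype(float)
        ta = TrialArray(values)
        for i in range(5):
            assert rk_naive(values[i], k) == pytest.approx(
                oracle_naive(values[i].tolist(), k), rel=1e-12
            )
        r_ts, _ = rk_trialseparated(ta, k)
        assert r_ts == pytest.approx(oracle_trialseparated(values.tolist(), k), rel=1e-12)
        assert rk_stationarymean(ta, k) == pytest.approx(
            oracle_stationarymean(values.tolist(), k), rel=1e-12
        )

    def test_single_trial_stationarymean_close_to_naive(self, rng):
        # both reduce to the same regression up to the denominator's range
        trial = rng.poisson(50, size=5000).astype(float)
        for k in (1, 5, 20):
            a = rk_naive(trial, k)
            b = rk_stationarymean(TrialArray(trial.reshape(1, -1)), k)
            assert abs(a - b) < 5 * k / trial.size + 1e-3


class TestCoefficientsDriver:
    def test_step_range_and_metadata(self, subcritical_trials):
        rks = coefficients(
            subcritical_trials, method="trialseparated", steps=(1, 20),
            dt=1.0, dtunit="bp steps",
        )
        np.testing.assert_array_equal(rks.steps, np.arange(1, 21))
        assert rks.dtunit == "bp steps"
        assert rks.trial_coefficients.shape == (subcritical_trials.numtrials, 20)

    def test_explicit_steps_kept_in_order(self, subcritical_trials):
        rks = coefficients(subcritical_trials, method="sm", steps=np.array([1, 3, 5]))
        np.testing.assert_array_equal(rks.steps, [1, 3, 5])
        assert rks.trial_coefficients is None

    def test_kmax_beyond_trial_length_clips_with_warning(self):
        ta = TrialArray(np.random.default_rng(0).poisson(10, (3, 50)).astype(float))
        with pytest.warns(UserWarning, match="clip"):
            rks = coefficients(ta, method="ts", steps=(1, 200))
        assert rks.steps[-1] == 48

    def test_unknown_method_rejected(self, subcritical_trials):
        with pytest.raises(ValidationError, match="method"):
            coefficients(subcritical_trials, method="median")

    def test_numboot_zero_attaches_no_stderr(self, subcritical_trials):
        rks = coefficients(subcritical_trials, method="ts", steps=(1, 5), numboot=0)
        assert rks.stderrs is None and rks.bootstrap_samples is None

    @pytest.mark.parametrize("method", ["ts", "sm"])
    def test_bootstrap_is_seed_deterministic(self, method):
        ta = TrialArray(
            np.random.default_rng(3).poisson(20, (8, 200)).astype(float)
        )
        a = coefficients(ta, method=method, steps=(1, 10), numboot=25, seed=11)
        b = coefficients(ta, method=method, steps=(1, 10), numboot=25, seed=11)
        np.testing.assert_array_equal(a.bootstrap_samples, b.bootstrap_samples)
        assert a.stderrs.shape == (10,)

    def test_sm_bootstrap_replicates_match_direct_recomputation(self, rng):
        # the sufficient-statistic fast path must agree with re-running the
        # pooled estimator on the resampled trials
        values = rng.poisson(30, size=(6, 150)).astype(float)
        ta = TrialArray(values)
        rks = coefficients(ta, method="sm", steps=(1, 8), numboot=10, seed=21)
        resample_rng = np.random.default_rng(21)
        idx = resample_rng.integers(0, 6, size=(10, 6))
        for b in range(10):
            direct = [
                rk_stationarymean(TrialArray(values[idx[b]]), int(k)) for k in rks.steps
            ]
            np.testing.assert_allclose(rks.bootstrap_samples[b], direct, rtol=1e-10)

    def test_methods_agree_on_long_stationary_trials(self):
        from mrtau import BranchingConfig, simulate_branching

        ta = simulate_branching(
            BranchingConfig(m=0.8, target_activity=100, length=5000, numtrials=20, seed=77)
        )
        a = coefficients(ta, method="ts", steps=(1, 10))
        b = coefficients(ta, method="sm", steps=(1, 10))
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=0.02)
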