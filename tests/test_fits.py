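import numpy as np
import pytest

from mrtau import (
    CoefficientResult,
    ValidationError,
    evaluate_fitfunc,
    fit,
    get_fitfunc,
    m_from_tau,
    tau_from_m,
)

COMPLEX_TRUTH = dict(
    tau=50.0, D=0.5, O=0.05, tau_osc=80.0, E=0.2, gamma=1.2, nu=0.05,
    tau_gauss=30.0, F=0.1,
)


def make_coeffs(steps, rk, dt=1.0):
    steps = np.asarray(steps, dtype=int)
    return CoefficientResult(
        steps=steps, coefficients=np.asarray(rk, dtype=float),
        method="stationarymean", dt=dt, num_trials=0,
        trial_length=int(steps[-1]) + 2,
    )


class TestTimescaleConversion:
    def test_known_value_near_criticality(self):
        assert tau_from_m(0.98, 1.0) == pytest.approx(49.498, abs=1e-3)

    def test_log_cancellation(self):
        assert tau_from_m(np.exp(-1.0), 1.0) == pytest.approx(1.0)

    def test_scaling_with_dt(self):
        assert tau_from_m(0.5, 2.0) == pytest.approx(2.0 / np.log(2.0))

    @pytest.mark.parametrize("m", [0.1, 0.5, 0.9, 0.999])
    def test_round_trip(self, m):
        assert m_from_tau(tau_from_m(m, 1.0), 1.0) == pytest.approx(m, rel=1e-14)

    def test_m_approaches_one_for_large_tau(self):
        taus = np.array([1.0, 10.0, 1e3, 1e6])
        ms = np.array([m_from_tau(t, 1.0) for t in taus])
        assert np.all(np.diff(ms) > 0) and ms[-1] < 1.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.2])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            tau_from_m(bad, 1.0)
        with pytest.raises(ValidationError):
            m_from_tau(-1.0, 1.0)


class TestEvaluateFitfunc:
    def test_complex_at_lag_zero_sums_amplitudes_and_offset(self):
        p = COMPLEX_TRUTH
        value = evaluate_fitfunc("complex", 0.0, list(p.values()))
        assert value == pytest.approx(p["D"] + p["E"] + p["F"] + p["O"])

    def test_exponential_decays_by_e_at_one_timescale(self):
        assert evaluate_fitfunc("exp", 49.5, [49.5, 1.0]) == pytest.approx(np.exp(-1))

    def test_offset_model_with_zero_amplitude_is_flat(self):
        lags = np.arange(1, 10, dtype=float)
        out = evaluate_fitfunc("eo", lags, [10.0, 0.0, 0.3])
        np.testing.assert_allclose(out, 0.3)

    def test_abbreviations_resolve_to_same_model(self):
        assert get_fitfunc("e") is get_fitfunc("exponential") is get_fitfunc("exp")
        assert get_fitfunc("eo") is get_fitfunc("exp_off") is get_fitfunc("exp_offset")
        assert get_fitfunc("c") is get_fitfunc("cplx") is get_fitfunc("complex")

    def test_wrong_parameter_count_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_fitfunc("exp", 1.0, [1.0, 2.0, 3.0])


class TestExactRecovery:
    def test_exponential(self):
        steps = np.arange(1, 501)
        res = fit(make_coeffs(steps, 0.5 * np.exp(-steps / 100.0)), "exponential")
        assert res.tau == pytest.approx(100.0, rel=1e-6)
        assert res.params["A"] == pytest.approx(0.5, rel=1e-6)

    def test_exponential_offset(self):
        steps = np.arange(1, 501)
        rk = 0.3 * np.exp(-steps / 50.0) + 0.01
        res = fit(make_coeffs(steps, rk), "exponential_offset")
        assert res.tau == pytest.approx(50.0, rel=1e-6)
        assert res.params["A"] == pytest.approx(0.3, rel=1e-6)
        assert res.params["O"] == pytest.approx(0.01, rel=1e-6)

    def test_complex(self):
        steps = np.arange(1, 401)
        rk = evaluate_fitfunc("complex", steps.astype(float), list(COMPLEX_TRUTH.values()))
        res = fit(make_coeffs(steps, rk), "complex")
        for name, true in COMPLEX_TRUTH.items():
            assert res.params[name] == pytest.approx(true, rel=1e-6), name

    def test_derived_m_matches_timescale(self):
        steps = np.arange(1, 301)
        res = fit(make_coeffs(steps, 0.98**steps), "exponential")
        assert res.mre == pytest.approx(0.98, rel=1e-6)


class TestFitBehaviour:
    def test_offset_model_never_fits_worse_than_plain(self, rng):
        steps = np.arange(1, 201)
        rk = 0.4 * np.exp(-steps / 40.0) + 0.02 + rng.normal(0, 0.01, steps.size)
        c = make_coeffs(steps, rk)
        assert fit(c, "eo").ssres <= fit(c, "exp").ssres + 1e-12

    def test_oscillation_breaks_plain_exponential_but_not_complex(self):
        steps = np.arange(1, 401).astype(float)
        rk = 0.5 * np.exp(-steps / 50.0) + 0.4 * np.exp(-steps / 120.0) * np.cos(
            2 * np.pi * 0.02 * steps
        )
        c = make_coeffs(steps.astype(int), rk)
        plain = fit(c, "exponential")
        cplx = fit(c, "complex")
        assert abs(cplx.tau - 50.0) / 50.0 < 0.02
        assert abs(plain.tau - 50.0) / 50.0 > 0.10
        assert cplx.params["nu"] == pytest.approx(0.02, rel=0.05)

    def test_supercritical_data_reports_growth_not_negative_tau(self):
        steps = np.arange(1, 60)
        c = make_coeffs(steps, 1.02**steps)
        with pytest.warns(UserWarning, match="supercritical"):
            res = fit(c, "exponential")
        assert np.isnan(res.tau)
        assert res.mre > 1.0
        assert "supercritical" in res.warnings

    def test_fitrange_restricts_steps(self):
        steps = np.arange(1, 301)
        rk = 0.5 * np.exp(-steps / 60.0)
        res = fit(make_coeffs(steps, rk), "exp", fitrange=(10, 100))
        assert res.fitrange[0] == 10 and res.fitrange[-1] == 100
        assert res.tau == pytest.approx(60.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        c = make_coeffs([1, 2], [0.5, 0.4])
        with pytest.raises(ValidationError):
            fit(c, "exponential_offset")

    def test_ci_from_trial_coefficients_is_deterministic(self):
        rng = np.random.default_rng(42)
        steps = np.arange(1, 80)
        base = 0.6 * np.exp(-steps / 20.0)
        tc = base + rng.normal(0, 0.03, size=(12, steps.size))
        c = CoefficientResult(
            steps=steps, coefficients=tc.mean(axis=0), method="trialseparated",
            trial_coefficients=tc, dt=1.0, num_trials=12, trial_length=81,
        )
        r1 = fit(c, "exp", numboot=30, seed=9)
        r2 = fit(c, "exp", numboot=30, seed=9)
        assert r1.ci["tau"] == r2.ci["tau"]
        lo, hi = r1.ci["tau"]
        assert lo < r1.tau < hi
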