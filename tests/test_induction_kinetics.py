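"""Step-change splitting, sigmoid induction fits and W_i machinery."""

import dataclasses

import numpy as np
import pytest

from gasxkit.data_model import Protocol
from gasxkit.induction_kinetics import (
    fit_induction,
    sigmoid_response,
    split_step,
    steady_state_wi,
    wi_timecourse,
)
from gasxkit.synthetic_data import simulate_step_response

from conftest import make_series


def step_series(y0=0.05, yf=0.20, lam=60.0, k=100.0, noise=0.0, seed=0,
                t_step=300.0, t_end=2100.0, q_jitter=0.0, variable="gs"):
    """Hand-built step series whose chosen channel follows the sigmoid."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + 5.0, 10.0)
    n = len(t)
    Q = np.where(t < t_step, 100.0, 1000.0)
    if q_jitter:
        Q = Q + rng.uniform(-q_jitter, q_jitter, n)
    y = np.where(t < t_step, y0, sigmoid_response(t - t_step, y0, yf, lam, k))
    y = y + rng.normal(0.0, noise, n)
    A = np.full(n, 10.0)
    gs = np.full(n, 0.1)
    if variable == "gs":
        gs = np.maximum(y, 1e-4)
    else:
        A = y
    return make_series(t, Q, A, gs, protocol=Protocol.STEP_CHANGE)


class TestSplitStep:
    def test_canonical_step_at_300s(self, noiseless_truth):
        phases = split_step(simulate_step_response(noiseless_truth, seed=1))
        assert phases.t_step == 300.0
        assert len(phases.baseline) == 30
        assert len(phases.response) == 181

    def test_two_steps_error(self):
        t = np.arange(0.0, 900.0, 10.0)
        Q = np.where((t >= 300) & (t < 600), 1000.0, 100.0)
        s = make_series(t, Q, [10.0] * len(t), [0.1] * len(t))
        with pytest.raises(ValueError, match="one upward step"):
            split_step(s)

    def test_no_step_error(self):
        s = make_series(np.arange(0, 600, 10.0), [100.0] * 60, [10.0] * 60, [0.1] * 60)
        with pytest.raises(ValueError, match="step"):
            split_step(s)

    def test_jittered_setpoints_still_detected(self):
        # Q wobbles 98–103 then 995–1005; the midpoint threshold must not care
        s = step_series(q_jitter=4.0, seed=3)
        phases = split_step(s)
        # independent oracle: first sample whose Q exceeds the plateau midpoint
        expected = s.t[np.argmax(s.Q > 0.5 * (s.Q.min() + s.Q.max()))]
        assert phases.t_step == expected == 300.0


class TestFitInduction:
    def test_noiseless_recovery_to_1e6(self):
        phases = split_step(step_series(0.05, 0.20, 60.0, 100.0))
        fit = fit_induction(phases, "gs")
        assert fit.y0 == pytest.approx(0.05, rel=1e-6)
        assert fit.yf == pytest.approx(0.20, rel=1e-6)
        assert fit.lam == pytest.approx(60.0, rel=1e-6)
        assert fit.k == pytest.approx(100.0, rel=1e-6)
        assert fit.tau == fit.k

    def test_noisy_recovery_median_within_10pct(self):
        errs = []
        for seed in range(20):
            phases = split_step(step_series(noise=0.005, seed=seed))
            fit = fit_induction(phases, "gs")
            errs.append(abs(fit.k - 100.0) / 100.0)
        assert np.median(errs) <= 0.10

    @pytest.mark.parametrize("k_true", [42.0, 300.0, 1062.0])
    def test_operating_range_recovery(self, k_true, truth):
        """Stomatal τ across its full observed span recovers within 15%
        under protocol sampling and channel noise."""
        tr = dataclasses.replace(truth, k_gs=k_true)
        errs = []
        for seed in range(8):
            phases = split_step(simulate_step_response(tr, seed=seed))
            fit = fit_induction(phases, "gs")
            errs.append(abs(fit.k - k_true) / k_true)
        assert np.median(errs) <= 0.15

    def test_closing_response_same_machinery(self):
        # yf < y0: same sigmoid fits a downward relaxation
        phases = split_step(step_series(y0=0.20, yf=0.05))
        fit = fit_induction(phases, "gs")
        assert fit.k == pytest.approx(100.0, rel=1e-6)
        assert fit.yf < fit.y0

    def test_time_origin_shift_equivariance(self):
        base = step_series(noise=0.002, seed=7)
        fit0 = fit_induction(split_step(base), "gs")
        shifted = dataclasses.replace(base, t=base.t + 500.0)
        fit1 = fit_induction(split_step(shifted), "gs")
        assert fit1.k == pytest.approx(fit0.k, rel=1e-6)
        assert (fit1.yf - fit1.y0) == pytest.approx(fit0.yf - fit0.y0, rel=1e-6)
        assert fit1.lam == pytest.approx(fit0.lam, rel=1e-6, abs=1e-6)

    def test_flat_trace_flagged_not_fitted(self):
        phases = split_step(step_series(y0=0.10, yf=0.10, noise=0.005, seed=2))
        fit = fit_induction(phases, "gs")
        assert fit.no_response
        assert np.isnan(fit.k)

    def test_fit_does_not_overshoot_data_range(self, truth):
        phases = split_step(simulate_step_response(truth, seed=4))
        fit = fit_induction(phases, "gs")
        t = np.linspace(0, 1800, 500)
        pred = fit.predict(t)
        margin = 5 * truth.noise_gs
        assert pred.min() >= phases.response.gs.min() - margin
        assert pred.max() <= phases.response.gs.max() + margin

    def test_estimates_are_global_minima(self):
        """The multi-start fit lands on the global SSE optimum: refining
        from the true parameters never finds a lower residual."""
        from scipy.optimize import least_squares

        for seed in (100, 107, 113):
            phases = split_step(step_series(k=900.0, noise=0.005, seed=seed))
            fit = fit_induction(phases, "gs")
            t = phases.response.t - phases.t_step
            y = phases.response.gs
            res = least_squares(
                lambda p: sigmoid_response(t, *p) - y,
                [0.05, 0.20, 60.0, 900.0],
                bounds=([-np.inf, -np.inf, 0, 1e-3], [np.inf, np.inf, t[-1], 20 * t[-1]]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            assert fit.sse <= float(2 * res.cost) + 1e-9


class TestWi:
    def test_arithmetic(self):
        s = make_series([0, 10], [100, 100], [20.0, 20.0], [0.1, 0.1])
        np.testing.assert_allclose(wi_timecourse(s), [200.0, 200.0])

    def test_zero_gs_masked_not_raised(self):
        s = make_series([0, 10], [100, 100], [20.0, 20.0], [0.0, 0.1])
        wi = wi_timecourse(s)
        assert np.isnan(wi[0]) and wi[1] == pytest.approx(200.0)

    def test_ratio_scale_invariance(self):
        s = make_series([0, 10, 20], [100] * 3, [10.0, 12.0, 14.0], [0.05, 0.06, 0.07])
        s3 = dataclasses.replace(s, A=s.A * 3, gs=s.gs * 3)
        np.testing.assert_allclose(wi_timecourse(s3), wi_timecourse(s), rtol=1e-12)


class TestSteadyStateWi:
    def test_constant_phases(self):
        t = np.arange(0.0, 2100.0, 10.0)
        Q = np.where(t < 300, 100.0, 1000.0)
        A = np.where(t < 300, 12.0, 18.0)
        gs = np.where(t < 300, 0.10, 0.10)
        s = make_series(t, Q, A, gs)
        wi = steady_state_wi(split_step(s))
        assert wi.wi_low == pytest.approx(120.0)
        assert wi.wi_high == pytest.approx(180.0)

    def test_matches_naive_mean_on_hand_fixture(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 2110.0, 10.0)
        Q = np.where(t < 300, 100.0, 1000.0)
        A = 15 + rng.normal(0, 0.5, len(t))
        gs = 0.1 + rng.normal(0, 0.003, len(t))
        s = make_series(t, Q, A, gs)
        wi = steady_state_wi(split_step(s))
        resp = t >= 300
        tail = t >= t[resp].max() - 300
        expected_high = np.mean(A[resp & tail] / gs[resp & tail])
        assert wi.wi_high == pytest.approx(expected_high, rel=1e-12)

    def test_short_phase_errors(self):
        t = np.arange(0.0, 500.0, 10.0)
        Q = np.where(t < 100, 100.0, 1000.0)
        s = make_series(t, Q, [15.0] * len(t), [0.1] * len(t))
        with pytest.warns(UserWarning):
            phases = split_step(s)
        with pytest.raises(ValueError, match="window"):
            steady_state_wi(phases)
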