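"""Heart-rate recovery and vagal-reactivation indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combatmet import cardiac as C
from combatmet.data import CombatProtocol, RRSeries
from combatmet.simulate import SimConfig, gen_rr_combat, gen_rr_recovery


def tachogram_from(fn, t_lo=-20.0, t_hi=400.0, dt=1.0):
    t = np.arange(t_lo, t_hi + dt / 2, dt)
    return C.Tachogram(t, fn(t), dt)


def exp_recovery(asym=120.0, amp=60.0, tau=60.0):
    def fn(t):
        hr = np.where(t < 0, asym + amp, asym + amp * np.exp(-np.maximum(t, 0) / tau))
        return hr

    return tachogram_from(fn)


class TestTachogram:
    @pytest.mark.parametrize("rr,expected", [(600.0, 100.0), (1000.0, 60.0)])
    def test_constant_rr_maps_to_hr(self, rr, expected):
        s = RRSeries(np.full(300, rr), t0=0.0)
        tacho = C.hr_from_rr(s)
        np.testing.assert_allclose(tacho.hr, expected)

    def test_generator_envelope_recovered(self, sim_cfg):
        series, truth = gen_rr_recovery(sim_cfg)
        tacho = C.hr_from_rr(series)
        t_chk = np.array([30.0, 120.0, 300.0])
        model = truth["asymptote"] + truth["amplitude"] * np.exp(-t_chk / truth["tau"])
        for tc, hm in zip(t_chk, model):
            i = int(np.argmin(np.abs(tacho.time - tc)))
            # beat-to-beat jitter leaves a little scatter; the envelope
            # itself must round-trip closely
            assert abs(tacho.hr[i] - hm) < 6.0

    def test_empty_or_short_rejected(self):
        with pytest.raises(ValueError):
            C.hr_from_rr(RRSeries(np.array([800.0]), t0=0.0))


class TestEndExerciseHR:
    def test_constant(self):
        assert C.end_exercise_hr(exp_recovery()) == pytest.approx(180.0)

    def test_linear_ramp_midpoint(self):
        def fn(t):
            return np.where(t < 0, 180.0 + 2.0 * (t + 2.5), 180.0)

        # 175 -> 185 over the last 5 s averages to 180
        tacho = tachogram_from(fn, t_lo=-5.0)
        assert C.end_exercise_hr(tacho) == pytest.approx(180.0, abs=1.1)

    def test_insufficient_span_rejected(self):
        tacho = tachogram_from(lambda t: np.full(t.size, 150.0), t_lo=-2.0)
        with pytest.raises(ValueError):
            C.end_exercise_hr(tacho)


class TestHRR60:
    def test_closed_form_drop(self):
        tacho = exp_recovery(asym=120.0, amp=60.0, tau=60.0)
        expected = 180.0 - (120.0 + 60.0 * math.exp(-1.0))
        assert C.hrr_60s(tacho) == pytest.approx(expected, abs=0.25)

    def test_flat_hr_zero_drop(self):
        tacho = tachogram_from(lambda t: np.full(t.size, 150.0))
        assert C.hrr_60s(tacho) == pytest.approx(0.0)

    def test_monotone_decreasing_positive(self):
        tacho = tachogram_from(lambda t: 190.0 - 0.1 * (t - t.min()))
        assert C.hrr_60s(tacho) > 0


class TestExponentialFit:
    def test_noiseless_exact(self):
        tacho = exp_recovery(asym=100.0, amp=70.0, tau=180.0)
        tau, amp, asym = C.fit_hrr_exponential(tacho)
        assert tau == pytest.approx(180.0, rel=1e-6)
        assert amp == pytest.approx(70.0, rel=1e-6)
        assert asym == pytest.approx(100.0, rel=1e-6)

    def test_constant_hr_degenerate(self):
        tacho = tachogram_from(lambda t: np.full(t.size, 140.0))
        tau, amp, asym = C.fit_hrr_exponential(tacho)
        assert amp == 0.0 and math.isnan(tau) and asym == pytest.approx(140.0)

    def test_tau_recovery_under_noise(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)

            def fn(t):
                clean = 100.0 + 70.0 * np.exp(-np.maximum(t, 0) / 180.0)
                return clean + rng.normal(0, 2.0, t.size)

            tau, _, _ = C.fit_hrr_exponential(tachogram_from(fn))
            errs.append(abs(tau - 180.0) / 180.0)
        assert np.median(errs) < 0.10


class TestT30:
    def test_pure_exponential_equals_tau(self):
        tacho = tachogram_from(lambda t: 180.0 * np.exp(-np.maximum(t, 0) / 300.0))
        assert C.t30(tacho) == pytest.approx(300.0, rel=1e-9)

    def test_rising_hr_flagged_sentinel(self):
        tacho = tachogram_from(lambda t: 100.0 + 0.2 * (t - t.min()))
        assert C.t30(tacho) == math.inf

    def test_asymptote_biases_t30_above_tau(self):
        tau = 90.0
        tacho = exp_recovery(asym=105.0, amp=75.0, tau=tau)
        est = C.t30(tacho)
        # closed form of the log-regression bias on [10, 40] s
        t = np.arange(10.0, 41.0)
        lr = np.polyfit(t, np.log(105.0 + 75.0 * np.exp(-t / tau)), 1)
        assert est == pytest.approx(-1.0 / lr[0], rel=1e-6)
        assert est > tau


class TestRMSSD:
    def test_constant_rr_zero(self):
        trace = C.rmssd_30s(RRSeries(np.full(500, 800.0), t0=0.0))
        assert np.nanmax(trace.rmssd) == pytest.approx(0.0)

    def test_alternating_rr_constant_diff(self):
        rr = np.tile([800.0, 810.0], 250)
        trace = C.rmssd_30s(RRSeries(rr, t0=0.0))
        np.testing.assert_allclose(trace.rmssd[trace.valid], 10.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        rr = 800.0 + rng.normal(0, 20.0, 500)
        a = C.rmssd_30s(RRSeries(rr, t0=0.0))
        b = C.rmssd_30s(RRSeries(rr + 100.0, t0=0.0))
        # same successive differences, though beats shift segments a little
        assert np.nanmean(b.rmssd) == pytest.approx(np.nanmean(a.rmssd), rel=0.15)

    def test_translation_invariance_exact_same_segmentation(self):
        rr = np.tile([800.0, 820.0, 790.0], 100)
        a = C.rmssd_30s(RRSeries(rr, t0=0.0), recovery_duration=60.0)
        b = C.rmssd_30s(RRSeries(rr + 5.0, t0=0.0), recovery_duration=60.0)
        np.testing.assert_allclose(a.rmssd, b.rmssd)

    def test_programmed_profile_recovered(self, sim_cfg):
        series, truth = gen_rr_recovery(sim_cfg)
        trace = C.rmssd_30s(series)
        prof = np.array(truth["rmssd_profile"])
        est = trace.rmssd[: prof.size]
        # per-segment sample RMSSD at ~30 beats/segment scatters around
        # the programmed value; the trace as a whole must track it
        assert np.nanmean(np.abs(est - prof) / prof) < 0.3
        assert np.nanmean(est) == pytest.approx(np.mean(prof), rel=0.15)

    def test_segment_count(self, sim_cfg):
        series, _ = gen_rr_recovery(sim_cfg)
        trace = C.rmssd_30s(series, recovery_duration=360.0)
        assert trace.rmssd.size == 12


class TestMedianFilter:
    def test_outlier_removed(self):
        trace = C.RMSSDTrace(np.arange(3) * 30.0, np.array([5.0, 100.0, 5.0]))
        np.testing.assert_allclose(C.median_filter3(trace).rmssd, [5.0, 5.0, 5.0])

    def test_monotone_unchanged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        trace = C.RMSSDTrace(np.arange(5) * 30.0, x)
        np.testing.assert_allclose(C.median_filter3(trace).rmssd, x)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_and_endpoints_preserved(self, values):
        trace = C.RMSSDTrace(30.0 * np.arange(len(values)), np.array(values))
        once = C.median_filter3(trace)
        twice = C.median_filter3(once)
        np.testing.assert_allclose(twice.rmssd, once.rmssd)
        assert once.rmssd[0] == trace.rmssd[0]
        assert once.rmssd[-1] == trace.rmssd[-1]

    def test_short_trace_unchanged(self):
        trace = C.RMSSDTrace(np.array([0.0, 30.0]), np.array([3.0, 9.0]))
        np.testing.assert_allclose(C.median_filter3(trace).rmssd, [3.0, 9.0])


class TestRoundSummary:
    def test_constant_hr(self, protocol):
        t = np.arange(-protocol.combat_end, 10.0)
        tacho = C.Tachogram(t, np.full(t.size, 170.0), 1.0)
        s = C.hr_round_summary(tacho, protocol)
        assert s.hr_mean == pytest.approx([170.0] * 3)
        assert s.hr_peak == pytest.approx([170.0] * 3)

    def test_spike_smoothed_by_rolling_mean(self, protocol):
        t = np.arange(-protocol.combat_end, 10.0)
        hr = np.full(t.size, 170.0)
        hr[50] = 200.0
        s = C.hr_round_summary(C.Tachogram(t, hr, 1.0), protocol)
        assert s.hr_peak[0] < 200.0
        assert s.hr_peak[0] > 170.0

    def test_generator_round_means(self, sim_cfg, protocol):
        series, truth = gen_rr_combat(sim_cfg)
        s = C.hr_round_summary(C.hr_from_rr(series), protocol)
        for est, true_mean in zip(s.hr_mean, truth["hr_round_mean"]):
            assert abs(est - true_mean) < 1.0
        for mean, peak in zip(s.hr_mean, s.hr_peak):
            assert peak >= mean


class TestIndicesBundle:
    def test_full_recovery_indices(self, sim_cfg, protocol):
        series, truth = gen_rr_recovery(sim_cfg)
        idx = C.hrr_indices(series, protocol.recovery_duration)
        assert idx.hrr_60s == pytest.approx(truth["hrr_60s"], abs=3.0)
        assert idx.tau == pytest.approx(truth["tau"], rel=0.05)
        assert idx.amplitude == pytest.approx(truth["amplitude"], rel=0.05)
        assert not idx.flagged
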