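"""Energy-system estimation against hand computations and closed forms."""

import math

import numpy as np
import pytest

from combatmet import energetics as E
from combatmet.data import Athlete, BreathSeries, CombatProtocol, LactateSamples, segment_phases
from combatmet.simulate import SimConfig, gen_lactate_profile, gen_vo2_trace

from conftest import make_flat_series


def series_with(protocol, fn, dt=1.0):
    t0, t1 = protocol.baseline_window[0], protocol.recovery_window[1]
    t = np.arange(t0, t1 + dt / 2, dt)
    return segment_phases(BreathSeries(t, fn(t)), protocol)


class TestRestingVO2:
    def test_constant_baseline(self, protocol, flat_series):
        assert E.resting_vo2(flat_series, protocol) == pytest.approx(300.0)

    def test_missing_baseline_errors(self, protocol):
        t = np.arange(0, protocol.recovery_window[1] + 1.0)
        s = BreathSeries(t, np.full(t.size, 300.0), np.full(t.size, "round_1", dtype=object))
        with pytest.raises(ValueError):
            E.resting_vo2(s, protocol)

    def test_noisy_baseline_mean_close(self, protocol):
        rng = np.random.default_rng(5)

        def fn(t):
            return 300.0 + rng.normal(0, 10, t.size)

        s = series_with(protocol, fn)
        assert abs(E.resting_vo2(s, protocol) - 300.0) < 2.0


class TestRoundMean:
    def test_constant(self, protocol, flat_series):
        s = make_flat_series(protocol, vo2=2800.0)
        assert E.round_vo2_mean(s, 1, 70.0, protocol) == pytest.approx(40.0)

    def test_linear_ramp_midpoint(self, protocol):
        start, end = protocol.round_window(2)

        def fn(t):
            v = np.full(t.size, 2000.0)
            in_rd = (t >= start) & (t <= end)
            v[in_rd] = 2000.0 + 1000.0 * (t[in_rd] - start) / (end - start)
            return v

        s = series_with(protocol, fn)
        assert E.round_vo2_mean(s, 2, 70.0, protocol) == pytest.approx(2500.0 / 70.0, rel=1e-3)

    def test_matches_fine_grid_oracle(self, protocol, sim_cfg):
        series, _ = gen_vo2_trace(sim_cfg)
        coarse = E.round_vo2_mean(series, 1, 71.0, protocol)
        start, end = protocol.round_window(1)
        tfine = np.linspace(start, end, 48001)
        vfine = np.interp(tfine, series.time, series.vo2)
        oracle = np.trapezoid(vfine, tfine) / (end - start) / 71.0
        assert coarse == pytest.approx(oracle, rel=1e-3)


class TestAerobicEnergy:
    def test_zero_net(self, protocol, flat_series):
        assert E.aerobic_energy(flat_series, 300.0, 1, protocol) == pytest.approx(0.0, abs=1e-9)

    def test_constant_net_hand_value(self, protocol):
        # 3 L/min above rest for 2 min = 6 L O2 = 125.52 kJ
        s = make_flat_series(protocol, vo2=3300.0)
        assert E.aerobic_energy(s, 300.0, 1, protocol) == pytest.approx(125.52, rel=1e-9)

    def test_exponential_on_kinetics_closed_form(self, protocol):
        start, end = protocol.round_window(1)
        base, amp, tau = 350.0, 2800.0, 30.0

        def fn(t):
            v = np.full(t.size, base)
            m = t >= start
            v[m] = base + amp * (1 - np.exp(-(t[m] - start) / tau))
            return v

        s = series_with(protocol, fn)
        est = E.aerobic_energy(s, base, 1, protocol)
        dur = end - start
        exact_ml = amp * (dur - tau * (1 - math.exp(-dur / tau))) / 60.0
        assert est == pytest.approx(exact_ml / 1000.0 * E.KJ_PER_L_O2, rel=0.005)


class TestEpocFit:
    def recovery(self, protocol, base, amp, tau, noise=0.0, seed=0):
        start, end = protocol.recovery_window
        t = np.arange(start, end, 1.0)
        v = base + amp * np.exp(-(t - start) / tau)
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, t.size)
        return BreathSeries(t, np.maximum(v, 0.0))

    def test_noiseless_recovery_exact(self, protocol):
        fit = E.fit_epoc(self.recovery(protocol, 400.0, 2000.0, 45.0), 400.0)
        assert fit.model == "mono" and not fit.degenerate
        assert fit.amplitude_A == pytest.approx(2000.0, rel=1e-6)
        assert fit.tau == pytest.approx(45.0, rel=1e-6)
        assert fit.baseline == pytest.approx(400.0, rel=1e-6)

    def test_flat_recovery_degenerate(self, protocol):
        fit = E.fit_epoc(self.recovery(protocol, 400.0, 0.0, 45.0), 400.0)
        assert fit.degenerate and fit.amplitude_A == 0.0

    def test_too_short_recovery_rejected(self):
        s = BreathSeries(np.arange(0, 100.0), 400 + np.arange(0, 100.0))
        with pytest.raises(ValueError, match="180"):
            E.fit_epoc(s, 400.0)

    def test_tau_recovery_under_noise(self, protocol):
        errs = []
        for seed in range(100):
            fit = E.fit_epoc(self.recovery(protocol, 400.0, 2000.0, 45.0, noise=50.0, seed=seed), 400.0)
            errs.append(abs(fit.tau - 45.0) / 45.0)
        assert np.median(errs) < 0.05

    def test_bi_model_detected_when_slow_component_real(self, protocol):
        start, end = protocol.recovery_window
        t = np.arange(start, end, 1.0)
        tt = t - start
        v = 400.0 + 2000.0 * np.exp(-tt / 40.0) + 500.0 * np.exp(-tt / 250.0)
        fit = E.fit_epoc(BreathSeries(t, v), 400.0)
        assert fit.model == "bi"
        assert fit.tau2 > fit.tau
        # W_PCR still uses only the fast term
        assert fit.fast_o2_volume_l == pytest.approx(fit.amplitude_A / 60 * fit.tau / 1000)


class TestPcrEnergy:
    def test_interval_at_rest_is_zero(self, protocol, flat_series):
        assert E.pcr_energy(flat_series, None, 300.0, 1, protocol) == pytest.approx(0.0, abs=1e-9)

    def test_final_round_analytic_a_tau(self, protocol):
        # A = 3000 mL/min, tau = 40 s -> 2.0 L O2 -> 41.84 kJ
        fit = E.ExpFit(3000.0, 40.0, 400.0)
        assert E.pcr_energy(None, fit, 400.0, 3, protocol) == pytest.approx(41.84, rel=1e-9)

    def test_missing_fit_errors(self, protocol, flat_series):
        with pytest.raises(ValueError, match="EPOC"):
            E.pcr_energy(flat_series, None, 300.0, 3, protocol)

    def test_simulated_fast_volume_within_5pct(self, protocol):
        cfg = SimConfig(seed=21)
        series, truth = gen_vo2_trace(cfg)
        vrest = E.resting_vo2(series, protocol)
        fit = E.fit_epoc(series.in_window(*protocol.recovery_window), vrest, t0=protocol.recovery_window[0])
        est = E.pcr_energy(series, fit, vrest, 3, protocol)
        assert est == pytest.approx(truth["epoc_fast_o2_l"] * E.KJ_PER_L_O2, rel=0.05)


class TestLactate:
    def test_deltas_from_profile(self):
        s = LactateSamples(
            {"post_warmup": 2.0, "post_round_1": 6.0, "post_round_2": 8.0, "post_round_3": 9.0}
        )
        d = E.lactate_deltas(s)
        assert d.delta == pytest.approx([4.0, 2.0, 1.0])
        assert d.peak == pytest.approx(9.0)

    def test_equal_samples_zero_deltas(self):
        s = LactateSamples({l: 5.0 for l in ("post_warmup", "post_round_1", "post_round_2", "post_round_3")})
        assert E.lactate_deltas(s).delta == pytest.approx([0.0, 0.0, 0.0])

    def test_recovery_sample_can_be_peak(self):
        s = LactateSamples(
            {
                "post_warmup": 2.0,
                "post_round_1": 6.0,
                "post_round_2": 8.0,
                "post_round_3": 9.0,
                "recovery_1min": 10.1,
            }
        )
        assert E.lactate_deltas(s).peak == pytest.approx(10.1)

    def test_missing_label_named(self):
        s = LactateSamples({"post_warmup": 2.0, "post_round_1": 6.0, "post_round_2": 8.0})
        with pytest.raises(ValueError, match="post_round_3"):
            E.lactate_deltas(s)

    @pytest.mark.parametrize(
        "delta,mass,expected",
        [(0.0, 70.0, 0.0), (1.0, 70.0, 70 * 3 / 1000 * 20.92), (-2.0, 70.0, 0.0)],
    )
    def test_glycolytic_energy(self, delta, mass, expected):
        assert E.glycolytic_energy(delta, mass) == pytest.approx(expected)
        assert E.glycolytic_energy(1.0, 70.0) == pytest.approx(4.3932)


class TestPartition:
    def test_generator_truth_within_5pct(self, protocol):
        cfg = SimConfig(seed=31)
        series, truth = gen_vo2_trace(cfg)
        lac, lt = gen_lactate_profile(cfg, "PLA", 71.0)
        part = E.partition_energy(Athlete("A", 71.0), series, lac, protocol)
        for est, true_l in zip(part.w_aer, truth["aerobic_o2_l"]):
            assert est == pytest.approx(true_l * E.KJ_PER_L_O2, rel=0.05)
        for est, true_l in zip(part.w_pcr[:-1], truth["interval_o2_l"]):
            assert est == pytest.approx(true_l * E.KJ_PER_L_O2, rel=0.05)
        assert part.w_pcr[-1] == pytest.approx(truth["epoc_fast_o2_l"] * E.KJ_PER_L_O2, rel=0.05)
        for est, true_kj in zip(part.w_la, lt["w_la_kj"]):
            assert est == pytest.approx(true_kj, abs=2.5 * 0.3 * 3 * 71 * 20.92 / 1000)

    def test_relative_sums_to_100(self, protocol):
        cfg = SimConfig(seed=31)
        series, _ = gen_vo2_trace(cfg)
        lac, _ = gen_lactate_profile(cfg, "CAF", 71.0)
        part = E.partition_energy(Athlete("A", 71.0, "CAF"), series, lac, protocol)
        rel_a, rel_p, rel_l = part.relative()
        for a, p, l in zip(rel_a, rel_p, rel_l):
            assert a + p + l == pytest.approx(100.0, abs=1e-9)
        assert part.w_total == pytest.approx(
            [a + p + l for a, p, l in zip(part.w_aer, part.w_pcr, part.w_la)]
        )

    def test_degenerate_all_zero_flagged(self, protocol, flat_series):
        lac = LactateSamples(
            {l: 2.0 for l in ("post_warmup", "post_round_1", "post_round_2", "post_round_3")}
        )
        part = E.partition_energy(Athlete("A", 70.0), flat_series, lac, protocol)
        assert part.degenerate_rounds == [1, 2, 3]
        assert all(math.isnan(v) for v in part.relative()[0])


class TestConditionMeans:
    @pytest.mark.parametrize(
        "rounds,expected",
        [
            ((17.7, 11.8, 8.1), 12.5),  # caffeine glycolytic
            ((13.3, 7.5, 5.8), 8.9),  # placebo glycolytic
            ((5.0, 5.0, 5.0), 5.0),
        ],
    )
    def test_round_means(self, rounds, expected):
        mean, _ = E.condition_round_means(rounds)
        assert mean == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            E.condition_round_means([])
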