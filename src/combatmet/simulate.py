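"""Synthetic physiological signals with analytic ground truth.

Generates everything the pipeline consumes — breath-by-breath VO2,
beat-to-beat R-R series, round-wise lactate profiles and time-motion
event logs — for a round-based combat protocol, with the quantities the
pipeline is supposed to estimate recorded exactly at generation time.

The deterministic VO2 skeleton is a piecewise first-order relaxation:
within a round VO2 relaxes toward ``baseline + round_amplitude`` with
time constant ``on_tau``; in rest intervals and recovery it relaxes
back toward baseline with ``off_tau``.  All phase integrals (aerobic
net O2 per round, net interval O2, the fast post-exercise O2 volume)
therefore have closed forms, which are stored as ground truth.  Breath
timestamps are irregular (gamma inter-breath intervals) so the
integrators must actually resample, and additive Gaussian noise models
breath-to-breath scatter.

Heart rate follows the same skeleton (round plateaus rising across
rounds, first-order recovery after the last round); R-R intervals are
60000/HR plus zero-mean jitter whose per-segment spread follows a
programmed RMSSD profile.  Lactate accumulates per round with
decreasing increments; a caffeine-like condition adds a programmed
glycolytic offset, specified in kJ per round and converted to
mmol·L⁻¹ through each subject's body mass.  Event logs alternate
stepping and attack actions with occasional referee pauses, on a 0.1-s
grid.

Per-signal random streams are split from one master seed, so altering
one generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd

from .data import Athlete, BreathSeries, CombatProtocol, LactateSamples, RRSeries, segment_phases
from .energetics import KJ_PER_L_O2, LACTATE_O2_ML_PER_KG

__all__ = [
    "VO2Config",
    "HRConfig",
    "LactateConfig",
    "EventConfig",
    "SimConfig",
    "SubjectBundle",
    "gen_vo2_trace",
    "gen_rr_recovery",
    "gen_rr_combat",
    "gen_lactate_profile",
    "gen_event_log",
    "gen_cohort",
]

_STREAMS = {"vo2": 1, "hr": 2, "lactate": 3, "events": 4, "cohort": 5}


def _rng(seed: int, stream: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, keys)]))


@dataclass(frozen=True)
class VO2Config:
    """Gas-exchange generator settings (mL·min⁻¹ absolute, s)."""

    baseline: float = 355.0  # ~5 mL/kg/min at 71 kg
    round_amplitude: float = 2750.0  # plateau above baseline during rounds
    on_tau: float = 25.0
    off_tau: float = 50.0
    warmup_frac: float = 0.35  # warm-up target as a fraction of round amplitude
    breath_noise_sd: float = 80.0
    breath_rate: float = 30.0  # breaths per minute (mean)


@dataclass(frozen=True)
class HRConfig:
    """Heart-rate generator settings (bpm, s, ms)."""

    end_hr: float = 180.0  # HR at exercise cessation
    asymptote: float = 105.0
    tau: float = 90.0  # recovery time constant
    round_rise: float = 5.0  # plateau increase per successive round
    on_tau: float = 20.0
    interval_drop: float = 35.0  # HR falls this far toward rest between rounds
    rmssd_profile: tuple[float, ...] = (4.0, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5, 11.0, 11.5, 12.0, 12.5)


@dataclass(frozen=True)
class LactateConfig:
    """Blood-lactate generator settings (mmol·L⁻¹)."""

    pre_warmup: float = 1.3
    start: float = 2.5  # post-warm-up value
    per_round_delta: tuple[float, ...] = (3.0, 1.7, 1.3)  # decreasing across rounds
    noise_sd: float = 0.3  # analyzer + sampling error per sample


@dataclass(frozen=True)
class EventConfig:
    """Time-motion generator settings (s)."""

    attack_dur_mean: float = 1.3
    step_dur_mean: float = 3.3
    pause_prob: float = 0.06  # chance a stepping slot becomes a referee pause
    pause_dur_mean: float = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Master configuration: one seed drives every stream."""

    seed: int = 0
    protocol: CombatProtocol = field(default_factory=CombatProtocol)
    vo2: VO2Config = field(default_factory=VO2Config)
    hr: HRConfig = field(default_factory=HRConfig)
    lactate: LactateConfig = field(default_factory=LactateConfig)
    events: EventConfig = field(default_factory=EventConfig)
    n_subjects: int = 10
    mean_body_mass: float = 71.0
    sd_body_mass: float = 12.9
    glycolytic_offset_kj: float = 3.6  # CAF minus PLA, per round


# ---------------------------------------------------------------------------
# VO2


def _vo2_segments(cfg: SimConfig, vo2: VO2Config) -> list[tuple[float, float, float, float]]:
    """(t_start, t_end, target, tau) pieces of the deterministic skeleton."""
    p = cfg.protocol
    b, amp = vo2.baseline, vo2.round_amplitude
    segs = [
        (p.baseline_window[0], p.warmup_window[0], b, vo2.off_tau),
        (p.warmup_window[0], p.warmup_window[1], b + vo2.warmup_frac * amp, vo2.on_tau),
        (p.warmup_window[1], 0.0, b, vo2.off_tau),
    ]
    for k in range(1, p.n_rounds + 1):
        segs.append((*p.round_window(k), b + amp, vo2.on_tau))
        if k < p.n_rounds:
            segs.append((*p.interval_window(k), b, vo2.off_tau))
    segs.append((*p.recovery_window, b, vo2.off_tau))
    return segs


def _skeleton(segs, v0: float):
    """Piecewise-exponential evaluator plus per-segment start values."""
    starts = [v0]
    for (t0, t1, target, tau) in segs:
        v_end = target + (starts[-1] - target) * math.exp(-(t1 - t0) / tau)
        starts.append(v_end)

    bounds = np.array([s[0] for s in segs] + [segs[-1][1]])

    def value(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(segs) - 1)
        out = np.empty_like(t)
        for i, (t0, t1, target, tau) in enumerate(segs):
            m = idx == i
            if m.any():
                out[m] = target + (starts[i] - target) * np.exp(-(t[m] - t0) / tau)
        return out

    return value, starts


def _segment_net_integral(seg, v0: float, ref: float) -> float:
    """∫ (v(t) − ref) dt over one (t0, t1, target, tau) segment, closed form."""
    t0, t1, target, tau = seg
    dt = t1 - t0
    return (target - ref) * dt + (v0 - target) * tau * (1.0 - math.exp(-dt / tau))


def gen_vo2_trace(cfg: SimConfig, subject: int = 0, condition: int = 0) -> tuple[BreathSeries, dict]:
    """Breath-by-breath VO2 trace for one bout, with analytic truth.

    Ground truth holds the baseline, per-round net aerobic O2 volumes,
    net interval O2 volumes, and the fast-component recovery amplitude,
    time constant and O2 volume — all in the units the pipeline
    estimates (litres O2 / mL·min⁻¹ / s).
    """
    return _gen_vo2(cfg, cfg.vo2, _rng(cfg.seed, "vo2", subject, condition))


def _gen_vo2(cfg: SimConfig, vo2: VO2Config, rng: np.random.Generator) -> tuple[BreathSeries, dict]:
    p = cfg.protocol
    segs = _vo2_segments(cfg, vo2)
    value, starts = _skeleton(segs, vo2.baseline)

    truth: dict = {"vo2_baseline": vo2.baseline}
    seg_by_window = {(t0, t1): i for i, (t0, t1, _, _) in enumerate(segs)}
    aer, inter, round_mean = [], [], []
    for k in range(1, p.n_rounds + 1):
        w = p.round_window(k)
        i = seg_by_window[w]
        net = _segment_net_integral(segs[i], starts[i], vo2.baseline)
        aer.append(net / 60.0 / 1000.0)  # L O2
        total = net + vo2.baseline * (w[1] - w[0])
        round_mean.append(total / (w[1] - w[0]))
        if k < p.n_rounds:
            w = p.interval_window(k)
            i = seg_by_window[w]
            net = _segment_net_integral(segs[i], starts[i], vo2.baseline)
            inter.append(net / 60.0 / 1000.0)
    rec_i = seg_by_window[p.recovery_window]
    amp = starts[rec_i] - vo2.baseline
    truth.update(
        aerobic_o2_l=aer,
        interval_o2_l=inter,
        round_mean_vo2=round_mean,
        epoc_amplitude=amp,
        epoc_tau=vo2.off_tau,
        epoc_fast_o2_l=amp * vo2.off_tau / 60.0 / 1000.0,
    )

    # irregular breath timestamps over the whole span
    t_lo, t_hi = segs[0][0], segs[-1][1]
    mean_ibi = 60.0 / vo2.breath_rate
    n_est = int((t_hi - t_lo) / mean_ibi * 1.4) + 50
    ibis = rng.gamma(4.0, mean_ibi / 4.0, size=n_est)
    times = t_lo + np.cumsum(ibis)
    times = np.concatenate([[t_lo], times[times <= t_hi]])
    if times[-1] < t_hi:
        times = np.append(times, t_hi)
    v = value(times) + rng.normal(0.0, vo2.breath_noise_sd, size=times.size)
    series = BreathSeries(times, np.maximum(v, 0.0))
    return segment_phases(series, p), truth


# ---------------------------------------------------------------------------
# heart rate


def _rr_from_envelope(hr_of_t, t_lo: float, t_hi: float, jitter_sd_of_t, rng) -> np.ndarray:
    """Sample beats so that instantaneous HR tracks the envelope."""
    rr = []
    t = t_lo
    while t < t_hi:
        hr = hr_of_t(t)
        interval = 60000.0 / hr + rng.normal(0.0, jitter_sd_of_t(t))
        interval = max(interval, 250.0)  # physiological floor
        rr.append(interval)
        t += interval / 1000.0
    return np.array(rr)


def gen_rr_recovery(cfg: SimConfig, subject: int = 0, condition: int = 0, pre_s: float = 15.0) -> tuple[RRSeries, dict]:
    """Post-exercise R-R recovery with a short pre-cessation plateau.

    HR(t) = asymptote + (end_hr − asymptote)·exp(−t/τ) for t ≥ 0 and
    end_hr for the ``pre_s`` seconds before cessation.  Jitter follows
    the per-30-s-segment RMSSD profile (SD of successive differences
    ≈ profile value).  Truth records τ, amplitude, asymptote and the
    model-implied 60-s drop.
    """
    hr = cfg.hr
    rng = _rng(cfg.seed, "hr", subject, condition, 0)
    amp = hr.end_hr - hr.asymptote
    prof = hr.rmssd_profile

    def envelope(t: float) -> float:
        return hr.end_hr if t < 0 else hr.asymptote + amp * math.exp(-t / hr.tau)

    def jitter_sd(t: float) -> float:
        if t < 0:
            return prof[0] / math.sqrt(2.0)
        seg = min(int(t // 30), len(prof) - 1)
        return prof[seg] / math.sqrt(2.0)

    dur = cfg.protocol.recovery_duration + 10.0
    rr = _rr_from_envelope(envelope, -pre_s, dur, jitter_sd, rng)
    truth = {
        "tau": hr.tau,
        "amplitude": amp,
        "asymptote": hr.asymptote,
        "end_hr": hr.end_hr,
        "hrr_60s": amp * (1.0 - math.exp(-60.0 / hr.tau)),
        "rmssd_profile": prof,
    }
    return RRSeries(rr, t0=pre_s), truth


def gen_rr_combat(cfg: SimConfig, subject: int = 0, condition: int = 0) -> tuple[RRSeries, dict]:
    """Full-bout R-R series: rising round plateaus, then mono recovery.

    The final round plateaus at ``end_hr`` so the recovery matches
    :func:`gen_rr_recovery`'s model exactly.  Truth records per-round
    envelope means and the recovery parameters.
    """
    hr = cfg.hr
    p = cfg.protocol
    rng = _rng(cfg.seed, "hr", subject, condition, 1)
    rest_hr = hr.asymptote
    segs = []
    for k in range(1, p.n_rounds + 1):
        target = hr.end_hr - hr.round_rise * (p.n_rounds - k)
        segs.append((*p.round_window(k), target, hr.on_tau))
        if k < p.n_rounds:
            segs.append((*p.interval_window(k), target - hr.interval_drop, 25.0))
    segs.append((p.combat_end, p.combat_end + p.recovery_duration + 10.0, hr.asymptote, hr.tau))
    value, starts = _skeleton(segs, rest_hr + 20.0)

    round_mean = []
    for k in range(1, p.n_rounds + 1):
        w = p.round_window(k)
        i = [tuple(s[:2]) for s in segs].index(w)
        net = _segment_net_integral(segs[i], starts[i], 0.0)
        round_mean.append(net / (w[1] - w[0]))

    prof = hr.rmssd_profile
    t_end = p.combat_end

    def envelope(t: float) -> float:  # t relative to cessation
        return float(value(np.array([t + t_end]))[0])

    def jitter_sd(t: float) -> float:
        if t < 0:
            return prof[0] / math.sqrt(2.0)
        seg = min(int(t // 30), len(prof) - 1)
        return prof[seg] / math.sqrt(2.0)

    rr = _rr_from_envelope(envelope, -t_end, p.recovery_duration + 10.0, jitter_sd, rng)
    amp = starts[-2] - hr.asymptote  # amplitude actually reached at cessation
    truth = {
        "hr_round_mean": round_mean,
        "hr_round_peak": [s[2] for s in segs if s[3] == hr.on_tau],
        "tau": hr.tau,
        "amplitude": amp,
        "asymptote": hr.asymptote,
        "hrr_60s": amp * (1.0 - math.exp(-60.0 / hr.tau)),
    }
    return RRSeries(rr, t0=t_end), truth


# ---------------------------------------------------------------------------
# lactate


def offset_mmol_for_kj(offset_kj: float, body_mass: float) -> float:
    """Per-round lactate increment equivalent to a programmed kJ offset."""
    return offset_kj * 1000.0 / (LACTATE_O2_ML_PER_KG * body_mass * KJ_PER_L_O2)


def gen_lactate_profile(
    cfg: SimConfig,
    condition: str = "PLA",
    body_mass: float | None = None,
    subject: int = 0,
    scale: float = 1.0,
) -> tuple[LactateSamples, dict]:
    """Round-wise lactate accumulation profile for one condition.

    Increments decrease across rounds; the CAF condition adds the
    configured glycolytic offset (kJ → mmol·L⁻¹ via body mass) to every
    round's increment.  Truth records the noiseless per-round deltas.
    """
    lac = cfg.lactate
    mass = body_mass if body_mass is not None else cfg.mean_body_mass
    cond_id = 1 if condition == "CAF" else 0
    rng = _rng(cfg.seed, "lactate", subject, cond_id)
    off = offset_mmol_for_kj(cfg.glycolytic_offset_kj, mass) if condition == "CAF" else 0.0
    deltas = [scale * d + off for d in lac.per_round_delta[: cfg.protocol.n_rounds]]

    clean = {"pre_warmup": lac.pre_warmup, "post_warmup": lac.start}
    level = lac.start
    for k, d in enumerate(deltas, start=1):
        level += d
        clean[f"post_round_{k}"] = level
    clean["recovery_1min"] = level + 0.3
    clean["recovery_3min"] = level - 0.3
    clean["recovery_5min"] = level - 0.9

    noisy = {k: max(v + rng.normal(0.0, lac.noise_sd), 0.0) for k, v in clean.items()}
    truth = {
        "deltas": deltas,
        "w_la_kj": [d * LACTATE_O2_ML_PER_KG * mass / 1000.0 * KJ_PER_L_O2 for d in deltas],
        "offset_mmol": off,
        "clean": clean,
    }
    return LactateSamples(noisy), truth


# ---------------------------------------------------------------------------
# events


def gen_event_log(cfg: SimConfig, subject: int = 0, condition: int = 0, pass_id: int = 1) -> tuple[pd.DataFrame, dict]:
    """Attack/stepping/pause event log on a 0.1-s grid, with counts.

    Rounds alternate stepping and attack segments; a stepping slot
    occasionally becomes a referee pause.  Truth records per-round
    attack counts and summed times exactly as emitted.
    """
    ev = cfg.events
    p = cfg.protocol
    rng = _rng(cfg.seed, "events", subject, condition, pass_id)
    rows = []
    truth = {"attack_number": [], "attack_time_sum": [], "stepping_time_sum": []}

    def draw(mean: float) -> float:
        d = rng.gamma(4.0, mean / 4.0)
        return max(round(d, 1), 0.3)

    for k in range(1, p.n_rounds + 1):
        t, limit = 0.0, p.round_duration
        kind = "stepping"
        an, at_sum, st_sum = 0, 0.0, 0.0
        while t < limit - 0.05:
            if kind == "stepping" and rng.random() < ev.pause_prob:
                this_kind, dur = "pause", draw(ev.pause_dur_mean)
            elif kind == "stepping":
                this_kind, dur = "stepping", draw(ev.step_dur_mean)
            else:
                this_kind, dur = "attack", draw(ev.attack_dur_mean)
            end = min(round(t + dur, 1), limit)
            if end - t >= 0.05:
                rows.append({"round": k, "kind": this_kind, "start_s": round(t, 1), "end_s": end, "pass_id": pass_id})
                d = round(end - t, 1)
                if this_kind == "attack":
                    an += 1
                    at_sum += d
                elif this_kind == "stepping":
                    st_sum += d
            t = end
            kind = "attack" if kind == "stepping" else "stepping"
        truth["attack_number"].append(an)
        truth["attack_time_sum"].append(round(at_sum, 1))
        truth["stepping_time_sum"].append(round(st_sum, 1))
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectBundle:
    """Everything one subject produced in one condition, plus truth."""

    athlete: Athlete
    breath: BreathSeries
    rr: RRSeries
    lactate: LactateSamples
    events: pd.DataFrame
    truth: dict


def gen_cohort(cfg: SimConfig) -> list[SubjectBundle]:
    """Two-condition crossover cohort with between-subject random effects.

    Each subject keeps their body mass and aerobic/lactate scaling in
    both conditions (crossover design); only the caffeine-like
    glycolytic offset distinguishes CAF from PLA.  Signal noise streams
    are independent per subject and condition.
    """
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = _rng(cfg.seed, "cohort")
    bundles = []
    for s in range(cfg.n_subjects):
        mass = float(np.clip(rng.normal(cfg.mean_body_mass, cfg.sd_body_mass), 48.0, 100.0))
        vo2_scale = float(rng.lognormal(0.0, 0.08))
        lac_scale = float(rng.lognormal(0.0, 0.15))
        hr_shift = float(rng.normal(0.0, 4.0))
        mass_factor = mass / cfg.mean_body_mass
        vo2_cfg = replace(
            cfg.vo2,
            baseline=cfg.vo2.baseline * mass_factor,
            round_amplitude=cfg.vo2.round_amplitude * mass_factor * vo2_scale,
        )
        hr_cfg = replace(cfg.hr, end_hr=cfg.hr.end_hr + hr_shift, asymptote=cfg.hr.asymptote + hr_shift)
        sub_cfg = replace(cfg, vo2=vo2_cfg, hr=hr_cfg)
        for ci, cond in enumerate(("CAF", "PLA")):
            breath, vo2_truth = _gen_vo2(sub_cfg, vo2_cfg, _rng(cfg.seed, "vo2", s, ci))
            rr, hr_truth = gen_rr_combat(sub_cfg, s, ci)
            lactate, lac_truth = gen_lactate_profile(sub_cfg, cond, mass, s, scale=lac_scale)
            events, ev_truth = gen_event_log(sub_cfg, s, ci)
            bundles.append(
                SubjectBundle(
                    Athlete(f"S{s + 1:02d}", mass, cond),
                    breath,
                    rr,
                    lactate,
                    events,
                    {"vo2": vo2_truth, "hr": hr_truth, "lactate": lac_truth, "events": ev_truth},
                )
            )
    return bundles
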