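"""Heart-rate summaries and post-exercise parasympathetic reactivation.

The R-R series is converted to an instantaneous-HR tachogram on a 1-s
grid (time 0 = exercise cessation).  From it we compute:

* per-round mean HR and peak HR (maximal 5-s rolling mean);
* ``HRR_60s``: HR drop from the last 5 s of exercise to a 5-s window
  centred on 60 s of recovery;
* ``HRR_τ`` / ``HRR_amp``: time constant and amplitude of a first-order
  exponential fitted to the 6-min recovery;
* ``T30``: −1/slope of ln(HR) regressed on time over seconds 10–40 of
  recovery (natural log), a short-term vagal-reactivation index;
* ``RMSSD_30s``: root mean square of successive R-R differences in
  consecutive 30-s recovery segments, with the 3-point median filter
  applied to interior segments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .data import CombatProtocol, RRSeries

__all__ = [
    "Tachogram",
    "HRRIndices",
    "RMSSDTrace",
    "HRSummary",
    "hr_from_rr",
    "end_exercise_hr",
    "hrr_60s",
    "fit_hrr_exponential",
    "t30",
    "rmssd_30s",
    "median_filter3",
    "hr_round_summary",
    "hrr_indices",
]

T30_SENTINEL = math.inf  # reported when HR is not falling over 10–40 s


@dataclass
class Tachogram:
    """Instantaneous HR (bpm) on a uniform grid; t=0 at cessation."""

    time: np.ndarray  # s, relative to exercise cessation
    hr: np.ndarray  # bpm
    dt: float

    def window(self, start: float, end: float, closed: bool = False) -> np.ndarray:
        mask = (self.time >= start) & ((self.time <= end) if closed else (self.time < end))
        if not mask.any():
            raise ValueError(f"no tachogram samples in [{start}, {end}]")
        return self.hr[mask]


def hr_from_rr(series: RRSeries, dt: float = 1.0) -> Tachogram:
    """Instantaneous HR (60000/RR at each beat) interpolated to a dt grid."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t_beat = series.recovery_times
    hr_beat = 60000.0 / series.rr
    t0 = math.ceil(t_beat[0] / dt) * dt
    n = int(math.floor((t_beat[-1] - t0) / dt)) + 1
    if n < 2:
        raise ValueError("R-R series too short to grid")
    grid = t0 + dt * np.arange(n)
    return Tachogram(grid, np.interp(grid, t_beat, hr_beat), dt)


def end_exercise_hr(tacho: Tachogram) -> float:
    """Mean HR over the final 5 s of exercise, [−5, 0)."""
    if tacho.time[0] > -5.0:
        raise ValueError("tachogram lacks 5 s of pre-cessation data")
    return float(np.mean(tacho.window(-5.0, 0.0)))


def hrr_60s(tacho: Tachogram) -> float:
    """Beats recovered in 60 s: end-exercise HR minus the 5-s mean at 60 s.

    The 5-s window at 60 s is centred (57.5–62.5 s).
    """
    if tacho.time[-1] < 62.5:
        raise ValueError("tachogram lacks 65 s of recovery")
    at60 = float(np.mean(tacho.window(57.5, 62.5, closed=True)))
    return end_exercise_hr(tacho) - at60


def fit_hrr_exponential(tacho: Tachogram, window: float = 360.0) -> tuple[float, float, float]:
    """First-order exponential fit of recovery HR over [0, window].

    Returns ``(tau, amplitude, asymptote)`` of
    HR(t) = asymptote + amplitude·exp(−t/τ).  A flat recovery is
    degenerate: amplitude 0 and τ = NaN.
    """
    if tacho.time[-1] < window - tacho.dt:
        raise ValueError(f"recovery does not cover the {window:g}-s fit window")
    mask = (tacho.time >= 0) & (tacho.time <= window)
    t, hr = tacho.time[mask], tacho.hr[mask]
    rng = float(np.max(hr) - np.min(hr))
    if rng < 1e-9:
        return math.nan, 0.0, float(np.mean(hr))

    def model(tt, asym, amp, tau):
        return asym + amp * np.exp(-tt / tau)

    best, best_rss = None, math.inf
    for tau0 in (30.0, 60.0, 120.0):
        try:
            p, _ = curve_fit(
                model, t, hr,
                p0=[float(np.min(hr)), rng, tau0],
                bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 5000.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hr - model(t, *p)) ** 2))
        if rss < best_rss:
            best, best_rss = p, rss
    if best is None:
        raise RuntimeError("exponential HRR fit did not converge")
    asym, amp, tau = best
    return float(tau), float(amp), float(asym)


def t30(tacho: Tachogram) -> float:
    """Short-term time constant: −1/slope of ln(HR) over 10–40 s.

    Uses the 1-s grid samples and the natural log.  If HR is not
    falling (slope ≥ 0) the index is undefined and +inf is returned.
    """
    if tacho.time[-1] < 40.0 or tacho.time[0] > 10.0:
        raise ValueError("tachogram does not cover seconds 10-40 of recovery")
    mask = (tacho.time >= 10.0) & (tacho.time <= 40.0)
    res = linregress(tacho.time[mask], np.log(tacho.hr[mask]))
    if res.slope >= 0:
        return T30_SENTINEL
    return -1.0 / res.slope


@dataclass
class RMSSDTrace:
    """RMSSD (ms) per successive 30-s recovery segment."""

    segment_start: np.ndarray  # s
    rmssd: np.ndarray  # ms; NaN where the segment had < 3 beats
    filtered: bool = False

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.rmssd)


def rmssd(rr: np.ndarray) -> float:
    """RMSSD (ms) of one R-R sequence: translation-invariant by construction."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 beats")
    d = np.diff(rr)
    return math.sqrt(float(np.mean(d**2)))


def rmssd_30s(series: RRSeries, recovery_duration: float = 360.0, segment: float = 30.0) -> RMSSDTrace:
    """RMSSD of successive R-R differences per 30-s recovery segment.

    Beats belong to the segment containing their R-wave time; each
    segment's first difference pairs its first beat with the last beat
    of the preceding segment, so no successive pair is lost.  Segments
    with fewer than 3 beats are flagged invalid (NaN).
    """
    t = series.recovery_times
    rr = series.rr
    if t[-1] < segment:
        raise ValueError("recovery span shorter than one segment")
    n_seg = int(recovery_duration // segment)
    starts = segment * np.arange(n_seg)
    out = np.full(n_seg, np.nan)
    for i, s in enumerate(starts):
        in_seg = (t >= s) & (t < s + segment)
        idx = np.flatnonzero(in_seg)
        if idx.size < 3:
            continue
        lo = idx[0] - 1 if idx[0] > 0 and t[idx[0] - 1] >= 0 else idx[0]
        d = np.diff(rr[lo : idx[-1] + 1])
        out[i] = math.sqrt(float(np.mean(d**2)))
    return RMSSDTrace(starts, out)


def median_filter3(trace: RMSSDTrace) -> RMSSDTrace:
    """In-place 3-point median smoothing; first and last values untouched.

    Each interior value is replaced, left to right, by the median of
    the (already smoothed) preceding value, itself and the following
    value.  This in-place variant reaches a root signal in a single
    pass, so the operation is idempotent.  Invalid (NaN) segments are
    left as-is.  Traces with fewer than 3 segments return unchanged.
    """
    x = trace.rmssd.copy()
    for i in range(1, x.size - 1):
        triple = np.array([x[i - 1], trace.rmssd[i], trace.rmssd[i + 1]])
        if not np.isnan(triple).any():
            x[i] = float(np.median(triple))
    return RMSSDTrace(trace.segment_start.copy(), x, filtered=True)


@dataclass
class HRSummary:
    """Per-round mean and peak HR (peak = max 5-s rolling mean), bpm."""

    hr_mean: list[float] = field(default_factory=list)
    hr_peak: list[float] = field(default_factory=list)


def hr_round_summary(tacho: Tachogram, protocol: CombatProtocol, t0_protocol: float | None = None) -> HRSummary:
    """Round-wise HR_mean and HR_peak from a combat tachogram.

    ``t0_protocol`` is where combat start (protocol t=0) falls on the
    tachogram's cessation-anchored axis; by default the cessation is the
    end of the final round, i.e. ``-combat_end``.
    """
    offset = -protocol.combat_end if t0_protocol is None else t0_protocol
    win = max(1, int(round(5.0 / tacho.dt)))
    summ = HRSummary()
    for k in range(1, protocol.n_rounds + 1):
        start, end = protocol.round_window(k)
        hr = tacho.window(start + offset, end + offset)
        if hr.size < win:
            raise ValueError(f"round {k} not covered by tachogram")
        kernel = np.ones(win) / win
        rolling = np.convolve(hr, kernel, mode="valid")
        summ.hr_mean.append(float(np.mean(hr)))
        summ.hr_peak.append(float(np.max(rolling)))
    return summ


@dataclass
class HRRIndices:
    """All parasympathetic-reactivation indices for one recovery."""

    hrr_60s: float
    t30: float
    tau: float
    amplitude: float
    asymptote: float
    flagged: bool = False


def hrr_indices(series: RRSeries, recovery_duration: float = 360.0) -> HRRIndices:
    """One-call computation of HRR_60s, T30, HRR_τ/amp for a recovery."""
    tacho = hr_from_rr(series)
    tau, amp, asym = fit_hrr_exponential(tacho, window=recovery_duration)
    drop = hrr_60s(tacho)
    tt30 = t30(tacho)
    flagged = drop < 0 or not math.isfinite(tt30) or not math.isfinite(tau)
    return HRRIndices(drop, tt30, tau, amp, asym, flagged)
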