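"""Energy-system partitioning from oxygen uptake and blood lactate.

Three systems are estimated per round:

* oxidative (``W_AER``): trapezoidal integral of net VO2 (above the
  pre-warm-up resting value, floored at zero) over the round;
* ATP-PCr (``W_PCR``): for rounds followed by a rest interval, the net
  VO2 integral over that interval; for the final round, the analytic
  area ``A·τ`` of the fast component of excess post-exercise oxygen
  consumption, fitted as a mono-exponential (a bi-exponential fit is
  tried and kept only when its slow amplitude is non-negligible, in
  which case W_PCR still uses the fast term alone);
* glycolytic (``W_[La-]``): the round's blood-lactate accumulation
  converted at 3 mL O2 per kg body mass per mmol·L⁻¹.

All O2 volumes convert to energy at the caloric quotient of
20.92 kJ per litre of O2.  Breath data are linearly interpolated to a
1-s grid before any integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as sps_f

from .data import Athlete, BreathSeries, CombatProtocol, LactateSamples

__all__ = [
    "KJ_PER_L_O2",
    "LACTATE_O2_ML_PER_KG",
    "ExpFit",
    "FitError",
    "EnergyPartition",
    "LactateDeltas",
    "resting_vo2",
    "round_vo2_mean",
    "aerobic_energy",
    "fit_epoc",
    "pcr_energy",
    "lactate_deltas",
    "glycolytic_energy",
    "partition_energy",
    "condition_round_means",
    "round1",
]

KJ_PER_L_O2 = 20.92  # caloric quotient, kJ per litre O2
LACTATE_O2_ML_PER_KG = 3.0  # mL O2 per kg per mmol/L lactate accumulated
INTEGRATION_DT = 1.0  # s; grid for all trapezoidal integrals

# slow component below this fraction of the fast amplitude is negligible
BI_SLOW_NEGLIGIBLE_FRAC = 0.05


class FitError(RuntimeError):
    """Exponential fit failed to converge; carries the best residual."""

    def __init__(self, msg: str, best_rss: float = math.inf):
        super().__init__(msg)
        self.best_rss = best_rss


@dataclass
class ExpFit:
    """Mono- or bi-exponential decay fit of recovery VO2.

    ``vo2(t) = baseline + A·exp(−t/τ) [+ A2·exp(−t/τ2)]`` with t in
    seconds from recovery onset, amplitudes in mL·min⁻¹.  For a bi fit
    the slow term satisfies ``tau2 > tau``.
    """

    amplitude_A: float
    tau: float
    baseline: float
    model: str = "mono"
    amplitude_A2: float = 0.0
    tau2: float = math.nan
    rss: float = math.nan
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.tau <= 0:
                raise ValueError("tau must be > 0")
            if self.amplitude_A < 0:
                raise ValueError("amplitude must be >= 0")
            if self.model == "bi" and not self.tau2 > self.tau:
                raise ValueError("bi model requires tau2 > tau")

    @property
    def fast_o2_volume_l(self) -> float:
        """Analytic O2 volume of the fast component over [0, ∞), litres."""
        if self.degenerate:
            return 0.0
        return self.amplitude_A / 60.0 * self.tau / 1000.0


def _grid_values(series: BreathSeries, start: float, end: float, dt: float = INTEGRATION_DT):
    """VO2 interpolated onto a dt grid spanning exactly [start, end]."""
    t = series.time
    if t[0] > start + 1e-9 or t[-1] < end - 1e-9:
        raise ValueError(
            f"series does not cover [{start:g}, {end:g}] s (have [{t[0]:g}, {t[-1]:g}])"
        )
    n = int(round((end - start) / dt))
    grid = start + dt * np.arange(n + 1)
    if grid[-1] < end - 1e-9:
        grid = np.append(grid, end)
    return grid, np.interp(grid, t, series.vo2)


def resting_vo2(series: BreathSeries, protocol: CombatProtocol) -> float:
    """Mean VO2 (mL·min⁻¹) over the pre-warm-up baseline rest window."""
    base = series.in_phase("rest_baseline")
    if base.time[-1] - base.time[0] < 60.0:
        raise ValueError("rest baseline shorter than 60 s")
    return float(np.mean(base.vo2))


def round_vo2_mean(
    series: BreathSeries,
    round_index: int,
    body_mass: float,
    protocol: CombatProtocol | None = None,
) -> float:
    """Time-weighted mean round VO2, mL·kg⁻¹·min⁻¹."""
    protocol = protocol or CombatProtocol()
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    start, end = protocol.round_window(round_index)
    grid, v = _grid_values(series, start, end)
    mean = float(np.trapezoid(v, grid) / (end - start))
    return mean / body_mass


def aerobic_energy(
    series: BreathSeries,
    vo2_rest: float,
    round_index: int,
    protocol: CombatProtocol | None = None,
) -> float:
    """Oxidative energy of one round (kJ): net-VO2 trapezoid above rest."""
    protocol = protocol or CombatProtocol()
    start, end = protocol.round_window(round_index)
    return _net_o2_energy(series, vo2_rest, start, end)


def _net_o2_energy(series: BreathSeries, vo2_rest: float, start: float, end: float) -> float:
    grid, v = _grid_values(series, start, end)
    net = np.maximum(v - vo2_rest, 0.0)  # mL/min; negative dips are unphysical
    ml = np.trapezoid(net, grid) / 60.0  # (mL/min)·s → mL
    return ml / 1000.0 * KJ_PER_L_O2


def _mono(t, base, a, tau):
    return base + a * np.exp(-t / tau)


def _bi(t, base, a1, tau1, a2, dtau):
    return base + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / (tau1 + dtau))


def fit_epoc(recovery: BreathSeries, vo2_rest: float, t0: float | None = None) -> ExpFit:
    """Fit post-exercise VO2 decay; mono unless the slow phase matters.

    ``t0`` anchors the decay's time origin (exercise cessation); it
    defaults to the first sample, but passing the true recovery onset
    matters when the first breath lands a little late — the amplitude
    is defined at the onset.  Multistart nonlinear least squares (τ
    started at 20/40/80 s).  A bi-exponential fit is attempted; it is
    reported only when it improves the fit beyond noise (nested-model
    F-test), its slow amplitude reaches 5% of the fast amplitude, and
    its slow τ is identifiable within the window — otherwise the mono
    model stands.  A flat recovery is flagged degenerate (amplitude 0,
    τ unidentifiable).
    """
    t = recovery.time - (recovery.time[0] if t0 is None else t0)
    v = recovery.vo2
    if t[-1] < 180.0:
        raise ValueError("recovery shorter than 180 s; cannot fit EPOC")
    rng = np.max(v) - np.min(v)
    scale = max(np.mean(v), 1.0)
    if rng < 1e-6 * scale:
        return ExpFit(0.0, math.nan, float(np.mean(v)), rss=0.0, degenerate=True)

    best = None
    best_rss = math.inf
    for tau0 in (20.0, 40.0, 80.0):
        try:
            p, _ = curve_fit(
                _mono,
                t,
                v,
                p0=[max(np.min(v), 1.0), max(rng, 1.0), tau0],
                bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 2000.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((v - _mono(t, *p)) ** 2))
        if rss < best_rss:
            best, best_rss = p, rss
    if best is None:
        raise FitError("mono-exponential EPOC fit did not converge", best_rss)
    base, a, tau = best
    if a < 1e-3 * scale:
        return ExpFit(0.0, math.nan, float(base), rss=best_rss, degenerate=True)

    bi = _fit_bi(t, v, base, a, tau)
    if bi is not None:
        (bbase, a1, tau1, a2, dtau), bi_rss = bi
        n = t.size
        # nested-model F-test: does the slow term improve the fit beyond
        # noise?  A long-tau slow term is also confounded with the free
        # baseline over a finite window, so its tau must sit inside it.
        if bi_rss > 0 and n > 5:
            f_stat = ((best_rss - bi_rss) / 2.0) / (bi_rss / (n - 5))
            p_improve = float(sps_f.sf(f_stat, 2, n - 5)) if f_stat > 0 else 1.0
        else:
            p_improve = 1.0
        identifiable = (tau1 + dtau) < (t[-1] - t[0])
        if p_improve < 0.01 and identifiable and a2 >= BI_SLOW_NEGLIGIBLE_FRAC * a1:
            return ExpFit(
                float(a1), float(tau1), float(bbase),
                model="bi", amplitude_A2=float(a2), tau2=float(tau1 + dtau), rss=bi_rss,
            )
    return ExpFit(float(a), float(tau), float(base), rss=best_rss)


def _fit_bi(t, v, base0, a0, tau0):
    try:
        p, _ = curve_fit(
            _bi,
            t,
            v,
            p0=[base0, a0, min(tau0, 60.0), 0.05 * a0, 300.0],
            bounds=([0.0, 0.0, 1.0, 0.0, 1.0], [np.inf, np.inf, 2000.0, np.inf, 5000.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return None
    rss = float(np.sum((v - _bi(t, *p)) ** 2))
    return p, rss


def pcr_energy(
    series: BreathSeries,
    fit: ExpFit | None,
    vo2_rest: float,
    round_index: int,
    protocol: CombatProtocol | None = None,
) -> float:
    """ATP-PCr energy of one round (kJ).

    Rounds followed by a rest interval use the net-VO2 trapezoid over
    that interval; the final round uses the analytic fast-component
    area A·τ of the fitted post-exercise decay.
    """
    protocol = protocol or CombatProtocol()
    protocol._check_round(round_index)
    if round_index < protocol.n_rounds:
        start, end = protocol.interval_window(round_index)
        return _net_o2_energy(series, vo2_rest, start, end)
    if fit is None:
        raise ValueError("final-round W_PCR requires an EPOC fit")
    return fit.fast_o2_volume_l * KJ_PER_L_O2


@dataclass
class LactateDeltas:
    """Per-round lactate accumulation and the observed peak (mmol·L⁻¹)."""

    delta: list[float]
    peak: float


def lactate_deltas(samples: LactateSamples, n_rounds: int = 3) -> LactateDeltas:
    """Round-wise lactate accumulation: post-round minus round-start value."""
    labels = ["post_warmup"] + [f"post_round_{k}" for k in range(1, n_rounds + 1)]
    samples.require(labels)
    deltas = [samples[labels[k]] - samples[labels[k - 1]] for k in range(1, n_rounds + 1)]
    peak_labels = labels[1:] + [l for l in ("recovery_1min", "recovery_3min", "recovery_5min") if l in samples]
    peak = max(samples[l] for l in peak_labels)
    return LactateDeltas(deltas, float(peak))


def glycolytic_energy(delta: float, body_mass: float) -> float:
    """Glycolytic energy (kJ) from one round's lactate accumulation.

    Negative deltas (net clearance) contribute zero energy.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    o2_l = max(delta, 0.0) * LACTATE_O2_ML_PER_KG * body_mass / 1000.0
    return o2_l * KJ_PER_L_O2


@dataclass
class EnergyPartition:
    """Per-round energy by system (kJ) plus relative contributions (%)."""

    w_aer: list[float]
    w_pcr: list[float]
    w_la: list[float]
    epoc_fit: ExpFit | None = None
    degenerate_rounds: list[int] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.w_aer)

    @property
    def w_total(self) -> list[float]:
        return [a + p + l for a, p, l in zip(self.w_aer, self.w_pcr, self.w_la)]

    def relative(self) -> tuple[list[float], list[float], list[float]]:
        """Per-round percentage contributions; NaN for all-zero rounds."""
        rel_a, rel_p, rel_l = [], [], []
        for a, p, l, tot in zip(self.w_aer, self.w_pcr, self.w_la, self.w_total):
            if tot <= 0:
                rel_a.append(math.nan), rel_p.append(math.nan), rel_l.append(math.nan)
            else:
                rel_a.append(100 * a / tot), rel_p.append(100 * p / tot), rel_l.append(100 * l / tot)
        return rel_a, rel_p, rel_l

    @property
    def totals(self) -> dict[str, float]:
        return {
            "w_aer_kj": sum(self.w_aer),
            "w_pcr_kj": sum(self.w_pcr),
            "w_la_kj": sum(self.w_la),
            "w_total_kj": sum(self.w_total),
        }


def partition_energy(
    athlete: Athlete,
    series: BreathSeries,
    samples: LactateSamples,
    protocol: CombatProtocol | None = None,
) -> EnergyPartition:
    """Full per-round three-system energy partition for one bout."""
    protocol = protocol or CombatProtocol()
    vrest = resting_vo2(series, protocol)
    rec_start, rec_end = protocol.recovery_window
    recovery = series.in_window(rec_start, rec_end)
    fit = fit_epoc(recovery, vrest, t0=rec_start)
    deltas = lactate_deltas(samples, protocol.n_rounds)

    w_aer, w_pcr, w_la = [], [], []
    for k in range(1, protocol.n_rounds + 1):
        w_aer.append(aerobic_energy(series, vrest, k, protocol))
        w_pcr.append(pcr_energy(series, fit, vrest, k, protocol))
        w_la.append(glycolytic_energy(deltas.delta[k - 1], athlete.body_mass))
    part = EnergyPartition(w_aer, w_pcr, w_la, epoc_fit=fit)
    part.degenerate_rounds = [k + 1 for k, tot in enumerate(part.w_total) if tot <= 0]
    return part


def condition_round_means(values) -> tuple[float, float]:
    """Mean ± SD across per-round values, reported to one decimal.

    Rounding is half-to-even so printed tables are reproduced
    deterministically.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no round values supplied")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return round1(float(np.mean(arr))), round1(sd)


def round1(x: float) -> float:
    """Round to one decimal, half-to-even (report-table precision)."""
    return float(np.round(x, 1))
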