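"""Core data types for round-based combat protocols.

Time convention: seconds, 0 at the start of round 1 ("combat start").
Everything before the combat (baseline rest, warm-up) sits at negative
times; the post-combat recovery window follows the final round.  All
phase windows are half-open ``[start, end)`` so every instant belongs to
exactly one phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CombatProtocol",
    "Athlete",
    "BreathSeries",
    "RRSeries",
    "LactateSamples",
    "LACTATE_LABELS",
    "segment_phases",
    "resample_uniform",
]


@dataclass(frozen=True)
class CombatProtocol:
    """Timing structure of a simulated combat.

    The default mirrors an official-rules bout: three 2-min rounds
    separated by 1-min passive rests, a 5-min warm-up ending 5 min
    before the first round, and a 6-min seated recovery after the last
    round.  The 5-min baseline rest window is taken to be the 5 minutes
    immediately preceding the warm-up.
    """

    n_rounds: int = 3
    round_duration: float = 120.0
    rest_duration: float = 60.0
    warmup_window: tuple[float, float] = (-600.0, -300.0)
    recovery_duration: float = 360.0
    baseline_duration: float = 300.0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        for name in ("round_duration", "rest_duration", "recovery_duration", "baseline_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.warmup_window[1] <= self.warmup_window[0]:
            raise ValueError("warmup_window must have end > start")
        if self.warmup_window[1] > 0:
            raise ValueError("warm-up must end before combat start (t=0)")

    # -- phase windows -------------------------------------------------
    @property
    def baseline_window(self) -> tuple[float, float]:
        start = self.warmup_window[0]
        return (start - self.baseline_duration, start)

    def round_window(self, k: int) -> tuple[float, float]:
        """Half-open window of round ``k`` (1-based)."""
        self._check_round(k)
        start = (k - 1) * (self.round_duration + self.rest_duration)
        return (start, start + self.round_duration)

    def interval_window(self, k: int) -> tuple[float, float]:
        """Rest interval following round ``k`` (only k < n_rounds)."""
        self._check_round(k)
        if k >= self.n_rounds:
            raise ValueError(f"no rest interval after final round {k}")
        start = self.round_window(k)[1]
        return (start, start + self.rest_duration)

    @property
    def combat_end(self) -> float:
        return self.round_window(self.n_rounds)[1]

    @property
    def recovery_window(self) -> tuple[float, float]:
        return (self.combat_end, self.combat_end + self.recovery_duration)

    def phase_marks(self) -> list[tuple[str, float, float]]:
        """Ordered (label, start, end) covering baseline → recovery."""
        marks = [
            ("rest_baseline", *self.baseline_window),
            ("warmup", *self.warmup_window),
        ]
        if self.warmup_window[1] < 0:
            marks.append(("pre_combat", self.warmup_window[1], 0.0))
        for k in range(1, self.n_rounds + 1):
            marks.append((f"round_{k}", *self.round_window(k)))
            if k < self.n_rounds:
                marks.append((f"interval_{k}", *self.interval_window(k)))
        marks.append(("recovery", *self.recovery_window))
        return marks

    def _check_round(self, k: int) -> None:
        if not 1 <= k <= self.n_rounds:
            raise ValueError(f"round index {k} outside 1..{self.n_rounds}")


@dataclass(frozen=True)
class Athlete:
    id: str
    body_mass: float  # kg
    condition: str = "PLA"  # {CAF, PLA}

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")


class BreathSeries:
    """Timestamped oxygen-uptake samples with optional phase labels.

    ``vo2`` is absolute uptake in mL·min⁻¹ (per-kg views are computed on
    demand by downstream code); ``time`` is seconds from combat start and
    must be strictly increasing.
    """

    def __init__(
        self,
        time: Sequence[float],
        vo2: Sequence[float],
        phase: Sequence[str] | None = None,
    ) -> None:
        self.time = np.asarray(time, dtype=float)
        self.vo2 = np.asarray(vo2, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.vo2.shape:
            raise ValueError("time and vo2 must be 1-D arrays of equal length")
        bad = np.flatnonzero(np.diff(self.time) <= 0)
        if bad.size:
            raise ValueError(f"time not strictly increasing at row {bad[0] + 1}")
        neg = np.flatnonzero(self.vo2 < 0)
        if neg.size:
            raise ValueError(f"negative VO2 at row {neg[0]}")
        self.phase = None if phase is None else np.asarray(phase, dtype=object)
        if self.phase is not None and self.phase.shape != self.time.shape:
            raise ValueError("phase must align with time")

    def __len__(self) -> int:
        return self.time.size

    def in_phase(self, label: str) -> "BreathSeries":
        """Sub-series of all samples labelled ``label`` (phases required)."""
        if self.phase is None:
            raise ValueError("series has no phase labels; run segment_phases first")
        mask = self.phase == label
        if not mask.any():
            raise ValueError(f"no samples in phase {label!r}")
        return BreathSeries(self.time[mask], self.vo2[mask], self.phase[mask])

    def in_window(self, start: float, end: float) -> "BreathSeries":
        """Sub-series with start <= t < end."""
        mask = (self.time >= start) & (self.time < end)
        if not mask.any():
            raise ValueError(f"no samples in window [{start}, {end})")
        phase = None if self.phase is None else self.phase[mask]
        return BreathSeries(self.time[mask], self.vo2[mask], phase)


def segment_phases(series: BreathSeries, protocol: CombatProtocol) -> BreathSeries:
    """Assign every sample its protocol phase.

    Windows are half-open, so a breath landing exactly on a round's end
    belongs to the following interval.  Samples before the baseline or
    after recovery are labelled ``pre``/``post``.  The series must cover
    the combat span (round 1 through the end of recovery).
    """
    t = series.time
    rec_end = protocol.recovery_window[1]
    if t[0] > 0 or t[-1] < rec_end:
        raise ValueError(
            "series does not cover the protocol span: "
            f"need [0, {rec_end:g}] s, have [{t[0]:g}, {t[-1]:g}] s"
        )
    labels = np.full(t.shape, "post", dtype=object)
    labels[t < rec_end] = "pre"
    for name, start, end in protocol.phase_marks():
        labels[(t >= start) & (t < end)] = name
    return BreathSeries(t, series.vo2, labels)


def resample_uniform(series: BreathSeries, dt: float) -> BreathSeries:
    """Linear interpolation onto a uniform grid; endpoints preserved.

    The grid starts at the first sample and steps by ``dt``; if the final
    sample does not land on the grid it is appended so the series span is
    unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(series) < 2:
        raise ValueError("need at least 2 samples to resample")
    t0, t1 = series.time[0], series.time[-1]
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    vo2 = np.interp(grid, series.time, series.vo2)
    return BreathSeries(grid, vo2)


@dataclass
class RRSeries:
    """Beat-to-beat R-R intervals (ms) anchored to exercise cessation.

    ``t0`` is the time, in seconds from the start of the series, at which
    exercise stops; beat times relative to cessation are therefore
    ``cumsum(rr)/1000 - t0``.  A pure recovery recording has ``t0 = 0``.
    """

    rr: np.ndarray  # ms
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1 or self.rr.size == 0:
            raise ValueError("rr must be a non-empty 1-D array")
        if (self.rr <= 0).any():
            i = int(np.flatnonzero(self.rr <= 0)[0])
            raise ValueError(f"non-positive R-R interval at beat {i}")

    @property
    def beat_times(self) -> np.ndarray:
        """Time of each beat, seconds from series start."""
        return np.cumsum(self.rr) / 1000.0

    @property
    def recovery_times(self) -> np.ndarray:
        """Beat times relative to exercise cessation (s)."""
        return self.beat_times - self.t0

    @property
    def span(self) -> float:
        return float(self.beat_times[-1])


LACTATE_LABELS = (
    "pre_warmup",
    "post_warmup",
    "post_round_1",
    "post_round_2",
    "post_round_3",
    "recovery_1min",
    "recovery_3min",
    "recovery_5min",
)


@dataclass
class LactateSamples:
    """Capillary blood-lactate samples keyed by protocol label (mmol·L⁻¹)."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in self.values.items():
            if label not in LACTATE_LABELS:
                raise ValueError(f"unknown lactate label {label!r}")
            if v < 0:
                raise ValueError(f"negative lactate for {label!r}")

    def __getitem__(self, label: str) -> float:
        if label not in self.values:
            raise KeyError(f"missing lactate sample {label!r}")
        return self.values[label]

    def __contains__(self, label: str) -> bool:
        return label in self.values

    def require(self, labels: Iterable[str]) -> None:
        missing = [l for l in labels if l not in self.values]
        if missing:
            raise ValueError(f"missing lactate sample(s): {', '.join(missing)}")
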