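"""Time-motion indices from attack/stepping/pause event logs.

Events are coded to a tenth of a second; durations are snapped to the
0.1-s grid and summed as integer tenths so repeated aggregation cannot
drift.  Per round we report mean attack time (AT), mean stepping time
(ST), their sums, the attack count (AN) and the AT:ST ratio of the
per-round mean durations.  Inter-pass coding reliability is an
intraclass correlation on paired values from two analysis passes.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

__all__ = ["TimeMotionRow", "summarize_round", "summarize_log", "icc_two_pass"]


@dataclass
class TimeMotionRow:
    """Per-round time-motion indices (seconds; AN is a count)."""

    round: int
    attack_time_mean: float  # AT
    stepping_time_mean: float  # ST
    attack_time_sum: float
    stepping_time_sum: float
    pause_time_sum: float
    attack_number: int  # AN
    at_st_ratio: float  # AT / ST of mean durations; NaN if degenerate


def _tenths(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) * 10).astype(np.int64)


def summarize_round(log: pd.DataFrame, round_index: int, pass_id: int = 1) -> TimeMotionRow:
    """Indices for one round of one coding pass.

    Overlapping entries within the round are rejected (coding error).
    Rounds without attacks get AN = 0 and NaN mean attack time.
    """
    sub = log[(log["round"] == round_index) & (log["pass_id"] == pass_id)]
    if sub.empty:
        raise ValueError(f"round {round_index} (pass {pass_id}) absent from event log")
    start = _tenths(sub["start_s"].to_numpy())
    end = _tenths(sub["end_s"].to_numpy())
    order = np.argsort(start)
    overlap = np.flatnonzero(start[order][1:] < end[order][:-1])
    if overlap.size:
        i = order[overlap[0]], order[overlap[0] + 1]
        raise ValueError(
            f"overlapping events in round {round_index}: rows {sub.index[i[0]]} and {sub.index[i[1]]}"
        )
    dur = (end - start) / 10.0
    kinds = sub["kind"].to_numpy()

    def agg(kind: str) -> tuple[float, float, int]:
        d = dur[kinds == kind]
        if d.size == 0:
            return math.nan, 0.0, 0
        return float(np.mean(d)), float(np.sum(d)), int(d.size)

    at, at_sum, an = agg("attack")
    st, st_sum, _ = agg("stepping")
    _, pt_sum, _ = agg("pause")
    ratio = at / st if st and not math.isnan(at) and not math.isnan(st) else math.nan
    return TimeMotionRow(round_index, at, st, at_sum, st_sum, pt_sum, an, ratio)


def summarize_log(log: pd.DataFrame, n_rounds: int = 3, pass_id: int = 1) -> pd.DataFrame:
    """All rounds of one pass as a tidy frame (one row per round)."""
    rows = [summarize_round(log, k, pass_id) for k in range(1, n_rounds + 1)]
    return pd.DataFrame([vars(r) for r in rows])


def icc_two_pass(pass1, pass2, form: str = "icc3") -> float:
    """Intraclass correlation between two coding passes of the same items.

    ``form`` selects ICC(3,1) (two-way mixed, consistency; default) or
    ``"icc2"`` for ICC(2,1) (two-way random, absolute agreement),
    single-measure in both cases.
    """
    x = np.asarray(pass1, dtype=float)
    y = np.asarray(pass2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("passes must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    data = np.column_stack([x, y])  # n targets x k=2 raters
    k = 2
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_m - grand) ** 2))
    ss_cols = n * float(np.sum((col_m - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    if ss_tot <= 0:
        raise ValueError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc3":
        denom = msr + (k - 1) * mse
        return (msr - mse) / denom if denom else math.nan
    if form == "icc2":
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        return (msr - mse) / denom if denom else math.nan
    raise ValueError(f"unknown ICC form {form!r}")
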