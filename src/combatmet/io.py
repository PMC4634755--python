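"""CSV readers and writers for the pipeline's input formats.

One documented schema per signal:

* breath table: ``time_s, vo2_ml_min[, phase]``
* R-R file: one interval (ms) per line, or CSV with a ``rr_ms`` column
  (an optional ``t0_s`` comment line ``# t0_s=<v>`` anchors cessation)
* lactate table: ``label, value_mmol_l``
* event log: ``round, kind, start_s, end_s[, pass_id]``
* protocol/athlete config: flat JSON

All files are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    Athlete,
    BreathSeries,
    CombatProtocol,
    LactateSamples,
    RRSeries,
    segment_phases,
)

__all__ = [
    "read_breath_table",
    "write_breath_table",
    "read_rr_series",
    "write_rr_series",
    "read_lactate_table",
    "write_lactate_table",
    "read_event_log",
    "write_event_log",
    "read_config",
    "write_config",
]

EVENT_KINDS = ("attack", "stepping", "pause")


def read_breath_table(path, protocol: CombatProtocol | None = None) -> BreathSeries:
    """Read a breath-by-breath VO2 table.

    If the file carries no ``phase`` column and a protocol is given,
    phases are derived from the protocol timing.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "vo2_ml_min"], path)
    phase = df["phase"].astype(str).to_numpy() if "phase" in df.columns else None
    series = BreathSeries(df["time_s"].to_numpy(float), df["vo2_ml_min"].to_numpy(float), phase)
    if phase is None and protocol is not None:
        series = segment_phases(series, protocol)
    return series


def write_breath_table(series: BreathSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.time, "vo2_ml_min": series.vo2})
    if series.phase is not None:
        df["phase"] = series.phase
    df.to_csv(path, index=False)


def read_rr_series(path) -> RRSeries:
    """Read an R-R interval file (one ms value per line, or CSV ``rr_ms``)."""
    path = Path(path)
    t0 = 0.0
    lines = path.read_text().splitlines()
    body: list[str] = []
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "t0_s=" in s:
                t0 = float(s.split("t0_s=")[1])
            continue
        body.append(s)
    if body and body[0].lower().replace(" ", "").startswith("rr_ms"):
        body = body[1:]
    try:
        rr = np.array([float(b.split(",")[0]) for b in body])
    except ValueError as e:
        raise ValueError(f"unparseable R-R value in {path}: {e}") from None
    return RRSeries(rr, t0=t0)


def write_rr_series(series: RRSeries, path) -> None:
    lines = [f"# t0_s={series.t0!r}", "rr_ms"]
    lines += [repr(float(v)) for v in series.rr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lactate_table(path) -> LactateSamples:
    df = pd.read_csv(path)
    _require_columns(df, ["label", "value_mmol_l"], path)
    labels = df["label"].astype(str)
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise ValueError(f"duplicate lactate label {dup!r} in {path}")
    return LactateSamples(dict(zip(labels, df["value_mmol_l"].astype(float))))


def write_lactate_table(samples: LactateSamples, path) -> None:
    pd.DataFrame(
        {"label": list(samples.values), "value_mmol_l": list(samples.values.values())}
    ).to_csv(path, index=False)


def read_event_log(path) -> pd.DataFrame:
    """Read a time-motion event log into a validated DataFrame."""
    df = pd.read_csv(path)
    _require_columns(df, ["round", "kind", "start_s", "end_s"], path)
    if "pass_id" not in df.columns:
        df["pass_id"] = 1
    df = df.astype({"round": int, "kind": str, "start_s": float, "end_s": float, "pass_id": int})
    bad = ~df["kind"].isin(EVENT_KINDS)
    if bad.any():
        raise ValueError(f"unknown event kind {df.loc[bad, 'kind'].iloc[0]!r} in {path}")
    if (df["end_s"] <= df["start_s"]).any():
        i = int(df.index[df["end_s"] <= df["start_s"]][0])
        raise ValueError(f"event with end <= start at row {i} in {path}")
    return df


def write_event_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_config(path) -> tuple[CombatProtocol, Athlete]:
    """Read a JSON config holding protocol timing and athlete fields."""
    cfg = json.loads(Path(path).read_text())
    proto = cfg.get("protocol", {})
    if "warmup_window" in proto:
        proto["warmup_window"] = tuple(proto["warmup_window"])
    protocol = CombatProtocol(**proto)
    athlete = Athlete(**cfg["athlete"])
    return protocol, athlete


def write_config(protocol: CombatProtocol, athlete: Athlete, path) -> None:
    payload = {"protocol": asdict(protocol), "athlete": asdict(athlete)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
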