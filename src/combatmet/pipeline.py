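"""End-to-end orchestration: subject analysis, study aggregation, tables.

A *subject bundle* (breath series, R-R series, lactate samples, event
log, athlete) flows through segmentation → energetics → cardiac →
time-motion, yielding one :class:`SubjectResult`.  A *study* aggregates
both conditions of every subject into the four report tables
(physiology per round, energy partition, time-motion, recovery
indices) and, when at least two complete crossover subjects exist, the
inferential layer: condition × round repeated-measures ANOVAs and
paired t-tests on the recovery indices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import math
import numpy as np
import pandas as pd

from . import cardiac, energetics, io, stats, timemotion
from .data import Athlete, CombatProtocol
from .simulate import SubjectBundle

__all__ = [
    "SubjectResult",
    "StudyReport",
    "analyze_bundle",
    "run_subject",
    "run_study",
    "write_tables",
    "read_manifest",
]

log = logging.getLogger("combatmet")


@dataclass
class SubjectResult:
    athlete: Athlete
    vo2_round_mean: list[float]  # mL/kg/min
    hr: cardiac.HRSummary
    partition: energetics.EnergyPartition
    hrr: cardiac.HRRIndices
    rmssd: cardiac.RMSSDTrace
    timemotion: pd.DataFrame
    lactate_peak: float


def analyze_bundle(bundle: SubjectBundle, protocol: CombatProtocol | None = None) -> SubjectResult:
    """Run every analysis stage for one subject-condition bundle."""
    protocol = protocol or CombatProtocol()
    ath = bundle.athlete
    series = bundle.breath
    part = energetics.partition_energy(ath, series, bundle.lactate, protocol)
    vo2_rounds = [
        energetics.round_vo2_mean(series, k, ath.body_mass, protocol)
        for k in range(1, protocol.n_rounds + 1)
    ]
    tacho = cardiac.hr_from_rr(bundle.rr)
    hr_summary = cardiac.hr_round_summary(tacho, protocol)
    hrr = cardiac.hrr_indices(bundle.rr, protocol.recovery_duration)
    rmssd = cardiac.median_filter3(cardiac.rmssd_30s(bundle.rr, protocol.recovery_duration))
    tm = timemotion.summarize_log(bundle.events, protocol.n_rounds)
    peak = energetics.lactate_deltas(bundle.lactate, protocol.n_rounds).peak
    return SubjectResult(ath, vo2_rounds, hr_summary, part, hrr, rmssd, tm, peak)


def run_subject(entry: dict, protocol: CombatProtocol | None = None) -> SubjectResult:
    """Analyze one manifest entry (paths to the four signal files)."""
    protocol = protocol or CombatProtocol()
    ath = Athlete(entry["athlete"], float(entry["body_mass"]), entry["condition"])
    bundle = SubjectBundle(
        ath,
        io.read_breath_table(entry["breath_file"], protocol),
        io.read_rr_series(entry["rr_file"]),
        io.read_lactate_table(entry["lactate_file"]),
        io.read_event_log(entry["event_file"]),
        truth={},
    )
    log.info("subject %s/%s: inputs %s", ath.id, ath.condition, _hash_entry(entry))
    return analyze_bundle(bundle, protocol)


@dataclass
class StudyReport:
    table1: pd.DataFrame  # HR / VO2 per round per condition
    table2: pd.DataFrame  # energy partition per round per condition
    table3: pd.DataFrame  # time-motion per round per condition
    table4: pd.DataFrame  # recovery indices per condition
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    paired: dict[str, stats.PairedTestResult] = field(default_factory=dict)
    inferential: bool = False
    metadata: dict = field(default_factory=dict)


def _long(results: list[SubjectResult], fetch) -> pd.DataFrame:
    rows = []
    for r in results:
        for k, v in enumerate(fetch(r), start=1):
            rows.append(
                {"subject": r.athlete.id, "condition": r.athlete.condition, "time": k, "value": v}
            )
    return pd.DataFrame(rows)


_ROUND_VARS = {
    "hr_mean_bpm": lambda r: r.hr.hr_mean,
    "hr_peak_bpm": lambda r: r.hr.hr_peak,
    "vo2_ml_kg_min": lambda r: r.vo2_round_mean,
    "w_aer_kj": lambda r: r.partition.w_aer,
    "w_pcr_kj": lambda r: r.partition.w_pcr,
    "w_la_kj": lambda r: r.partition.w_la,
    "w_total_kj": lambda r: r.partition.w_total,
    "rel_aer_pct": lambda r: r.partition.relative()[0],
    "rel_pcr_pct": lambda r: r.partition.relative()[1],
    "rel_la_pct": lambda r: r.partition.relative()[2],
    "attack_time_s": lambda r: r.timemotion["attack_time_mean"],
    "stepping_time_s": lambda r: r.timemotion["stepping_time_mean"],
    "attack_time_sum_s": lambda r: r.timemotion["attack_time_sum"],
    "stepping_time_sum_s": lambda r: r.timemotion["stepping_time_sum"],
    "attack_number": lambda r: r.timemotion["attack_number"],
    "at_st_ratio": lambda r: r.timemotion["at_st_ratio"],
}

_HRR_VARS = {
    "hrr_60s_bpm": lambda r: r.hrr.hrr_60s,
    "t30_s": lambda r: r.hrr.t30,
    "hrr_tau_s": lambda r: r.hrr.tau,
    "hrr_amp_bpm": lambda r: r.hrr.amplitude,
}


def _mean_sd_table(results: list[SubjectResult], variables: dict) -> pd.DataFrame:
    rows = []
    for var, fetch in variables.items():
        frame = _long(results, fetch)
        g = frame.groupby(["condition", "time"])["value"]
        for (cond, rd), m in g.mean().items():
            rows.append(
                {
                    "variable": var,
                    "condition": cond,
                    "round": rd,
                    "mean": energetics.round1(m),
                    "sd": energetics.round1(g.std().loc[(cond, rd)]) if g.count().loc[(cond, rd)] > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    results: list[SubjectResult],
    protocol: CombatProtocol | None = None,
    anova_vars: tuple[str, ...] = ("vo2_ml_kg_min", "hr_mean_bpm", "w_aer_kj", "w_pcr_kj", "w_la_kj", "attack_number"),
) -> StudyReport:
    """Aggregate subject results into report tables and inference."""
    table1_vars = {k: _ROUND_VARS[k] for k in ("hr_mean_bpm", "hr_peak_bpm", "vo2_ml_kg_min")}
    table2_vars = {
        k: _ROUND_VARS[k]
        for k in ("w_aer_kj", "rel_aer_pct", "w_pcr_kj", "rel_pcr_pct", "w_la_kj", "rel_la_pct", "w_total_kj")
    }
    table3_vars = {
        k: _ROUND_VARS[k]
        for k in (
            "attack_time_s",
            "stepping_time_s",
            "attack_time_sum_s",
            "stepping_time_sum_s",
            "attack_number",
            "at_st_ratio",
        )
    }
    report = StudyReport(
        table1=_mean_sd_table(results, table1_vars),
        table2=_mean_sd_table(results, table2_vars),
        table3=_mean_sd_table(results, table3_vars),
        table4=_table4(results),
    )

    paired_ids = _complete_crossover_ids(results)
    if len(paired_ids) >= 2:
        report.inferential = True
        for var in anova_vars:
            frame = _long([r for r in results if r.athlete.id in paired_ids], _ROUND_VARS[var])
            res = stats.rm_anova(frame)
            tab = stats.rm_anova_table(res)
            tab["variable"] = var
            report.anova[var] = tab
        for var, fetch in _HRR_VARS.items():
            x, y = _paired_values(results, paired_ids, fetch)
            try:
                report.paired[var] = stats.paired_t(x, y)
            except ValueError:
                log.warning("paired t for %s skipped (degenerate differences)", var)
    else:
        log.warning("fewer than 2 complete crossover subjects: descriptive report only")
    report.metadata["n_subjects"] = len({r.athlete.id for r in results})
    report.metadata["n_paired"] = len(paired_ids)
    return report


def _complete_crossover_ids(results: list[SubjectResult]) -> list[str]:
    seen: dict[str, set[str]] = {}
    for r in results:
        seen.setdefault(r.athlete.id, set()).add(r.athlete.condition)
    return sorted(sid for sid, conds in seen.items() if {"CAF", "PLA"} <= conds)


def _paired_values(results, ids, fetch):
    by = {(r.athlete.id, r.athlete.condition): fetch(r) for r in results}
    x = [by[(i, "CAF")] for i in ids]
    y = [by[(i, "PLA")] for i in ids]
    return np.asarray(x, float), np.asarray(y, float)


def _table4(results: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for var, fetch in _HRR_VARS.items():
        for cond in ("CAF", "PLA"):
            vals = [fetch(r) for r in results if r.athlete.condition == cond and math.isfinite(fetch(r))]
            if not vals:
                continue
            rows.append(
                {
                    "variable": var,
                    "condition": cond,
                    "mean": energetics.round1(float(np.mean(vals))),
                    "sd": energetics.round1(float(np.std(vals, ddof=1))) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def write_tables(report: StudyReport, outdir) -> None:
    """Persist all report tables (and inference, if present) as CSV/JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("table1", "table2", "table3", "table4"):
        getattr(report, name).to_csv(out / f"{name}.csv", index=False)
    if report.anova:
        pd.concat(report.anova.values(), ignore_index=True).to_csv(out / "anova.csv", index=False)
    if report.paired:
        payload = {
            var: {
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "mean_diff": r.mean_diff,
                "effect_size": r.effect_size,
                "ci95": list(r.ci95),
            }
            for var, r in report.paired.items()
        }
        (out / "paired_t.json").write_text(json.dumps(payload, indent=2) + "\n")
    (out / "metadata.json").write_text(json.dumps(report.metadata, indent=2) + "\n")


def read_manifest(path) -> list[dict]:
    """Read a study manifest (JSON list of subject-condition entries)."""
    entries = json.loads(Path(path).read_text())
    root = Path(path).parent
    seen = set()
    for e in entries:
        key = (e["athlete"], e["condition"])
        if key in seen:
            raise ValueError(f"duplicate manifest entry {key}")
        seen.add(key)
        for f in ("breath_file", "rr_file", "lactate_file", "event_file"):
            p = root / e[f]
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
            e[f] = str(p)
    return entries


def _hash_entry(entry: dict) -> str:
    h = hashlib.sha256()
    for f in ("breath_file", "rr_file", "lactate_file", "event_file"):
        h.update(Path(entry[f]).read_bytes())
    return h.hexdigest()[:12]
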