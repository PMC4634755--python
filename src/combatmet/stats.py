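"""Repeated-measures inference for two-condition crossover designs.

Implements a two-way fully-within-subjects ANOVA (condition × time)
with the classical sums-of-squares decomposition: each effect is tested
against its own effect-by-subject interaction.  Sphericity of the time
factor is assessed with Mauchly's W; when violated (p < 0.05) the time
and interaction tests use Greenhouse-Geisser corrected degrees of
freedom.  Effect sizes are classical eta-squared (SS_effect/SS_total);
partial eta-squared is available behind a flag.  Pairwise follow-ups
are Bonferroni-adjusted paired t-tests, and single comparisons (HRR
indices) use a paired t with a standardized effect size and a 95% CI
of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "PairedTestResult",
    "rm_anova",
    "rm_anova_table",
    "bonferroni_pairwise",
    "paired_t",
    "check_assumptions",
]


@dataclass
class EffectResult:
    name: str
    ss: float
    ss_err: float
    df_num: float
    df_den: float
    F: float
    p: float
    eta_sq: float
    eta_sq_partial: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected, where applied


@dataclass
class AnovaResult:
    condition: EffectResult
    time: EffectResult
    interaction: EffectResult
    ss_total: float
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    gg_applied: bool = False
    pairwise_time: pd.DataFrame | None = None

    def effects(self) -> list[EffectResult]:
        return [self.condition, self.time, self.interaction]


def _pivot(data: pd.DataFrame, subject: str, condition: str, time: str, value: str) -> np.ndarray:
    """Long frame → complete (n_subjects, a_cond, b_time) cube, or raise."""
    for col in (subject, condition, time, value):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    counts = data.groupby([subject, condition, time], sort=True)[value].count()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(f"design not balanced/complete at cell {bad}: no imputation is done")
    wide = data.pivot_table(index=subject, columns=[condition, time], values=value, sort=True)
    if wide.isna().any().any():
        raise ValueError("missing cells in design; no imputation is done")
    subs = wide.index
    conds = sorted(data[condition].unique())
    times = sorted(data[time].unique())
    cube = np.empty((len(subs), len(conds), len(times)))
    for i, c in enumerate(conds):
        for j, t in enumerate(times):
            cube[:, i, j] = wide[(c, t)].to_numpy()
    return cube


def rm_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    time: str = "time",
    value: str = "value",
) -> AnovaResult:
    """Two-way fully-within ANOVA on a long-format balanced dataset."""
    y = _pivot(data, subject, condition, time, value)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if b < 2:
        raise ValueError("need at least 2 time levels")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_total = float(np.sum((y - grand) ** 2))
    ss_s = a * b * float(np.sum((m_s - grand) ** 2))
    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2))
    ss_sa = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2))
    ss_sb = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2))
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    # clamp float dust so structurally absent effects test as exactly zero
    tiny = 1e-12 * max(ss_total, 1e-300)
    ss_a, ss_b, ss_ab, ss_sa, ss_sb, ss_sab = (
        0.0 if abs(v) < tiny else v for v in (ss_a, ss_b, ss_ab, ss_sa, ss_sb, ss_sab)
    )

    def effect(name, ss_eff, df_eff, ss_err, df_err) -> EffectResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
        p = float(sps.f.sf(F, df_eff, df_err)) if math.isfinite(F) else 0.0
        return EffectResult(
            name, ss_eff, ss_err, df_eff, df_err, float(F), p,
            eta_sq=ss_eff / ss_total if ss_total > 0 else math.nan,
            eta_sq_partial=ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else math.nan,
        )

    eff_a = effect("condition", ss_a, a - 1, ss_sa, (a - 1) * (n - 1))
    eff_b = effect("time", ss_b, b - 1, ss_sb, (b - 1) * (n - 1))
    eff_ab = effect("interaction", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1))

    res = AnovaResult(eff_a, eff_b, eff_ab, ss_total)

    if b >= 3 and n > b - 1:
        w, p_m, eps = _mauchly_gg(y.mean(axis=1))  # time factor, averaged over condition
        res.mauchly_w, res.mauchly_p, res.gg_epsilon = w, p_m, eps
        if p_m is not None and p_m < 0.05:
            res.gg_applied = True
            for eff in (eff_b, eff_ab):
                eff.p_gg = float(sps.f.sf(eff.F, eps * eff.df_num, eps * eff.df_den))
    elif b == 2:
        res.gg_epsilon = 1.0
    return res


def _mauchly_gg(x: np.ndarray) -> tuple[float, float | None, float]:
    """Mauchly's W and Greenhouse-Geisser ε for an (n, k) within matrix."""
    n, k = x.shape
    # orthonormal contrasts via QR of the centering complement
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    z = x @ c
    s = np.cov(z, rowvar=False, ddof=1)
    d = k - 1
    tr = float(np.trace(s))
    eps = tr**2 / (d * float(np.sum(s * s.T)))
    eps = min(max(eps, 1.0 / d), 1.0)
    det = float(np.linalg.det(s))
    mean_var = tr / d
    if det <= 0 or mean_var <= 0:
        return 0.0, 0.0, eps
    w = det / mean_var**d
    df = d * (d + 1) // 2 - 1
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * math.log(w)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else None
    return float(w), p, float(eps)


def bonferroni_pairwise(
    data: pd.DataFrame,
    effect: str,
    subject: str = "subject",
    value: str = "value",
) -> pd.DataFrame:
    """Bonferroni-adjusted paired t-tests over all level pairs of a factor.

    The factor's levels are compared within subject, averaging over the
    other within factor(s); adjusted p = raw p × number of comparisons,
    capped at 1.
    """
    means = data.groupby([subject, effect], sort=True)[value].mean().unstack(effect)
    levels = list(means.columns)
    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        res = paired_t(means[levels[i]].to_numpy(), means[levels[j]].to_numpy())
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "mean_diff": res.mean_diff,
                "t": res.t,
                "df": res.df,
                "p_raw": res.p,
                "p_bonferroni": min(1.0, res.p * m),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    effect_size: float  # Cohen's d_z: mean diff / SD of diffs
    ci95: tuple[float, float]


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test with d_z effect size and 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D, n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    n = d.size
    mean = float(np.mean(d))
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return PairedTestResult(t, df, p, mean, mean / sd, (mean - tcrit * se, mean + tcrit * se))


@dataclass
class AssumptionReport:
    ks_stat: float
    ks_p: float
    levene_stat: float | None = None
    levene_p: float | None = None


def check_assumptions(values, *groups) -> AssumptionReport:
    """Advisory normality (KS vs fitted normal) and Levene homogeneity.

    The pipeline reports these but never branches on them, matching a
    complete-case parametric analysis plan.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    ks = sps.kstest(x, "norm", args=(mu, sd if sd > 0 else 1.0))
    rep = AssumptionReport(float(ks.statistic), float(ks.pvalue))
    if groups:
        lev = sps.levene(x, *[np.asarray(g, dtype=float) for g in groups])
        rep.levene_stat, rep.levene_p = float(lev.statistic), float(lev.pvalue)
    return rep


def rm_anova_table(res: AnovaResult) -> pd.DataFrame:
    """AnovaResult as a tidy one-row-per-effect frame for reports."""
    rows = []
    for eff in res.effects():
        rows.append(
            {
                "effect": eff.name,
                "F": eff.F,
                "df_num": eff.df_num,
                "df_den": eff.df_den,
                "p": eff.p,
                "p_gg": eff.p_gg if eff.p_gg is not None else eff.p,
                "eta_sq": eff.eta_sq,
                "eta_sq_partial": eff.eta_sq_partial,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mauchly_w"] = res.mauchly_w
    df.attrs["mauchly_p"] = res.mauchly_p
    df.attrs["gg_epsilon"] = res.gg_epsilon
    return df
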