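"""Cohort-level statistics: correlations, mixed repeated-measures ANOVA
with sphericity correction, group tests and DaT+/- dichotomization.

The mixed rmANOVA decomposes a balanced subjects-by-levels matrix with one
between-subject grouping factor into the classical sums of squares
(between groups, subjects within groups, within-subject levels, the
level-by-group interaction and the residual).  Sphericity of the
within-subject covariance is quantified by the Greenhouse-Geisser epsilon
(from the double-centred pooled within-group covariance) and its
Huynh-Feldt correction; corrected p-values evaluate F at epsilon-scaled
degrees of freedom.  For a two-level within factor sphericity holds
trivially and epsilon is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import ClinicalRecord

__all__ = [
    "AnovaTable",
    "DatGroups",
    "pearson",
    "mixed_rmanova",
    "mann_whitney_u",
    "dichotomize_dat",
    "ttest",
    "gg_epsilon",
    "hf_epsilon",
]


@dataclass(frozen=True)
class AnovaTable:
    """Effect table of a mixed rmANOVA plus the sphericity epsilons."""

    table: pd.DataFrame
    epsilon_gg: float
    epsilon_hf: float


@dataclass(frozen=True)
class DatGroups:
    """DaT+/- dichotomization of the clinical cohort with group summaries."""

    labels: tuple[str, ...]  # per record, "DaT_minus" or "DaT_plus"
    summary: pd.DataFrame  # indexed by group label
    cutoff: float


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a J x J within-level covariance."""
    cov = np.asarray(cov, dtype=float)
    J = cov.shape[0]
    row = cov.mean(axis=0, keepdims=True)
    col = cov.mean(axis=1, keepdims=True)
    dc = cov - row - col + cov.mean()
    denom = (J - 1) * (dc**2).sum()
    if denom <= 0:
        return 1.0 / (J - 1)
    return float(np.trace(dc) ** 2 / denom)


def hf_epsilon(eps_gg: float, n_subjects: int, n_groups: int, J: int) -> float:
    """Huynh-Feldt correction of the Greenhouse-Geisser epsilon, capped at 1."""
    num = n_subjects * (J - 1) * eps_gg - 2.0
    den = (J - 1) * (n_subjects - n_groups - (J - 1) * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def mixed_rmanova(
    data: np.ndarray,
    group: Sequence,
) -> AnovaTable:
    """Mixed ANOVA: one between-subject factor, one within-subject factor.

    ``data`` is an (n_subjects, J) matrix of a balanced design (every
    subject measured at every level); ``group`` gives each subject's group.
    Corrected p-values for the within and interaction effects use the
    Huynh-Feldt epsilon whenever the Greenhouse-Geisser estimate indicates
    a sphericity violation (eps_GG < 1).
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"data must be (subjects, levels), got shape {Y.shape}")
    if np.isnan(Y).any():
        raise ValueError("unbalanced design: data contains missing cells")
    group = np.asarray(group)
    n, J = Y.shape
    if group.shape != (n,):
        raise ValueError("group must have one label per subject")
    levels, counts = np.unique(group, return_counts=True)
    a = len(levels)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    if J < 2:
        raise ValueError("need at least 2 within-subject levels")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    level_means = Y.mean(axis=0)
    group_means = np.array([Y[group == g].mean() for g in levels])
    cell_means = np.stack([Y[group == g].mean(axis=0) for g in levels])  # (a, J)

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = J * ((subj_means - grand) ** 2).sum()
    ss_group = J * (counts * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_level = n * ((level_means - grand) ** 2).sum()
    ss_inter = (
        counts[:, None]
        * (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
    ).sum()
    ss_err_within = ss_within - ss_level - ss_inter

    df_group = a - 1
    df_subj = n - a
    df_level = J - 1
    df_inter = (a - 1) * (J - 1)
    df_err = (n - a) * (J - 1)

    # pooled within-group covariance of the J levels
    pooled = np.zeros((J, J))
    for g in levels:
        Xg = Y[group == g]
        pooled += (len(Xg) - 1) * np.cov(Xg, rowvar=False)
    pooled /= n - a
    if np.linalg.matrix_rank(pooled) < J - 1:
        warnings.warn(
            "singular within-level covariance: falling back to the "
            "lower-bound epsilon",
            RuntimeWarning,
            stacklevel=2,
        )
        eps_gg = 1.0 / (J - 1)
    else:
        eps_gg = gg_epsilon(pooled)
    eps_gg = float(np.clip(eps_gg, 1.0 / (J - 1), 1.0))
    eps_hf = hf_epsilon(eps_gg, n, a, J)
    eps_hf = float(np.clip(eps_hf, eps_gg, 1.0))

    def _f_p(ss_eff, df_eff, ss_err, df_err_):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err_
        if ms_err <= 0:
            return ms_eff, ms_err, 0.0, 1.0
        F = ms_eff / ms_err
        return ms_eff, ms_err, F, float(sps.f.sf(F, df_eff, df_err_))

    rows = []
    if a > 1:
        ms_g, _, F_g, p_g = _f_p(ss_group, df_group, ss_subj_within, df_subj)
        rows.append(("group", ss_group, df_group, ms_g, F_g, p_g, np.nan, p_g))
    rows.append(
        ("subjects(group)", ss_subj_within, df_subj, ss_subj_within / df_subj,
         np.nan, np.nan, np.nan, np.nan)
    )
    correct = eps_gg < 1.0
    within_effects = [("within", ss_level, df_level)]
    if a > 1:
        within_effects.append(("within*group", ss_inter, df_inter))
    for label, ss_eff, df_eff in within_effects:
        ms_eff, ms_err, F, p = _f_p(ss_eff, df_eff, ss_err_within, df_err)
        if correct and F > 0:
            p_corr = float(sps.f.sf(F, eps_hf * df_eff, eps_hf * df_err))
        else:
            p_corr = p
        rows.append((label, ss_eff, df_eff, ms_eff, F, p, eps_hf, p_corr))
    rows.append(
        ("error(within)", ss_err_within, df_err, ss_err_within / df_err,
         np.nan, np.nan, np.nan, np.nan)
    )
    table = pd.DataFrame(
        rows,
        columns=["effect", "SS", "df", "MS", "F", "p_uncorrected",
                 "epsilon_hf", "p_corrected"],
    )
    return AnovaTable(table=table, epsilon_gg=eps_gg, epsilon_hf=eps_hf)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties and tie-corrected normal p (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def dichotomize_dat(
    records: Sequence[ClinicalRecord], cutoff: float = -2.5
) -> DatGroups:
    """Split the cohort on the age-adjusted putaminal z-score.

    ``DaT_minus`` (depletion suggestive of a neurodegenerative Parkinsonian
    syndrome) iff z_putamen < cutoff, strictly; a z exactly at the cutoff
    is DaT_plus.  Group summaries report n, female count and mean/SD of
    age and UES.
    """
    missing = [r.subject_id for r in records if r.z_putamen is None or np.isnan(r.z_putamen)]
    if missing:
        raise ValueError(f"missing putaminal z-score for subject(s) {missing}")
    labels = tuple(
        "DaT_minus" if r.z_putamen < cutoff else "DaT_plus" for r in records
    )
    rows = {}
    for grp in ("DaT_minus", "DaT_plus"):
        sel = [r for r, lab in zip(records, labels) if lab == grp]
        ages = np.array([r.age for r in sel], dtype=float)
        ues = np.array([r.ues for r in sel], dtype=float)
        rows[grp] = dict(
            n=len(sel),
            n_female=sum(1 for r in sel if r.sex == "F"),
            age_mean=float(ages.mean()) if len(sel) else np.nan,
            age_sd=float(ages.std(ddof=1)) if len(sel) > 1 else np.nan,
            ues_mean=float(ues.mean()) if len(sel) else np.nan,
            ues_sd=float(ues.std(ddof=1)) if len(sel) > 1 else np.nan,
        )
    return DatGroups(
        labels=labels,
        summary=pd.DataFrame.from_dict(rows, orient="index"),
        cutoff=cutoff,
    )


def ttest(
    a: Sequence[float],
    b: Sequence[float],
    sides: str = "two",
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float, float]:
    """t-test returning (t, df, p).

    ``sides``: "two", or one-sided "greater" / "less" for the alternative
    mean(a) > mean(b) / mean(a) < mean(b).  Independent tests pool the
    variance by default (Welch by flag).  When both samples are constant
    and equal, t = 0 and p = 1 by convention.
    """
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}.get(sides)
    if alt is None:
        raise ValueError(f"sides must be 'two', 'greater' or 'less', got {sides!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        res = sps.ttest_rel(a, b, alternative=alt)
        df = len(a) - 1
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch, alternative=alt)
        df = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # degenerate variance with equal means
        t, p = 0.0, 1.0
    return t, float(df), p
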