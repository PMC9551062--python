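"""Reliability and group-contrast statistics for biomarker panels.

Test–retest reliability of a daily biomarker over a week is summarised by
ICC(2,k): the intraclass correlation from a two-way random-effects model
with absolute agreement, for the mean of k repeated days.  Group contrasts
use the Kruskal–Wallis test with Dunn post-hoc comparisons for
non-parametric continuous biomarkers, one-way ANOVA with Tukey HSD for
parametric ones, and the Pearson chi-square test for contingency tables.
Algorithm accuracy against a reference system is reported as mean absolute
percentage error (MAPE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class ICCResult:
    """ICC(2,k) with the mean squares and variance components behind it."""

    icc: float
    model: str
    k: int
    n: int
    var_subject: float
    var_day: float
    var_residual: float


@dataclass
class GroupTestResult:
    """Omnibus test with optional adjusted pairwise table."""

    test: str
    statistic: float
    df: float
    p: float
    pairwise: Optional[pd.DataFrame] = None  # columns: group1, group2, statistic, p_adj


def icc_2k(values: np.ndarray | pd.DataFrame) -> ICCResult:
    """ICC(2,k): two-way random effects, absolute agreement, mean of k days.

    ``values`` is a subjects × days matrix.  Cells may be missing (NaN) up
    to 20%; the mean-squares decomposition is fit on listwise-complete
    subjects.  From the two-way ANOVA mean squares (MSR between subjects,
    MSC between days, MSE residual):

        ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE) / n)

    with variance components σ²_subject = (MSR − MSE)/k,
    σ²_day = (MSC − MSE)/n, σ²_residual = MSE (clipped at zero).
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("values must be a subjects × days matrix")
    missing_frac = np.mean(~np.isfinite(m))
    if missing_frac > 0.20:
        raise ValueError(f"{missing_frac:.0%} missing cells exceeds the 20% allowance")
    complete = np.all(np.isfinite(m), axis=1)
    m = m[complete]
    n, k = m.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 complete subjects")
    if k < 2:
        raise ValueError("ICC needs at least 2 days")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (msc - mse) / n)
    return ICCResult(
        icc=float(icc),
        model="two-way random, absolute agreement, mean of k",
        k=k,
        n=n,
        var_subject=float(max((msr - mse) / k, 0.0)),
        var_day=float(max((msc - mse) / n, 0.0)),
        var_residual=float(max(mse, 0.0)),
    )


def _group_arrays(values: Sequence[float], groups: Sequence) -> dict:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    out = {lab: v[g == lab] for lab in pd.unique(g)}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for lab, arr in out.items():
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has fewer than two observations")
    return out


def kruskal_dunn(
    values: Sequence[float], groups: Sequence, adjust: str = "holm",
    pairwise: bool = True,
) -> GroupTestResult:
    """Kruskal–Wallis omnibus test with Dunn post-hoc pairwise comparisons.

    The Dunn z statistic for groups i, j uses the pooled mid-ranks,

        z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ),

    with the tie correction T = Σ(t³−t) / (12(N−1)); two-sided p-values are
    Holm-adjusted by default.
    """
    by = _group_arrays(values, groups)
    labels = list(by)
    h, p = sp_stats.kruskal(*by.values())
    df = len(by) - 1

    pairwise_table = None
    if pairwise and len(by) >= 3:
        pooled = np.concatenate([by[lab] for lab in labels])
        ranks = sp_stats.rankdata(pooled)
        n_total = len(pooled)
        mean_rank = {}
        pos = 0
        for lab in labels:
            n_g = len(by[lab])
            mean_rank[lab] = ranks[pos: pos + n_g].mean()
            pos += n_g
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
        rows = []
        for a, b in combinations(labels, 2):
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / len(by[a]) + 1.0 / len(by[b]))
            )
            z = (mean_rank[a] - mean_rank[b]) / se
            p_raw = 2 * sp_stats.norm.sf(abs(z))
            rows.append((a, b, float(z), p_raw))
        p_adj = multipletests([r[3] for r in rows], method=adjust)[1]
        pairwise_table = pd.DataFrame(
            [(a, b, z, pa) for (a, b, z, _), pa in zip(rows, p_adj)],
            columns=["group1", "group2", "statistic", "p_adj"],
        )
    return GroupTestResult(
        test="kruskal_wallis+dunn", statistic=float(h), df=df, p=float(p),
        pairwise=pairwise_table,
    )


def anova_tukey(
    values: Sequence[float], groups: Sequence, pairwise: bool = True
) -> GroupTestResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""
    by = _group_arrays(values, groups)
    f, p = sp_stats.f_oneway(*by.values())
    df = len(by) - 1
    pairwise_table = None
    if pairwise and len(by) >= 3:
        v = np.concatenate([by[lab] for lab in by])
        g = np.concatenate([[lab] * len(by[lab]) for lab in by])
        tk = pairwise_tukeyhsd(v, g)
        pairwise_table = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        ).rename(columns={"p-adj": "p_adj"})
    return GroupTestResult(
        test="anova+tukey", statistic=float(f), df=df, p=float(p),
        pairwise=pairwise_table,
    )


def chi_square_table(counts: np.ndarray) -> GroupTestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D contingency table")
    expected = sp_stats.contingency.expected_freq(counts)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    chi2, p, df, _ = sp_stats.chi2_contingency(counts, correction=False)
    return GroupTestResult(test="chi_square", statistic=float(chi2), df=df, p=float(p))


def mape(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    if np.any(tru == 0):
        raise ValueError("truths must be nonzero")
    return float(np.mean(np.abs(est - tru) / np.abs(tru)) * 100.0)
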