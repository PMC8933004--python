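"""Enrichment and comparison statistics for eCpG characterization.

Enrichments are 2x2 Pearson chi-square tests (no continuity correction by
default) of a target flag (e.g. is-eCpG) against a category flag (e.g.
lies in a CpG island, carries an active-promoter chromatin state), with
non-target CpGs as the reference group.  Odds ratios come from the same
table, with a Haldane 0.5 pseudo-count applied to the OR only when a cell
is zero.  Continuous variables are compared between groups with two-sided
rank-sum tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def chisq_enrichment(
    target_flags, category_flags, correction: bool = False, reference: str = "non eCpGs"
) -> dict:
    """2x2 enrichment of ``category`` among ``target`` vs non-target.

    Table layout: rows = target yes/no, columns = category yes/no;
    OR = (a*d)/(b*c) with a = target & category.
    """
    t = np.asarray(target_flags, bool)
    c = np.asarray(category_flags, bool)
    if len(t) != len(c):
        raise ValueError("flag vectors must be aligned")
    if len(t) < 2:
        raise ValueError("need at least 2 CpGs")
    if t.all() or (~t).all() or c.all() or (~c).all():
        raise ValueError("degenerate 2x2 table: a flag vector is constant")
    a = int(np.sum(t & c))
    b = int(np.sum(t & ~c))
    cc = int(np.sum(~t & c))
    d = int(np.sum(~t & ~c))
    table = np.array([[a, b], [cc, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    if min(a, b, cc, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, cc, d))
    else:
        a2, b2, c2, d2 = a, b, cc, d
    return {
        "odds_ratio": (a2 * d2) / (b2 * c2),
        "p": float(p),
        "chi2": float(chi2),
        "counts": np.array([[a, b], [cc, d]]),
        "reference": reference,
    }


def methylation_level_category(median_beta: float) -> str:
    """Bin a CpG's median methylation: low (<=0.3), medium (>0.3-0.7),
    high (>0.7)."""
    v = float(median_beta)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"median methylation {v} outside [0, 1]")
    if v <= 0.3:
        return "low"
    if v <= 0.7:
        return "medium"
    return "high"


def wilcoxon_compare(values, group) -> dict:
    """Two-sided rank-sum comparison of a continuous variable between two
    groups; ``group`` is a boolean mask for group A.  ``median_diff`` is
    median(A) - median(B)."""
    v = np.asarray(values, float)
    g = np.asarray(group, bool)
    if len(v) != len(g):
        raise ValueError("values and group mask must be aligned")
    a, b = v[g], v[~g]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"p": float(stat.pvalue), "median_diff": float(np.median(a) - np.median(b)), "u": float(stat.statistic)}


def heritability_trend(heritability, n_egenes) -> dict:
    """OLS of a heritability measure on the number of eGenes per eCpG."""
    h = np.asarray(heritability, float)
    k = np.asarray(n_egenes, float)
    if len(np.unique(k)) < 3:
        raise ValueError("need at least 3 distinct eGene counts")
    res = stats.linregress(k, h)
    return {"slope": float(res.slope), "p": float(res.pvalue), "se": float(res.stderr)}


def reliability_filter(cpgs: pd.DataFrame, icc_threshold: float = 0.4) -> pd.DataFrame:
    """Keep CpGs measured reliably: ICC strictly above the threshold.

    CpGs without an ICC are dropped; the dropped count is recorded in
    ``DataFrame.attrs['n_missing_icc']``.
    """
    if "icc" not in cpgs.columns:
        raise ValueError("annotation has no 'icc' column")
    icc = pd.to_numeric(cpgs["icc"], errors="coerce")
    n_missing = int(icc.isna().sum())
    out = cpgs[icc > icc_threshold].copy()
    out.attrs["n_missing_icc"] = n_missing
    return out
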