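"""Per-taxon differential abundance testing with BH-FDR control.

Workflow: a Shapiro-Wilk normality screen (reported, not gating), a
Wilcoxon rank-sum test per taxon between case and control samples, and
Benjamini-Hochberg adjustment over all taxa at the analyzed taxonomic
level.  Taxa with adjusted q < 0.05 are flagged significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston approximation), 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Shapiro-Wilk requires a vector with n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-value approximation requires n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant vector")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of the first sample (midranks for
    ties) and a two-sided p-value: exact by enumeration when
    ``n1 + n2 <= 12`` with no ties, otherwise a normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.ptp(combined) == 0:
        return w, 1.0  # all observations identical: no evidence either way
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return w, float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, mapped back to
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def diff_abundance_table(ft: FeatureTable, level: str,
                         alpha: float = 0.05,
                         min_prevalence: float = 0.0) -> pd.DataFrame:
    """Wilcoxon + BH differential abundance for every taxon at one level.

    ``ft`` must be a relative-mode table already collapsed to ``level``
    with case and control samples present; the BH family is all taxa in
    the table (one family per level).  ``min_prevalence`` optionally
    drops taxa present in fewer than that fraction of samples before
    testing.
    """
    if ft.mode != "relative":
        raise ValueError("diff_abundance_table requires a relative-mode table")
    groups = ft.groups()
    case_ids = list(groups.index[groups == "case"])
    ctrl_ids = list(groups.index[groups == "control"])
    if not case_ids or not ctrl_ids:
        raise ValueError("both case and control samples are required")

    data = ft.data
    if min_prevalence > 0:
        prev = (data > 0).mean(axis=1)
        data = data.loc[prev >= min_prevalence]

    rows = []
    for taxon in data.index:
        x = data.loc[taxon, case_ids].to_numpy(float)
        y = data.loc[taxon, ctrl_ids].to_numpy(float)
        w, p = wilcoxon_rank_sum(x, y)
        rows.append((taxon, level, x.mean(), y.mean(), w, p))
    out = pd.DataFrame(rows, columns=["taxon", "level", "mean_case",
                                      "mean_control", "W", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.set_index("taxon")
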