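"""Two-sample and multi-group tests shared by the analysis modules.

The routines here wrap SciPy where a standard implementation exists
(Welch's t, Mann-Whitney U, Kruskal-Wallis) and implement Dunn's rank-based
post hoc z-test directly, since no canonical SciPy routine exists for it.
The classic equal-variance Student's t used for interactome scoring is
implemented in vectorized form with explicit handling of the zero-variance
degeneracies that arise with spectral-count data (a protein absent from
every replicate of both conditions, or perfectly constant values).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "student_t_rows",
    "welch_t",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "KruskalDunnResult",
]


def student_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided Student's t-test (equal variance pooled).

    Parameters
    ----------
    a, b : (n_rows, n_replicates) arrays
        Per-replicate values for the two conditions.

    Returns
    -------
    t, p, degenerate : arrays of shape (n_rows,)
        ``degenerate`` flags rows where both groups had zero variance but
        different means; there the t statistic diverges and p is reported
        as 0.  Zero variance with equal means yields p = 1 (no evidence of
        a difference is obtainable from constant data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("Student's t-test requires >=2 replicates per condition")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    zero_se = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, diff / np.where(zero_se, 1.0, se))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = zero_se & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    p = np.where(zero_se, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test requires >=2 values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``method`` is passed through to SciPy ("auto", "exact", or
    "asymptotic"; the asymptotic form uses tie and continuity corrections).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("Mann-Whitney requires >=1 value per group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected) across >=2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires >=2 groups")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups, labels=None, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post hoc z-tests on joint ranks.

    For groups i, j with sizes :math:`n_i, n_j` and mean joint ranks
    :math:`\\bar R_i, \\bar R_j` over :math:`N` pooled observations,

    .. math::
        z_{ij} = \\frac{\\bar R_i - \\bar R_j}
                      {\\sqrt{\\left(\\frac{N(N+1)}{12} - T\\right)
                              \\left(\\frac{1}{n_i}+\\frac{1}{n_j}\\right)}}

    with tie correction :math:`T = \\sum_t (t^3 - t) / (12 (N-1))` over tie
    groups of size *t*.  Two-sided p values come from the standard normal;
    ``p_adjust`` is "bonferroni" (multiply by the number of tested pairs,
    clipped at 1) or "none".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Dunn's test requires >=2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("Dunn's test requires >=2 values per group")
    if p_adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction over groups of tied values in the pooled sample
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var0 = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        offset += g.size
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = np.sqrt(var0 * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if p_adjust == "bonferroni" else p
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_value": float(p),
                "p_adjusted": float(p_adj),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis result plus Dunn pairwise table."""

    statistic: float
    p_value: float
    pairwise: pd.DataFrame
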