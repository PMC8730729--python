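"""ROI-based organelle accumulation and motile-tubule summaries.

The centrosome-accumulation statistic normalizes the fraction of a cell's
fluorescence found in a centrosomal ROI by the fraction of the cell's area
that ROI occupies:

.. math::
    r = \\frac{I_{centrosome} / I_{cell}}{A_{centrosome} / A_{cell}}

so that uniformly distributed fluorescence gives exactly 1 and values
above 1 indicate accumulation.  Motile-tubule counting applies the two
qualification clauses (the tubule moved from its initial location, and it
exceeded 1 um in length at some point), and per-cell counts are summarized
as the percentage of cells above a count threshold.  Group comparisons use
the Kruskal-Wallis omnibus test with Dunn's post hoc pairwise z-tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import KruskalDunnResult, dunn_posthoc, kruskal_wallis

__all__ = [
    "centrosome_enrichment",
    "count_motile_tubules",
    "percent_cells_above",
    "kruskal_dunn",
]


def centrosome_enrichment(rois: pd.DataFrame, *, background: float = 0.0) -> pd.Series:
    """Area-normalized centrosomal intensity ratio per cell.

    ``rois`` needs columns ``centrosome_intensity``, ``whole_cell_intensity``,
    ``centrosome_area``, ``whole_cell_area``.  ``background`` is an optional
    constant per-pixel offset subtracted from both intensities (scaled by
    ROI area) before forming the ratio; default 0 (no subtraction).
    The result is invariant to global intensity rescaling and to uniform
    changes of the area unit.
    """
    ci = rois["centrosome_intensity"].to_numpy(dtype=float)
    wi = rois["whole_cell_intensity"].to_numpy(dtype=float)
    ca = rois["centrosome_area"].to_numpy(dtype=float)
    wa = rois["whole_cell_area"].to_numpy(dtype=float)
    if background:
        ci = ci - background * ca
        wi = wi - background * wa
    if np.any(wi <= 0) or np.any(wa <= 0) or np.any(ca <= 0):
        raise ValueError("whole-cell intensity and ROI areas must be positive")
    ratio = (ci / wi) / (ca / wa)
    return pd.Series(ratio, index=rois.index, name="centrosome_enrichment")


def count_motile_tubules(tracks: pd.DataFrame, *, min_length: float = 1.0) -> pd.Series:
    """Qualifying motile tubules per cell.

    A track counts iff it moved from its initial location
    (``moved_from_origin``) and its maximum extent ``max_length_um``
    exceeded ``min_length`` (strictly) at some point.  Non-moving tubules
    and puncta never longer than the cutoff are excluded.  Cells whose
    tracks all fail still appear with count 0.
    """
    qualifies = tracks["moved_from_origin"].astype(bool) & (
        tracks["max_length_um"].astype(float) > min_length
    )
    counts = qualifies.groupby(tracks["cell_id"]).sum().astype(int)
    counts.name = "n_motile_tubules"
    return counts


def percent_cells_above(counts, *, threshold: int = 5) -> float:
    """Percentage of cells with strictly more than ``threshold`` qualifying tubules."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("no cells supplied")
    return 100.0 * float(np.mean(arr > threshold))


def kruskal_dunn(groups, labels=None, *, p_adjust: str = "bonferroni") -> KruskalDunnResult:
    """Kruskal-Wallis omnibus plus Dunn's post hoc pairwise comparisons.

    Requires >=3 groups (with fewer groups there is nothing to correct
    post hoc) and >=2 values in each.  ``p_adjust`` is "bonferroni"
    (default, over the tested pairs) or "none".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("the omnibus test requires >=3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >=2 values")
    h, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, labels=labels, p_adjust=p_adjust)
    return KruskalDunnResult(statistic=h, p_value=p, pairwise=pairwise)
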