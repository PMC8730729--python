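"""BioID interactome quantification from peptide-level spectral counts.

The chain implemented here is the standard label-free spectral-counting
workflow used to call proximity-labeling hits against a cytoplasmic
control:

1. **Shared-count distribution** — a spectrum matched to a peptide shared
   by several proteins is split among them in proportion to each protein's
   *unique* spectral evidence in that replicate, giving distributed
   spectral counts (dSpC).
2. **dNSAF** — distributed counts are length-normalized and scaled to sum
   to one within each replicate:
   ``dNSAF_i = (dSpC_i / L_i) / sum_j (dSpC_j / L_j)``.
3. **Enrichment** — per protein, the ratio of bait to control average
   dNSAF (averages taken over replicates with nonzero dNSAF), with a
   two-sample two-tailed Student's t-test on the per-replicate dNSAF
   vectors.
4. **Hit calling** — the three-part filter: fold enrichment above a
   threshold (or absence from the control), p below a significance level,
   and presence in a minimum number of bait replicates.
5. **Multi-bait intersections** and node/edge table export for generic
   graph viewers.

Peptide evidence tables carry one row per peptide with a semicolon-joined
``protein_ids`` column and ``rep1..repN`` integer count columns (see
:mod:`fhfquant.io` for the on-disk schema).
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io as fio
from .stats import student_t_rows, welch_t

__all__ = [
    "rep_columns",
    "distribute_shared_counts",
    "compute_dnsaf",
    "average_nonzero",
    "enrichment_test",
    "call_hits",
    "intersect_datasets",
    "export_interaction_tables",
    "read_interaction_tables",
    "interactome_pipeline",
]

#: sentinel used for infinite fold enrichment in exported tables
INF_SENTINEL = "inf"


def rep_columns(df: pd.DataFrame) -> list[str]:
    """Replicate count columns of a peptide or dSpC table, in order."""
    cols = [c for c in df.columns if c.startswith("rep")]
    if not cols:
        raise ValueError("no replicate columns (rep1..repN) found")
    return cols


def _split_protein_ids(value) -> list[str]:
    if isinstance(value, str):
        return value.split(";")
    return list(value)


def distribute_shared_counts(evidence: pd.DataFrame, proteins: pd.DataFrame) -> pd.DataFrame:
    """Distribute peptide spectral counts to proteins (dSpC).

    Uniquely mapped peptides assign their counts wholly to their protein.
    A shared peptide's count in each replicate is split among its proteins
    in proportion to each protein's unique spectral count in that
    replicate; when none of the sharing proteins has unique evidence in a
    replicate the count is split equally (the proportional rule is 0/0
    there, and the equal split is the symmetric choice that conserves
    counts).

    Parameters
    ----------
    evidence : DataFrame
        Columns ``peptide_id``, ``protein_ids`` (semicolon-joined string or
        iterable), ``rep1..repN``.
    proteins : DataFrame
        Columns ``protein_id``, ``length_aa``; defines the protein universe
        of the output (proteins without evidence get zero rows).

    Returns
    -------
    DataFrame indexed by ``protein_id`` with ``rep1..repN`` dSpC columns.
    Per-replicate totals equal the raw per-replicate count totals.
    """
    reps = rep_columns(evidence)
    universe = list(proteins["protein_id"])
    known = set(universe)
    memberships = [_split_protein_ids(v) for v in evidence["protein_ids"]]
    for pep, members in zip(evidence["peptide_id"], memberships):
        if not members:
            raise ValueError(f"peptide {pep!r} maps to no protein")
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ValueError(f"peptide {pep!r} references unknown protein(s) {unknown}")

    counts = evidence[reps].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative spectral counts")

    index = {p: i for i, p in enumerate(universe)}
    dspc = np.zeros((len(universe), len(reps)))
    # unique counts first: they both assign directly and set the weights
    unique_counts = np.zeros_like(dspc)
    shared_rows: list[tuple[np.ndarray, np.ndarray]] = []
    for row, members in enumerate(memberships):
        if len(set(members)) == 1:
            unique_counts[index[members[0]]] += counts[row]
        else:
            idx = np.array([index[m] for m in dict.fromkeys(members)])
            shared_rows.append((idx, counts[row]))
    dspc += unique_counts
    for idx, cnt in shared_rows:
        u = unique_counts[idx]  # (n_members, n_reps)
        denom = u.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = np.where(denom > 0, u / np.where(denom > 0, denom, 1.0), 1.0 / len(idx))
        dspc[idx] += cnt * weights
    out = pd.DataFrame(dspc, columns=reps)
    out.insert(0, "protein_id", universe)
    return out.set_index("protein_id")


def compute_dnsaf(dspc: pd.DataFrame, proteins: pd.DataFrame) -> pd.DataFrame:
    """Length-normalize dSpC to dNSAF per replicate.

    ``dNSAF_i = (dSpC_i / L_i) / sum_j (dSpC_j / L_j)``; a replicate with
    no counts at all yields an all-zero column.
    """
    lengths = proteins.set_index("protein_id")["length_aa"].reindex(dspc.index)
    if lengths.isna().any():
        missing = list(dspc.index[lengths.isna()])
        raise ValueError(f"no length for protein(s) {missing}")
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    saf = dspc.to_numpy(dtype=float) / lengths.to_numpy(dtype=float)[:, None]
    totals = saf.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dnsaf = np.where(totals > 0, saf / np.where(totals > 0, totals, 1.0), 0.0)
    return pd.DataFrame(dnsaf, index=dspc.index, columns=dspc.columns)


def average_nonzero(values) -> float:
    """Arithmetic mean over the nonzero entries; 0 if all entries are zero."""
    arr = np.asarray(values, dtype=float)
    nz = arr[arr != 0]
    return float(nz.mean()) if nz.size else 0.0


def _pair_test(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, bool]:
    """Two-sided t-test p value for one protein with degeneracy handling."""
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        same = a.mean() == b.mean()
        return (1.0 if same else 0.0), (not same)
    if equal_var:
        _, p, degen = student_t_rows(a, b)
        return float(p[0]), bool(degen[0])
    _, p = welch_t(a, b)
    return p, False


def enrichment_test(
    bait: pd.DataFrame,
    control: pd.DataFrame,
    *,
    equal_var: bool = True,
    log_transform: bool = False,
    zero_policy: str = "nonzero",
) -> pd.DataFrame:
    """Per-protein fold enrichment and t-test of bait vs control dNSAF.

    The protein universe is the union of both tables; a protein missing
    from one condition contributes a zero vector there.  Fold enrichment is
    ``average_nonzero(bait) / average_nonzero(control)``, recorded as +inf
    when the protein is absent from the control but present in the bait.
    The p value comes from a two-sample two-tailed t-test on the
    per-replicate dNSAF vectors (classic equal-variance Student's t by
    default; ``equal_var=False`` selects Welch).

    ``zero_policy`` controls how zero dNSAF replicates enter the t-test:

    * ``"nonzero"`` (default) — test only the replicates with nonzero
      dNSAF on each side, consistent with how the averages behind the fold
      ratio are formed; when either side has fewer than two nonzero
      replicates the full vectors are used, so an absent protein is still
      tested against its zeros.  A replicate in which a protein escapes
      detection carries no abundance information, and treating it as a
      measured zero inflates the within-group variance enough to mask
      severalfold-enriched proteins.
    * ``"include"`` — full per-replicate vectors, zeros as measured values.

    ``log_transform`` applies log2(x + eps) before testing, where eps is
    half the smallest nonzero dNSAF observed.

    Returns a DataFrame with columns ``protein_id``, ``avg_dnsaf_bait``,
    ``avg_dnsaf_control``, ``fold_enrichment``, ``log2_fold``, ``p_value``,
    ``neg_log10_p``, ``q_value`` (Benjamini-Hochberg, informational only),
    ``n_present_bait``, ``n_present_control``, ``degenerate_test``.
    """
    if bait.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >=2 replicates in each condition for the t-test")
    if zero_policy not in ("nonzero", "include"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    universe = bait.index.union(control.index, sort=False)
    b = bait.reindex(universe).fillna(0.0).to_numpy(dtype=float)
    c = control.reindex(universe).fillna(0.0).to_numpy(dtype=float)

    avg_b = np.array([average_nonzero(row) for row in b])
    avg_c = np.array([average_nonzero(row) for row in c])
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(avg_c > 0, avg_b / np.where(avg_c > 0, avg_c, 1.0), np.where(avg_b > 0, np.inf, 0.0))

    tb, tc = b, c
    if log_transform:
        nonzero = np.concatenate([b[b > 0], c[c > 0]])
        eps = nonzero.min() / 2.0 if nonzero.size else 1.0
        tb, tc = np.log2(b + eps), np.log2(c + eps)

    if zero_policy == "include" and equal_var:
        _, p, degen = student_t_rows(tb, tc)
    else:
        p = np.empty(len(universe))
        degen = np.zeros(len(universe), dtype=bool)
        for i in range(len(universe)):
            bi, ci = tb[i], tc[i]
            if zero_policy == "nonzero":
                bnz, cnz = bi[b[i] != 0], ci[c[i] != 0]
                if len(bnz) >= 2 and len(cnz) >= 2:
                    bi, ci = bnz, cnz
            p[i], degen[i] = _pair_test(bi, ci, equal_var)

    with np.errstate(divide="ignore"):
        log2_fold = np.log2(fold, where=fold > 0, out=np.full_like(fold, -np.inf))
        neg_log10_p = -np.log10(np.maximum(p, np.finfo(float).tiny))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "protein_id": universe,
            "avg_dnsaf_bait": avg_b,
            "avg_dnsaf_control": avg_c,
            "fold_enrichment": fold,
            "log2_fold": log2_fold,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "q_value": q,
            "n_present_bait": (b != 0).sum(axis=1),
            "n_present_control": (c != 0).sum(axis=1),
            "degenerate_test": degen,
        }
    )


def call_hits(
    results: pd.DataFrame,
    *,
    fold_threshold: float = 3.0,
    p_threshold: float = 0.05,
    min_present: int = 3,
) -> pd.DataFrame:
    """Apply the three-part hit filter and return results with ``is_hit``.

    A protein is a hit iff (fold enrichment >= ``fold_threshold`` OR it is
    absent from the control while present in the bait) AND p <
    ``p_threshold`` AND it is present (nonzero dNSAF) in at least
    ``min_present`` bait replicates.  Control-absent proteins still have to
    satisfy the presence and significance clauses.
    """
    if not (fold_threshold > 0 and 0 < p_threshold <= 1 and min_present >= 0):
        raise ValueError("hit-filter thresholds out of range")
    fold = results["fold_enrichment"].to_numpy(dtype=float)
    control_absent = (results["avg_dnsaf_control"].to_numpy(dtype=float) == 0) & (
        results["avg_dnsaf_bait"].to_numpy(dtype=float) > 0
    )
    enriched = (fold >= fold_threshold) | control_absent
    significant = results["p_value"].to_numpy(dtype=float) < p_threshold
    present = results["n_present_bait"].to_numpy() >= min_present
    out = results.copy()
    out["is_hit"] = enriched & significant & present
    return out


def intersect_datasets(hits_by_bait: dict[str, set]) -> dict[frozenset, list]:
    """Partition the union of hits by exact membership across bait datasets.

    Returns a mapping from every non-empty subset of bait names to the
    sorted list of proteins that are hits in exactly that subset (the
    counting behind multi-bait interaction diagrams).  Subsets with no
    proteins are included, so the values partition the union of all hits
    and the counts sum to its size.
    """
    if not hits_by_bait:
        raise ValueError("need at least one bait dataset")
    baits = sorted(hits_by_bait)
    summary: dict[frozenset, list] = {}
    for r in range(1, len(baits) + 1):
        for combo in combinations(baits, r):
            summary[frozenset(combo)] = []
    union = set().union(*hits_by_bait.values())
    for protein in sorted(union):
        members = frozenset(b for b in baits if protein in hits_by_bait[b])
        summary[members].append(protein)
    return summary


def export_interaction_tables(
    results: pd.DataFrame,
    bait_name: str,
    out_dir,
    *,
    annotations: dict[str, str] | None = None,
    log2_fold_cap: float = 10.0,
) -> tuple[Path, Path]:
    """Write node and edge tables for generic graph viewers.

    The node table holds one row per protein with its fold enrichment
    (infinite folds written as the sentinel ``inf``), log2 fold capped at
    ``log2_fold_cap`` for display, -log10 p, the hit flag, and an optional
    category tag.  The edge table holds one bait-prey edge per hit.  The
    pair round-trips losslessly through :func:`read_interaction_tables`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = results.copy()
    annotations = annotations or {}
    nodes["category"] = [annotations.get(p, "") for p in nodes["protein_id"]]
    nodes["log2_fold_display"] = np.minimum(nodes["log2_fold"], log2_fold_cap)
    cols = [
        "protein_id",
        "fold_enrichment",
        "log2_fold_display",
        "p_value",
        "neg_log10_p",
        "n_present_bait",
        "is_hit",
        "category",
    ]
    node_path = out_dir / "nodes.tsv"
    fio.write_table(
        nodes[cols],
        node_path,
        comment=f"bait: {bait_name}\ninfinite fold enrichment written as '{INF_SENTINEL}'",
    )
    edges = pd.DataFrame(
        {
            "bait": bait_name,
            "prey": nodes.loc[nodes["is_hit"], "protein_id"],
            "fold_enrichment": nodes.loc[nodes["is_hit"], "fold_enrichment"],
        }
    )
    edge_path = out_dir / "edges.tsv"
    fio.write_table(edges, edge_path)
    return node_path, edge_path


def read_interaction_tables(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read node/edge tables written by :func:`export_interaction_tables`.

    The ``inf`` sentinel is parsed back to +inf by the float converter.
    """
    out_dir = Path(out_dir)
    nodes = fio.read_table(out_dir / "nodes.tsv")
    edges = fio.read_table(out_dir / "edges.tsv")
    nodes["fold_enrichment"] = nodes["fold_enrichment"].astype(float)
    return nodes, edges


def interactome_pipeline(
    bait_evidence: pd.DataFrame,
    control_evidence: pd.DataFrame,
    proteins: pd.DataFrame,
    *,
    fold_threshold: float = 3.0,
    p_threshold: float = 0.05,
    min_present: int = 3,
    equal_var: bool = True,
    log_transform: bool = False,
    zero_policy: str = "nonzero",
) -> pd.DataFrame:
    """Full chain from peptide evidence to hit-flagged enrichment results."""
    dspc_bait = distribute_shared_counts(bait_evidence, proteins)
    dspc_ctrl = distribute_shared_counts(control_evidence, proteins)
    dnsaf_bait = compute_dnsaf(dspc_bait, proteins)
    dnsaf_ctrl = compute_dnsaf(dspc_ctrl, proteins)
    results = enrichment_test(
        dnsaf_bait,
        dnsaf_ctrl,
        equal_var=equal_var,
        log_transform=log_transform,
        zero_policy=zero_policy,
    )
    return call_hits(
        results,
        fold_threshold=fold_threshold,
        p_threshold=p_threshold,
        min_present=min_present,
    )
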