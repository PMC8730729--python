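"""Independent brute-force reference implementations used by the tests.

These are deliberately written as plain dict/loop code, sharing nothing
with the package's vectorized implementations, so agreement between the
two is meaningful.
"""

from __future__ import annotations


def brute_force_dspc(peptides: list[tuple[str, list[str], list[float]]], protein_ids: list[str]):
    """Peptide-by-peptide distributed spectral counts.

    ``peptides`` holds (peptide_id, member proteins, per-replicate counts).
    Returns {protein_id: [dSpC per replicate]}.
    """
    n_reps = len(peptides[0][2]) if peptides else 0
    unique = {p: [0.0] * n_reps for p in protein_ids}
    for _, members, counts in peptides:
        if len(set(members)) == 1:
            for r in range(n_reps):
                unique[members[0]][r] += counts[r]
    dspc = {p: list(unique[p]) for p in protein_ids}
    for _, members, counts in peptides:
        members = list(dict.fromkeys(members))
        if len(members) == 1:
            continue
        for r in range(n_reps):
            denom = sum(unique[m][r] for m in members)
            for m in members:
                if denom > 0:
                    share = counts[r] * unique[m][r] / denom
                else:
                    share = counts[r] / len(members)
                dspc[m][r] += share
    return dspc


def brute_force_hit(row: dict, fold_threshold=3.0, p_threshold=0.05, min_present=3) -> bool:
    """Literal evaluation of the three hit-filter clauses on one row."""
    control_absent = row["avg_dnsaf_control"] == 0 and row["avg_dnsaf_bait"] > 0
    enriched = row["fold_enrichment"] >= fold_threshold or control_absent
    significant = row["p_value"] < p_threshold
    present = row["n_present_bait"] >= min_present
    return enriched and significant and present


def brute_force_classify(positions, threshold=0.6) -> str:
    """Event taxonomy by exhaustive enumeration of ordered sample pairs."""
    n = len(positions)
    up = any(
        positions[j] - positions[i] > threshold for i in range(n) for j in range(i + 1, n)
    )
    down = any(
        positions[i] - positions[j] > threshold for i in range(n) for j in range(i + 1, n)
    )
    if up and down:
        return "diffusive"
    if abs(positions[-1] - positions[0]) >= threshold:
        return "processive"
    return "static"


def brute_force_motile_count(rows: list[dict], min_length=1.0) -> dict:
    """Row-by-row application of the motile-tubule qualification clauses."""
    counts: dict = {}
    for row in rows:
        counts.setdefault(row["cell_id"], 0)
        if row["moved_from_origin"] and row["max_length_um"] > min_length:
            counts[row["cell_id"]] += 1
    return counts


def random_trace(rng):
    """A mixed bag of trace shapes exercising all three event classes."""
    import numpy as np

    n = int(rng.integers(2, 31))
    kind = rng.integers(4)
    if kind == 0:  # drift
        v = rng.uniform(-0.5, 0.5)
        x = np.cumsum(np.full(n, v)) + rng.normal(0, 0.05, n)
    elif kind == 1:  # drift with one reversal
        x = np.concatenate(
            [
                np.cumsum(np.full(n // 2 + 1, rng.uniform(0.05, 0.4))),
                np.cumsum(np.full(n - n // 2 - 1, -rng.uniform(0.05, 0.4))) if n - n // 2 - 1 else [],
            ]
        )
        x = np.asarray(x, dtype=float) + rng.normal(0, 0.02, n)
    elif kind == 2:  # random walk
        x = np.cumsum(rng.normal(0, rng.uniform(0.05, 0.4), n))
    else:  # near-stationary
        x = rng.normal(0, 0.1, n)
    return x


def random_spectral_instance(rng, max_proteins=6, max_peptides=10, n_reps=3):
    """A tiny random peptide-evidence instance for oracle comparisons."""
    n_prot = int(rng.integers(2, max_proteins + 1))
    protein_ids = [f"P{i}" for i in range(n_prot)]
    n_pep = int(rng.integers(1, max_peptides + 1))
    peptides = []
    for p in range(n_pep):
        if rng.random() < 0.4:
            k = int(rng.integers(2, min(3, n_prot) + 1))
            members = list(rng.choice(protein_ids, size=k, replace=False))
        else:
            members = [protein_ids[int(rng.integers(n_prot))]]
        counts = rng.poisson(3.0, size=n_reps).tolist()
        peptides.append((f"pep{p}", members, counts))
    return protein_ids, peptides
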