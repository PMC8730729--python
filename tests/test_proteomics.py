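"""Unit and property tests for the spectral-count enrichment chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhfquant.proteomics import (
    average_nonzero,
    call_hits,
    compute_dnsaf,
    distribute_shared_counts,
    enrichment_test,
    export_interaction_tables,
    intersect_datasets,
    interactome_pipeline,
    read_interaction_tables,
)

from oracles import brute_force_dspc, brute_force_hit, random_spectral_instance


def evidence_frame(peptides):
    """Build a peptide-evidence DataFrame from (id, members, counts) triples."""
    n_reps = len(peptides[0][2])
    return pd.DataFrame(
        {
            "peptide_id": [p[0] for p in peptides],
            "protein_ids": [";".join(p[1]) for p in peptides],
            **{f"rep{r + 1}": [p[2][r] for p in peptides] for r in range(n_reps)},
        }
    )


class TestDistributeSharedCounts:
    def test_proportional_split_hand_example(self, small_proteins):
        # unique A=4, B=4, one shared peptide of 2 -> 2 x (4/8) each side
        ev = evidence_frame([("p1", ["A"], [4]), ("p2", ["B"], [4]), ("ps", ["A", "B"], [2])])
        dspc = distribute_shared_counts(ev, small_proteins)
        assert dspc.loc["A", "rep1"] == pytest.approx(5.0)
        assert dspc.loc["B", "rep1"] == pytest.approx(5.0)

    def test_no_sharing_equals_raw_sums(self, small_proteins):
        ev = evidence_frame([("p1", ["A"], [3]), ("p2", ["A"], [2]), ("p3", ["B"], [7])])
        dspc = distribute_shared_counts(ev, small_proteins)
        assert dspc.loc["A", "rep1"] == 5
        assert dspc.loc["B", "rep1"] == 7

    def test_zero_unique_tie_splits_equally(self, small_proteins):
        ev = evidence_frame([("ps", ["A", "B"], [3])])
        dspc = distribute_shared_counts(ev, small_proteins)
        assert dspc.loc["A", "rep1"] == pytest.approx(1.5)
        assert dspc.loc["B", "rep1"] == pytest.approx(1.5)
        assert dspc["rep1"].sum() == pytest.approx(3.0, abs=1e-9)

    def test_unknown_protein_rejected(self, small_proteins):
        ev = evidence_frame([("p1", ["ZZZ"], [1])])
        with pytest.raises(ValueError, match="unknown protein"):
            distribute_shared_counts(ev, small_proteins)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_and_conserves_counts(self, seed):
        rng = np.random.default_rng(seed)
        protein_ids, peptides = random_spectral_instance(rng)
        proteins = pd.DataFrame({"protein_id": protein_ids, "length_aa": 100})
        dspc = distribute_shared_counts(evidence_frame(peptides), proteins)
        oracle = brute_force_dspc(peptides, protein_ids)
        for p in protein_ids:
            for r in range(3):
                assert dspc.loc[p, f"rep{r + 1}"] == pytest.approx(oracle[p][r], abs=1e-9)
        for r in range(3):
            raw_total = sum(pep[2][r] for pep in peptides)
            assert dspc[f"rep{r + 1}"].sum() == pytest.approx(raw_total, abs=1e-9)


class TestDnsaf:
    def test_single_protein_normalizes_to_one(self):
        proteins = pd.DataFrame({"protein_id": ["A"], "length_aa": [250]})
        dspc = pd.DataFrame({"rep1": [8.0]}, index=pd.Index(["A"], name="protein_id"))
        assert compute_dnsaf(dspc, proteins).loc["A", "rep1"] == pytest.approx(1.0)

    def test_length_normalization_hand_example(self, small_proteins):
        # A: 5/100 = 0.05, B: 5/200 = 0.025 -> 2/3 and 1/3
        dspc = pd.DataFrame({"rep1": [5.0, 5.0]}, index=pd.Index(["A", "B"], name="protein_id"))
        dnsaf = compute_dnsaf(dspc, small_proteins)
        assert dnsaf.loc["A", "rep1"] == pytest.approx(2 / 3)
        assert dnsaf.loc["B", "rep1"] == pytest.approx(1 / 3)

    def test_zero_dspc_and_empty_replicate(self, small_proteins):
        dspc = pd.DataFrame(
            {"rep1": [5.0, 0.0], "rep2": [0.0, 0.0]},
            index=pd.Index(["A", "B"], name="protein_id"),
        )
        dnsaf = compute_dnsaf(dspc, small_proteins)
        assert dnsaf.loc["B", "rep1"] == 0.0
        assert (dnsaf["rep2"] == 0).all()

    def test_nonpositive_length_rejected(self):
        proteins = pd.DataFrame({"protein_id": ["A"], "length_aa": [0]})
        dspc = pd.DataFrame({"rep1": [1.0]}, index=pd.Index(["A"], name="protein_id"))
        with pytest.raises(ValueError, match="positive"):
            compute_dnsaf(dspc, proteins)

    @given(st.integers(0, 10_000), st.floats(0.1, 1000.0))
    def test_columns_sum_to_one_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        proteins = pd.DataFrame(
            {"protein_id": [f"P{i}" for i in range(n)], "length_aa": rng.integers(50, 900, n)}
        )
        dspc = pd.DataFrame(
            rng.poisson(4.0, size=(n, 3)).astype(float),
            index=pd.Index(proteins["protein_id"], name="protein_id"),
            columns=["rep1", "rep2", "rep3"],
        )
        dnsaf = compute_dnsaf(dspc, proteins)
        for col in dnsaf:
            total = dnsaf[col].sum()
            assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0
        scaled = dspc.copy()
        scaled["rep2"] = scaled["rep2"] * scale
        dnsaf_scaled = compute_dnsaf(scaled, proteins)
        assert np.allclose(dnsaf_scaled["rep2"], dnsaf["rep2"], atol=1e-9)


@pytest.mark.parametrize(
    "values, expected",
    [
        ((0.02, 0, 0.04, 0.06), 0.04),
        ((0, 0, 0, 0), 0.0),
        ((0.03, 0.03, 0.03, 0.03), 0.03),
    ],
)
def test_average_nonzero(values, expected):
    assert average_nonzero(values) == pytest.approx(expected)


def dnsaf_table(rows: dict, reps=4) -> pd.DataFrame:
    return pd.DataFrame(
        {f"rep{r + 1}": [v[r] for v in rows.values()] for r in range(reps)},
        index=pd.Index(list(rows), name="protein_id"),
    )


class TestEnrichment:
    def test_fold_ratio_of_nonzero_averages(self):
        bait = dnsaf_table({"X": [0.04, 0.04, 0.04, 0.04]})
        control = dnsaf_table({"X": [0.01, 0.01, 0.01, 0.01]})
        res = enrichment_test(bait, control).set_index("protein_id")
        assert res.loc["X", "fold_enrichment"] == pytest.approx(4.0)

    def test_absent_from_control_gives_infinite_fold_hit(self):
        bait = dnsaf_table({"X": [0.03, 0.035, 0.032, 0.03]})
        control = dnsaf_table({"X": [0.0, 0.0, 0.0, 0.0]})
        res = call_hits(enrichment_test(bait, control)).set_index("protein_id")
        assert np.isinf(res.loc["X", "fold_enrichment"])
        assert bool(res.loc["X", "is_hit"])

    def test_identical_vectors_give_fold_one_p_one(self):
        bait = dnsaf_table({"X": [0.02, 0.03, 0.025, 0.02]})
        res = enrichment_test(bait, bait.copy()).set_index("protein_id")
        assert res.loc["X", "fold_enrichment"] == pytest.approx(1.0)
        assert res.loc["X", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_but_different_is_degenerate(self):
        bait = dnsaf_table({"X": [0.04] * 4})
        control = dnsaf_table({"X": [0.01] * 4})
        res = enrichment_test(bait, control).set_index("protein_id")
        assert res.loc["X", "p_value"] == 0.0
        assert bool(res.loc["X", "degenerate_test"])

    def test_fewer_than_two_replicates_rejected(self):
        bait = dnsaf_table({"X": [0.04]}, reps=1)
        control = dnsaf_table({"X": [0.01, 0.01]}, reps=2)
        with pytest.raises(ValueError, match="2 replicates"):
            enrichment_test(bait, control)


class TestCallHits:
    @pytest.mark.parametrize(
        "fold, p, present, expected",
        [
            (4.0, 0.01, 4, True),  # all three clauses hold
            (10.0, 0.01, 2, False),  # missing from too many bait replicates
            (2.9, 0.001, 4, False),  # below the threefold threshold
            (np.inf, 0.2, 4, False),  # control-absent but not significant
        ],
    )
    def test_three_clause_filter(self, fold, p, present, expected):
        avg_c = 0.0 if np.isinf(fold) else 0.01
        res = pd.DataFrame(
            {
                "protein_id": ["X"],
                "avg_dnsaf_bait": [0.04],
                "avg_dnsaf_control": [avg_c],
                "fold_enrichment": [fold],
                "p_value": [p],
                "n_present_bait": [present],
            }
        )
        assert bool(call_hits(res)["is_hit"].iloc[0]) is expected
        assert brute_force_hit(res.iloc[0].to_dict()) is expected

    def test_bad_thresholds_rejected(self):
        res = pd.DataFrame(
            {
                "protein_id": ["X"],
                "avg_dnsaf_bait": [0.0],
                "avg_dnsaf_control": [0.0],
                "fold_enrichment": [0.0],
                "p_value": [1.0],
                "n_present_bait": [0],
            }
        )
        with pytest.raises(ValueError):
            call_hits(res, p_threshold=1.5)


class TestIntersections:
    def test_two_bait_partition(self):
        summary = intersect_datasets({"A": {"p1", "p2"}, "B": {"p2"}})
        assert summary[frozenset({"A"})] == ["p1"]
        assert summary[frozenset({"A", "B"})] == ["p2"]
        assert summary[frozenset({"B"})] == []

    def test_single_bait_collects_all_hits(self):
        summary = intersect_datasets({"A": {"p1", "p2"}})
        assert summary == {frozenset({"A"}): ["p1", "p2"]}

    def test_disjoint_sets_leave_overlap_empty(self):
        summary = intersect_datasets({"A": {"p1"}, "B": {"p2"}})
        assert summary[frozenset({"A", "B"})] == []
        total = sum(len(v) for v in summary.values())
        assert total == 2

    def test_counts_partition_the_union(self, rng):
        hits = {
            name: set(rng.choice(20, size=rng.integers(0, 10), replace=False).tolist())
            for name in ["a", "b", "c"]
        }
        summary = intersect_datasets(hits)
        union = set().union(*hits.values())
        assert sum(len(v) for v in summary.values()) == len(union)


class TestExportRoundTrip:
    def test_tables_round_trip_including_infinite_fold(self, tmp_path):
        bait = dnsaf_table({"X": [0.03, 0.035, 0.032, 0.03], "Y": [0.01, 0.012, 0.011, 0.01]})
        control = dnsaf_table({"X": [0.0, 0.0, 0.0, 0.0], "Y": [0.01, 0.01, 0.012, 0.009]})
        res = call_hits(enrichment_test(bait, control))
        export_interaction_tables(res, "bait1", tmp_path, annotations={"X": "endosome"})
        nodes, edges = read_interaction_tables(tmp_path)
        merged = nodes.set_index("protein_id")
        assert np.isinf(merged.loc["X", "fold_enrichment"])
        assert merged.loc["Y", "fold_enrichment"] == pytest.approx(
            res.set_index("protein_id").loc["Y", "fold_enrichment"]
        )
        assert merged.loc["X", "category"] == "endosome"
        assert list(edges["prey"]) == ["X"]
        # display cap applies to the exported log2 column only
        assert merged.loc["X", "log2_fold_display"] == pytest.approx(10.0)


def test_pipeline_flags_planted_interactor():
    """A strongly enriched protein passes the filter end to end."""
    from fhfquant.simulate import ProteomeSimConfig, simulate_spectral_counts

    sim = simulate_spectral_counts(
        ProteomeSimConfig(
            n_background_proteins=30,
            n_true_interactors=3,
            enrichment_factor=10.0,
            dropout_prob=0.0,
            seed=5,
        )
    )
    res = interactome_pipeline(sim.bait, sim.control, sim.proteins)
    hits = set(res.loc[res["is_hit"], "protein_id"])
    assert sim.true_interactors <= hits
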