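"""Clonality, contamination, LOOCV pools, accuracy metrics, lineage graphs."""

import numpy as np
import pytest

from ablineage import (
    Rearrangement,
    SimConfig,
    assign_lineages,
    build_lineage_graph,
    clonality_fraction,
    cross_donor_contamination,
    germline_usage,
    lineage_feature_table,
    lineage_size_histogram,
    loocv_pools,
    pairwise_precision_recall,
    short_hcdr3_enrichment,
    simulate_repertoire,
)
from ablineage.lineages import Lineage, LineagePartition

from conftest import make_rec


def manual_partition(groups):
    assignments = {}
    lineages = []
    for i, members in enumerate(groups, 1):
        lid = f"L{i}"
        lineages.append(Lineage(lineage_id=lid, member_ids=list(members)))
        for sid in members:
            assignments[sid] = lid
    return LineagePartition(assignments=assignments, lineages=lineages)


class TestClonality:
    def test_hand_examples(self):
        assert clonality_fraction(manual_partition([["a", "b"], ["c"]])) == pytest.approx(2 / 3)
        assert clonality_fraction(manual_partition([["a"], ["b"], ["c"]])) == 0.0
        assert clonality_fraction(manual_partition([["a", "b", "c"]])) == 1.0

    def test_empty_partition_is_error(self):
        with pytest.raises(ValueError):
            clonality_fraction(manual_partition([]))

    def test_clonality_rises_with_depth_toward_plateau(self):
        """Deeper sampling of a fixed lineage pool finds more clonal
        relatives; the mean curve is non-decreasing."""
        cfg = SimConfig(seed=21, n_lineages=1200, alpha=2.0)
        pool, _ = simulate_repertoire(cfg)
        rng = np.random.default_rng(0)
        means = []
        for depth in (250, 500, 1000, 2000):
            vals = []
            for _ in range(3):
                idx = rng.choice(len(pool), size=depth, replace=False)
                part = assign_lineages([pool[i] for i in idx])
                vals.append(clonality_fraction(part))
            means.append(np.mean(vals))
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))


class TestContamination:
    def test_modal_donor_hand_count(self):
        part = manual_partition([["a1", "a2", "b1"], ["b2"]])
        donors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert cross_donor_contamination(part, donors) == pytest.approx(0.25)

    def test_strict_rule_counts_whole_mixed_lineage(self):
        part = manual_partition([["a1", "a2", "b1"], ["b2"]])
        donors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert cross_donor_contamination(part, donors, strict=True) == pytest.approx(0.75)

    def test_single_donor_lineages_give_zero(self):
        part = manual_partition([["a1", "a2"], ["b1", "b2"]])
        donors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert cross_donor_contamination(part, donors) == 0.0

    def test_modal_tie_broken_lexicographically(self):
        part = manual_partition([["a1", "b1"]])
        donors = {"a1": "A", "b1": "B"}
        # tie -> modal donor A; b1 is the contaminant
        assert cross_donor_contamination(part, donors) == pytest.approx(0.5)


class TestLoocvPools:
    def _donor_sets(self, n_donors, per_donor):
        return {
            f"D{d}": [make_rec(f"D{d}s{i}", donor_id=f"D{d}") for i in range(per_donor)]
            for d in range(1, n_donors + 1)
        }

    def test_pool_construction(self):
        pools = loocv_pools(self._donor_sets(8, 30), n_per_donor=25, seed=0)
        assert len(pools) == 8
        for left_out, pool in pools:
            assert len(pool) == 7 * 25
            assert all(r.donor_id != left_out for r in pool)

    def test_two_donor_minimum(self):
        pools = loocv_pools(self._donor_sets(2, 5), n_per_donor=5, seed=0)
        assert [len(p) for _, p in pools] == [5, 5]
        with pytest.raises(ValueError):
            loocv_pools({"D1": []}, n_per_donor=1)

    def test_seed_reproducibility(self):
        data = self._donor_sets(3, 20)
        ids = lambda pools: [[r.sequence_id for r in p] for _, p in pools]
        assert ids(loocv_pools(data, 10, seed=4)) == ids(loocv_pools(data, 10, seed=4))

    def test_insufficient_records_error(self):
        with pytest.raises(ValueError):
            loocv_pools(self._donor_sets(2, 3), n_per_donor=5)


class TestShortHcdr3Enrichment:
    def test_no_incorrect_sequences_reports_null(self):
        recs = [make_rec("a1", donor_id="A"), make_rec("a2", donor_id="A")]
        part = manual_partition([["a1", "a2"]])
        frac_bad, frac_good = short_hcdr3_enrichment(
            recs, part, {"a1": "A", "a2": "A"}
        )
        assert frac_bad is None
        assert frac_good == 1.0  # CARDYW is short

    def test_short_cross_donor_lineage_fully_enriched(self):
        recs = [
            make_rec("a1", cdr3_aa="CARDYW", donor_id="A"),
            make_rec("a2", cdr3_aa="CARDYW", donor_id="A"),
            make_rec("b1", cdr3_aa="CARDYW", donor_id="B"),
            make_rec("b2", cdr3_aa="CAKDLRGVIDYYYGMDVW", donor_id="B"),
        ]
        part = manual_partition([["a1", "a2", "b1"], ["b2"]])
        donors = {r.sequence_id: r.donor_id for r in recs}
        frac_bad, frac_good = short_hcdr3_enrichment(recs, part, donors)
        assert frac_bad == 1.0
        assert frac_good == pytest.approx(2 / 3)


class TestGermlineUsage:
    def test_lineage_level_removes_size_influence(self):
        recs = [make_rec(f"v3_{i}", v_gene="IGHV3-23*01") for i in range(100)]
        recs.append(make_rec("v1_0", v_gene="IGHV1-2*01"))
        part = manual_partition([[r.sequence_id for r in recs[:100]], ["v1_0"]])
        seq_usage = germline_usage(recs, level="sequence")["v_family"]
        lin_usage = germline_usage(recs, part, level="lineage")["v_family"]
        assert lin_usage == {"IGHV1": 0.5, "IGHV3": 0.5}
        assert seq_usage["IGHV3"] == pytest.approx(100 / 101)

    def test_frequencies_sum_to_one(self, default_repertoire):
        records, _ = default_repertoire
        part = assign_lineages(records)
        for level in ("sequence", "lineage"):
            usage = germline_usage(records, part, level=level)
            for cls, freqs in usage.items():
                if freqs:
                    assert sum(freqs.values()) == pytest.approx(1.0)

    def test_size_independent_draw_gives_matching_levels(self):
        """When gene use is independent of lineage size, sequence- and
        lineage-level V-family distributions agree within sampling error
        (needs many lineages for the comparison to be meaningful)."""
        cfg = SimConfig(seed=61, n_lineages=400, alpha=2.0)
        records, truth = simulate_repertoire(cfg)
        part = assign_lineages(records)
        seq_usage = germline_usage(records, level="sequence")["v_family"]
        lin_usage = germline_usage(records, part, level="lineage")["v_family"]
        for fam in set(seq_usage) | set(lin_usage):
            assert abs(seq_usage.get(fam, 0) - lin_usage.get(fam, 0)) < 0.12


class TestPrecisionRecall:
    def test_perfect_partition(self):
        part = manual_partition([["a", "b"], ["c"]])
        truth = {"a": "x", "b": "x", "c": "y"}
        assert pairwise_precision_recall(part, truth) == (1.0, 1.0)

    def test_all_singletons_has_null_precision(self):
        part = manual_partition([["a"], ["b"], ["c"]])
        truth = {"a": "x", "b": "x", "c": "y"}
        precision, recall = pairwise_precision_recall(part, truth)
        assert precision is None and recall == 0.0

    def test_split_lineage_pair_counts(self):
        part = manual_partition([["a", "b"], ["c"]])
        truth = {"a": "x", "b": "x", "c": "x"}
        precision, recall = pairwise_precision_recall(part, truth)
        assert precision == 1.0 and recall == pytest.approx(1 / 3)

    def test_missing_truth_is_error(self):
        part = manual_partition([["a"]])
        with pytest.raises(ValueError):
            pairwise_precision_recall(part, {})


class TestLineageTables:
    def test_feature_table_and_size_histogram(self, recovery_repertoire):
        records, _ = recovery_repertoire
        part = assign_lineages(records)
        table = lineage_feature_table(part)
        assert len(table) == len(part.lineages)
        assert table["size"].sum() == len(records)
        hist = lineage_size_histogram(part)
        assert (hist["size"] * hist["n_lineages"]).sum() == len(records)


class TestLineageGraph:
    def test_identical_sequences_collapse(self):
        recs = [make_rec(f"r{i}", junction_nt="TGTGCAGCATGG") for i in range(3)]
        for r in recs:
            r.sequence_alignment = "ACGT"
        g = build_lineage_graph(recs)
        assert g.number_of_nodes() == 1
        assert g.number_of_edges() == 0
        assert g.nodes["N0"]["weight"] == 3

    def test_two_distinct_sequences_one_edge(self):
        a = make_rec("a", cdr3_aa="CARDYW")
        b = make_rec("b", cdr3_aa="CARDFW")
        g = build_lineage_graph([a, b])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_equidistant_node_gets_edge_per_nearest_neighbor(self):
        a = make_rec("a", cdr3_aa="CARDYW")
        b = make_rec("b", cdr3_aa="CARDFW")  # dist 1/6 to a
        c = make_rec("c", cdr3_aa="CARDYF")  # dist 1/6 to a, 2/6 to b
        g = build_lineage_graph([a, b, c])
        node_of = {g.nodes[n]["sequence_ids"]: n for n in g.nodes}
        assert g.degree[node_of["a"]] == 2

    def test_node_weights_sum_to_lineage_size(self, recovery_repertoire):
        records, truth = recovery_repertoire
        from collections import Counter

        biggest = Counter(truth.lineage_of.values()).most_common(1)[0][0]
        members = [r for r in records if truth.lineage_of[r.sequence_id] == biggest]
        g = build_lineage_graph(members)
        assert sum(d["weight"] for _, d in g.nodes(data=True)) == len(members)
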