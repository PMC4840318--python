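"""The ground-truth repertoire generator and the barcode-collision calculator."""

import math
from collections import Counter

import numpy as np
import pytest

from ablineage import (
    SimConfig,
    expand_lineage,
    gene_family,
    sample_naive_rearrangement,
    simulate_reads,
    simulate_repertoire,
    unique_labeling_probability,
)
from ablineage.germlines import J_GENES, V_GENES, V_LENGTH


class TestGermlineCatalog:
    def test_catalog_shape(self):
        assert len(V_GENES) >= 8
        assert len({gene_family(v) for v in V_GENES}) >= 4
        assert len(J_GENES) >= 4
        assert all(len(s) == V_LENGTH for s in V_GENES.values())


class TestNaiveSampling:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5)
        a = sample_naive_rearrangement(cfg, np.random.default_rng(5))
        b = sample_naive_rearrangement(cfg, np.random.default_rng(5))
        assert a.junction_nt == b.junction_nt and a.v_gene == b.v_gene

    def test_junction_is_anchored_and_in_range(self):
        cfg = SimConfig(seed=6)
        rng = np.random.default_rng(6)
        for _ in range(50):
            rec = sample_naive_rearrangement(cfg, rng)
            aa_len = len(rec.junction_nt) // 3
            assert cfg.junction_len_range[0] <= aa_len <= cfg.junction_len_range[1]
            assert rec.junction_nt.startswith("TGT")  # conserved Cys
            assert rec.junction_nt.endswith("TGG")  # conserved Trp
            assert rec.mutations == []
            assert len(rec.cdr3_aa) == aa_len - 2

    def test_v_usage_follows_configured_weights(self):
        weights = {v: (3.0 if "IGHV3" in v else 1.0) for v in V_GENES}
        cfg = SimConfig(seed=7, v_weights=weights)
        rng = np.random.default_rng(7)
        draws = Counter(
            gene_family(sample_naive_rearrangement(cfg, rng).v_gene) for _ in range(5000)
        )
        total_w = sum(weights.values())
        expected = {
            fam: sum(w for v, w in weights.items() if gene_family(v) == fam) / total_w
            for fam in draws
        }
        # chi-square-style sanity bound: observed within 5 SE of expected
        for fam, exp_p in expected.items():
            se = math.sqrt(exp_p * (1 - exp_p) / 5000)
            assert abs(draws[fam] / 5000 - exp_p) < 5 * se


class TestExpandLineage:
    def test_zero_rate_gives_identical_copies(self):
        cfg = SimConfig(seed=8, shm_sub_rate=0.0)
        rng = np.random.default_rng(8)
        anc = sample_naive_rearrangement(cfg, rng)
        members = expand_lineage(anc, 4, cfg, rng)
        assert all(m.sequence_alignment == anc.sequence_alignment for m in members)
        assert all(m.mutations == [] for m in members)

    def test_star_mutation_load_matches_binomial_expectation(self):
        cfg = SimConfig(seed=9, shm_sub_rate=0.03)
        rng = np.random.default_rng(9)
        anc = sample_naive_rearrangement(cfg, rng)
        members = expand_lineage(anc, 1000, cfg, rng)
        counts = [len(m.mutations) for m in members]
        L = len(anc.sequence_alignment)
        expected = 0.03 * L
        se = math.sqrt(0.03 * L) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_two_level_members_share_intermediate_mutations(self):
        cfg = SimConfig(seed=10, topology="two_level", shm_sub_rate=0.03)
        rng = np.random.default_rng(10)
        anc = sample_naive_rearrangement(cfg, rng)
        members = expand_lineage(anc, 8, cfg, rng)
        from ablineage import shared_mutation_count

        shared = [
            shared_mutation_count(members[i].mutations, members[j].mutations)
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        assert max(shared) > 0
        assert np.mean(shared) > 0.5

    def test_members_share_germline_calls(self):
        cfg = SimConfig(seed=11)
        rng = np.random.default_rng(11)
        anc = sample_naive_rearrangement(cfg, rng)
        members = expand_lineage(anc, 5, cfg, rng)
        assert {m.v_gene for m in members} == {anc.v_gene}
        assert {m.j_gene for m in members} == {anc.j_gene}


class TestSimulateRepertoire:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=12)
        recs1, truth1 = simulate_repertoire(cfg)
        recs2, truth2 = simulate_repertoire(cfg)
        assert [r.sequence_alignment for r in recs1] == [r.sequence_alignment for r in recs2]
        assert truth1.lineage_of == truth2.lineage_of

    def test_no_lineage_spans_donors(self):
        cfg = SimConfig(seed=13, n_donors=2)
        _, truth = simulate_repertoire(cfg)
        donors_per_lineage = {}
        for sid, lin in truth.lineage_of.items():
            donors_per_lineage.setdefault(lin, set()).add(truth.donor_of[sid])
        assert all(len(d) == 1 for d in donors_per_lineage.values())

    def test_singleton_dominated_size_law(self):
        """With exponent 3.0 the lineage-size law lands in the 80-90%
        singleton band characteristic of IgG+ memory repertoires."""
        fracs = []
        for seed in range(20):
            cfg = SimConfig(seed=300 + seed, n_lineages=200, alpha=3.0)
            _, truth = simulate_repertoire(cfg)
            sizes = Counter(Counter(truth.lineage_of.values()).values())
            fracs.append(sizes[1] / 200)
        assert 0.80 <= np.mean(fracs) <= 0.90

    def test_truth_covers_every_record(self):
        cfg = SimConfig(seed=14)
        recs, truth = simulate_repertoire(cfg)
        ids = {r.sequence_id for r in recs}
        assert set(truth.lineage_of) == ids
        assert set(truth.donor_of) == ids
        assert set(truth.transcript_of) == ids


class TestSimulateReads:
    def test_error_free_single_copies_equal_barcoded_transcripts(self):
        cfg = SimConfig(
            seed=15, n_lineages=10, seq_error_rate=0.0,
            amplification_mu=0.0, amplification_sigma=0.0,
        )
        recs, _ = simulate_repertoire(cfg)
        reads, read_truth = simulate_reads(recs, cfg)
        assert len(reads) == len(recs)
        by_id = {r.sequence_id: r for r in recs}
        for read in reads:
            transcript = by_id[read_truth[read.id]].sequence_alignment
            assert read.seq[20:] == transcript

    def test_observed_error_rate_matches_configuration(self):
        cfg = SimConfig(
            seed=16, n_lineages=30, seq_error_rate=0.01,
            amplification_mu=1.5, amplification_sigma=0.5,
        )
        recs, _ = simulate_repertoire(cfg)
        reads, read_truth = simulate_reads(recs, cfg)
        by_id = {r.sequence_id: r for r in recs}
        # reconstruct each read's errorless template (barcode voted per transcript)
        mism = total = 0
        from collections import defaultdict

        uaids = defaultdict(Counter)
        for rd in reads:
            uaids[read_truth[rd.id]][rd.seq[:20]] += 1
        for rd in reads:
            tx = by_id[read_truth[rd.id]]
            template = uaids[read_truth[rd.id]].most_common(1)[0][0] + tx.sequence_alignment
            if len(template) == len(rd.seq):
                mism += sum(a != b for a, b in zip(template, rd.seq))
                total += len(rd.seq)
        observed = mism / total
        se = math.sqrt(0.01 * 0.99 / total)
        assert abs(observed - 0.01) < 6 * se

    def test_every_read_traces_to_one_transcript(self):
        cfg = SimConfig(seed=17, n_lineages=20)
        recs, _ = simulate_repertoire(cfg)
        reads, read_truth = simulate_reads(recs, cfg)
        ids = {r.sequence_id for r in recs}
        assert set(read_truth) == {r.id for r in reads}
        assert set(read_truth.values()) <= ids


class TestUniqueLabelingProbability:
    def test_edge_cases(self):
        assert unique_labeling_probability(1, 20) == 1.0
        assert unique_labeling_probability(2, 1) == pytest.approx(0.75)
        assert unique_labeling_probability(5, 1) == 0.0  # more transcripts than barcodes

    def test_matches_hand_product_small(self):
        # 3 transcripts over 16 barcodes: (1)(15/16)(14/16)
        assert unique_labeling_probability(3, 2) == pytest.approx(15 / 16 * 14 / 16)

    def test_exact_and_approximation_agree(self):
        exact = unique_labeling_probability(250_000, 20)
        approx = unique_labeling_probability(250_000, 20, method="approx")
        assert abs(exact - approx) < 1e-6
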