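"""Accuracy and repertoire-description measures.

Clonality (fraction of sequences in multi-member lineages), cross-donor
contamination (an accuracy proxy: true lineages cannot span donors),
leave-one-out multi-donor pools, pair-counting precision/recall against
simulation truth, sequence- vs lineage-level germline usage, per-lineage
feature tables and nearest-neighbor lineage graphs.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .lineages import LineagePartition
from .metric import ScoreParams, pairwise_score
from .records import Rearrangement, gene_family, strip_allele

__all__ = [
    "clonality_fraction",
    "cross_donor_contamination",
    "loocv_pools",
    "short_hcdr3_enrichment",
    "germline_usage",
    "lineage_feature_table",
    "lineage_size_histogram",
    "pairwise_precision_recall",
    "build_lineage_graph",
]


def clonality_fraction(partition: LineagePartition) -> float:
    """Fraction of sequences belonging to a lineage with at least two members."""
    if not partition.assignments:
        raise ValueError("empty partition")
    clonal = sum(lin.size for lin in partition.lineages if lin.size >= 2)
    return clonal / partition.n_sequences


def _modal_donor(donors: list[str]) -> str:
    counts = Counter(donors)
    top = max(counts.values())
    return min(d for d, c in counts.items() if c == top)


def cross_donor_contamination(
    partition: LineagePartition,
    donor_labels: dict[str, str],
    strict: bool = False,
) -> float:
    """Fraction of sequences assigned to a lineage dominated by another donor.

    Default rule: a sequence is 'incorrect' when its donor differs from its
    lineage's modal donor (ties broken lexicographically). ``strict=True``
    instead counts every member of any multi-donor lineage as incorrect.
    """
    total = partition.n_sequences
    if total == 0:
        raise ValueError("empty partition")
    bad = 0
    for lin in partition.lineages:
        donors = [donor_labels[sid] for sid in lin.member_ids]
        if strict:
            if len(set(donors)) > 1:
                bad += len(donors)
        else:
            modal = _modal_donor(donors)
            bad += sum(d != modal for d in donors)
    return bad / total


def incorrect_sequence_ids(
    partition: LineagePartition,
    donor_labels: dict[str, str],
    strict: bool = False,
) -> set[str]:
    """Sequence ids counted as incorrectly assigned under the chosen rule."""
    bad: set[str] = set()
    for lin in partition.lineages:
        donors = [donor_labels[sid] for sid in lin.member_ids]
        if strict:
            if len(set(donors)) > 1:
                bad.update(lin.member_ids)
        else:
            modal = _modal_donor(donors)
            bad.update(
                sid for sid, d in zip(lin.member_ids, donors) if d != modal
            )
    return bad


def loocv_pools(
    donor_datasets: dict[str, list[Rearrangement]],
    n_per_donor: int,
    seed: int | None = None,
) -> list[tuple[str, list[Rearrangement]]]:
    """Leave-one-out cross-validation pools: one pool per donor, containing
    ``n_per_donor`` seeded-random records from each of the other donors."""
    if len(donor_datasets) < 2:
        raise ValueError("need at least two donors")
    for donor, recs in donor_datasets.items():
        if len(recs) < n_per_donor:
            raise ValueError(f"donor {donor} has fewer than {n_per_donor} records")
    rng = np.random.default_rng(seed)
    donors = sorted(donor_datasets)
    pools = []
    for left_out in donors:
        pool: list[Rearrangement] = []
        for donor in donors:
            if donor == left_out:
                continue
            recs = donor_datasets[donor]
            idx = rng.choice(len(recs), size=n_per_donor, replace=False)
            pool.extend(recs[i] for i in sorted(idx))
        pools.append((left_out, pool))
    return pools


def short_hcdr3_enrichment(
    records: Sequence[Rearrangement],
    partition: LineagePartition,
    donor_labels: dict[str, str],
    cutoff: int = 15,
    strict: bool = False,
) -> tuple[float | None, float | None]:
    """Fraction of CDR3s shorter than ``cutoff`` amino acids among
    incorrectly vs correctly assigned sequences. Undefined fractions (no
    sequences in a class) are returned as None, never coerced to 0 or 1."""
    bad = incorrect_sequence_ids(partition, donor_labels, strict=strict)
    short_bad = n_bad = short_good = n_good = 0
    for rec in records:
        if rec.sequence_id not in partition.assignments:
            continue
        is_short = len(rec.cdr3_aa) < cutoff
        if rec.sequence_id in bad:
            n_bad += 1
            short_bad += is_short
        else:
            n_good += 1
            short_good += is_short
    frac_bad = short_bad / n_bad if n_bad else None
    frac_good = short_good / n_good if n_good else None
    return frac_bad, frac_good


def germline_usage(
    records: Sequence[Rearrangement],
    partition: LineagePartition | None = None,
    level: str = "sequence",
) -> dict[str, dict[str, float]]:
    """Germline gene-use frequencies by class (V family, D family, J gene).

    ``level="sequence"`` counts every record; ``level="lineage"`` counts each
    lineage once via its modal call, removing lineage-size influence.
    Frequencies sum to 1 within each class (classes with no calls are empty).
    """
    if level not in ("sequence", "lineage"):
        raise ValueError("level must be 'sequence' or 'lineage'")
    v_counts: Counter = Counter()
    d_counts: Counter = Counter()
    j_counts: Counter = Counter()
    if level == "sequence":
        for r in records:
            v_counts[gene_family(r.v_gene)] += 1
            if r.d_gene:
                d_counts[gene_family(r.d_gene)] += 1
            j_counts[strip_allele(r.j_gene)] += 1
    else:
        if partition is None:
            raise ValueError("lineage-level usage requires a partition")
        by_id = {r.sequence_id: r for r in records}
        for lin in partition.lineages:
            members = [by_id[sid] for sid in lin.member_ids if sid in by_id]
            if not members:
                continue
            v_counts[_modal_str([gene_family(r.v_gene) for r in members])] += 1
            d_calls = [gene_family(r.d_gene) for r in members if r.d_gene]
            if d_calls:
                d_counts[_modal_str(d_calls)] += 1
            j_counts[_modal_str([strip_allele(r.j_gene) for r in members])] += 1
    out = {}
    for name, counts in (("v_family", v_counts), ("d_family", d_counts), ("j_gene", j_counts)):
        total = sum(counts.values())
        out[name] = {k: c / total for k, c in sorted(counts.items())} if total else {}
    return out


def _modal_str(values: list[str]) -> str:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def lineage_feature_table(partition: LineagePartition) -> pd.DataFrame:
    """Per-lineage table of size, mean mutation loads and mean CDR3 length
    (each lineage one row, regardless of size)."""
    return pd.DataFrame(
        {
            "lineage_id": [l.lineage_id for l in partition.lineages],
            "size": [l.size for l in partition.lineages],
            "mean_nt_mutations": [l.mean_nt_mutations for l in partition.lineages],
            "mean_aa_mutations": [l.mean_aa_mutations for l in partition.lineages],
            "mean_cdr3_len": [l.mean_cdr3_len for l in partition.lineages],
        }
    )


def lineage_size_histogram(partition: LineagePartition) -> pd.DataFrame:
    """Lineage-size spectrum: one row per observed size with its lineage count."""
    counts = Counter(l.size for l in partition.lineages)
    return pd.DataFrame(
        {"size": sorted(counts), "n_lineages": [counts[s] for s in sorted(counts)]}
    )


def pairwise_precision_recall(
    partition: LineagePartition, truth: dict[str, str]
) -> tuple[float | None, float | None]:
    """Pair-counting accuracy against ground truth.

    Over all unordered sequence pairs, a true positive is a pair co-clustered
    in both the partition and the truth. Precision = TP/(TP+FP),
    recall = TP/(TP+FN); an undefined ratio (no predicted or no true pairs)
    is returned as None.
    """
    missing = set(partition.assignments) - set(truth)
    if missing:
        raise ValueError(f"truth lacks labels for {len(missing)} sequences")
    joint: Counter = Counter()
    pred: Counter = Counter()
    true: Counter = Counter()
    for sid, lab in partition.assignments.items():
        joint[(lab, truth[sid])] += 1
        pred[lab] += 1
        true[truth[sid]] += 1
    tp = sum(c * (c - 1) // 2 for c in joint.values())
    p_pairs = sum(c * (c - 1) // 2 for c in pred.values())
    t_pairs = sum(c * (c - 1) // 2 for c in true.values())
    precision = tp / p_pairs if p_pairs else None
    recall = tp / t_pairs if t_pairs else None
    return precision, recall


def build_lineage_graph(
    lineage_records: Sequence[Rearrangement],
    score_params: ScoreParams | None = None,
) -> nx.Graph:
    """Nearest-neighbor network of one lineage.

    Identical sequences collapse to a single node weighted by multiplicity;
    every node gains an undirected edge to each node at its minimum distance
    (ties produce one edge per co-nearest neighbor). Node weights sum to the
    lineage size; a single-unique-sequence lineage has one node, no edges.
    """
    if score_params is None:
        score_params = ScoreParams()
    groups: dict[str, list[Rearrangement]] = {}
    for rec in lineage_records:
        key = rec.sequence_alignment or rec.junction_nt
        groups.setdefault(key, []).append(rec)
    keys = sorted(groups)
    graph = nx.Graph()
    for i, key in enumerate(keys):
        members = groups[key]
        graph.add_node(
            f"N{i}",
            weight=len(members),
            sequence_ids=",".join(r.sequence_id for r in members),
        )
    n = len(keys)
    if n < 2:
        return graph
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_score(groups[keys[i]][0], groups[keys[j]][0], score_params)
            dist[i, j] = dist[j, i] = d
    for i in range(n):
        row = np.delete(dist[i], i)
        min_d = row.min()
        for j in range(n):
            if j != i and dist[i, j] == min_d:
                graph.add_edge(f"N{i}", f"N{j}", distance=float(dist[i, j]))
    return graph
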