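"""Hierarchical clustering of antibody distances into clonal lineages."""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .metric import ScoreParams, condensed_distances
from .records import Rearrangement, gene_family, strip_allele

logger = logging.getLogger(__name__)

__all__ = ["ClusterParams", "Lineage", "LineagePartition", "cluster", "assign_lineages"]


@dataclass
class ClusterParams:
    """How the pairwise distances are turned into lineages.

    The threshold default (0.35) is an implementation default on the
    normalized-score axis; the principled route is to calibrate it from the
    trough of the pairwise-score histogram (see :mod:`ablineage.calibration`).
    """

    threshold: float = 0.35
    linkage: Literal["average", "single", "complete"] = "average"
    precluster: Literal["none", "v_gene", "v_family"] = "none"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class Lineage:
    lineage_id: str
    member_ids: list[str]
    representative_junction: str | None = None
    v_family: str | None = None
    v_gene: str | None = None
    j_gene: str | None = None
    mean_nt_mutations: float | None = None
    mean_aa_mutations: float | None = None
    mean_cdr3_len: float | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class LineagePartition:
    """Assignment of every input sequence to exactly one lineage."""

    assignments: dict[str, str]
    lineages: list[Lineage] = field(default_factory=list)

    @property
    def n_sequences(self) -> int:
        return len(self.assignments)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "lineage_id": lin.lineage_id,
                "size": lin.size,
                "representative_junction": lin.representative_junction,
                "v_family": lin.v_family,
                "v_gene": lin.v_gene,
                "j_gene": lin.j_gene,
                "mean_nt_mutations": lin.mean_nt_mutations,
                "mean_aa_mutations": lin.mean_aa_mutations,
                "mean_cdr3_len": lin.mean_cdr3_len,
                "member_ids": lin.member_ids,
            }
            for lin in self.lineages
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


def _modal(values: list[str | None]) -> str | None:
    """Most common non-null value; ties broken lexicographically."""
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    counts = Counter(vals)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


# codon-level amino-acid mutation count: translate aligned codons that are
# complete and ungapped in both strings, count differing residues
_CODON = {}


def _codon_table():
    global _CODON
    if not _CODON:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON[stop] = "*"
    return _CODON


def aa_mutation_count(rec: Rearrangement) -> int | None:
    """Amino-acid substitutions between aligned sequence and germline
    (codon-wise translation; codons with gaps or ambiguity are skipped)."""
    if rec.sequence_alignment is None or rec.germline_alignment is None:
        return None
    table = _codon_table()
    s, g = rec.sequence_alignment.upper(), rec.germline_alignment.upper()
    n = 0
    for i in range(0, len(s) - 2, 3):
        cs, cg = s[i : i + 3], g[i : i + 3]
        if cs in table and cg in table and table[cs] != table[cg]:
            n += 1
    return n


def _build_lineages(
    records: Sequence[Rearrangement], labels: Sequence[int], prefix: str = "L"
) -> LineagePartition:
    groups: dict[int, list[Rearrangement]] = {}
    for rec, lab in zip(records, labels):
        groups.setdefault(int(lab), []).append(rec)
    # deterministic lineage order: descending size, then first member's input order
    first_index = {rec.sequence_id: i for i, rec in enumerate(records)}
    ordered = sorted(
        groups.values(), key=lambda mem: (-len(mem), first_index[mem[0].sequence_id])
    )
    assignments: dict[str, str] = {}
    lineages: list[Lineage] = []
    for i, members in enumerate(ordered, 1):
        lid = f"{prefix}{i:06d}"
        aa_counts = [aa_mutation_count(r) for r in members]
        aa_counts = [c for c in aa_counts if c is not None]
        lin = Lineage(
            lineage_id=lid,
            member_ids=[r.sequence_id for r in members],
            representative_junction=_modal([r.junction_nt for r in members]),
            v_family=_modal([gene_family(r.v_gene) for r in members]),
            v_gene=_modal([strip_allele(r.v_gene) for r in members]),
            j_gene=_modal([strip_allele(r.j_gene) for r in members]),
            mean_nt_mutations=float(np.mean([len(r.mutations) for r in members])),
            mean_aa_mutations=float(np.mean(aa_counts)) if aa_counts else None,
            mean_cdr3_len=float(np.mean([len(r.cdr3_aa) for r in members])),
        )
        lineages.append(lin)
        for sid in lin.member_ids:
            assignments[sid] = lid
    return LineagePartition(assignments=assignments, lineages=lineages)


def cluster(
    condensed: np.ndarray,
    cluster_params: ClusterParams,
    ids: Sequence[str],
) -> dict[str, int]:
    """Cut an agglomerative tree at the threshold: all merges with height
    <= threshold are applied. Returns sequence_id -> integer cluster label."""
    if cluster_params.threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(ids)
    if n == 1:
        return {ids[0]: 1}
    Z = linkage(np.asarray(condensed, dtype=np.float64), method=cluster_params.linkage)
    labels = fcluster(Z, t=cluster_params.threshold, criterion="distance")
    return {sid: int(lab) for sid, lab in zip(ids, labels)}


def _filter_scorable(records: Sequence[Rearrangement]) -> list[Rearrangement]:
    kept = []
    n_dropped = 0
    for r in records:
        if r.cdr3_aa and r.v_gene and r.j_gene and r.junction_nt:
            kept.append(r)
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("excluded %d records lacking CDR3 or V/J calls", n_dropped)
    return kept


def assign_lineages(
    records: Sequence[Rearrangement],
    score_params: ScoreParams | None = None,
    cluster_params: ClusterParams | None = None,
) -> LineagePartition:
    """Full unseeded lineage assignment: pairwise distances, agglomerative
    clustering, threshold cut, per-lineage summaries.

    With ``precluster`` set, records are first split by V gene or V family and
    each group is clustered separately; because cross-family pairs score the
    sentinel distance (far above any sensible threshold), pre-clustering by
    family yields the same partition as the global run, only faster.
    """
    if score_params is None:
        score_params = ScoreParams()
    if cluster_params is None:
        cluster_params = ClusterParams()
    records = _filter_scorable(records)
    if not records:
        return LineagePartition(assignments={}, lineages=[])

    if cluster_params.precluster == "none":
        groups = [list(records)]
    else:
        key_fn = (
            (lambda r: strip_allele(r.v_gene))
            if cluster_params.precluster == "v_gene"
            else (lambda r: gene_family(r.v_gene))
        )
        grouped: dict[str, list[Rearrangement]] = {}
        for r in records:
            grouped.setdefault(key_fn(r), []).append(r)
        groups = [grouped[k] for k in sorted(grouped)]

    all_labels: list[int] = []
    ordered_records: list[Rearrangement] = []
    offset = 0
    for group in groups:
        ids = [r.sequence_id for r in group]
        if len(group) == 1:
            labels = {ids[0]: 1}
        else:
            condensed = condensed_distances(group, score_params)
            labels = cluster(condensed, cluster_params, ids)
        ordered_records.extend(group)
        all_labels.extend(labels[sid] + offset for sid in ids)
        offset += max(labels.values())
    return _build_lineages(ordered_records, all_labels)


def add_clone_ids(records: Sequence[Rearrangement], partition: LineagePartition):
    """Yield (record, clone_id) pairs; records the partition dropped get None."""
    for r in records:
        yield r, partition.assignments.get(r.sequence_id)
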