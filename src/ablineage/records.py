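"""Core record types for antibody repertoire data.

A :class:`Rearrangement` is one annotated heavy-chain sequence: germline V/J
calls, the CDR3/junction, the aligned observed and germline sequences and the
derived somatic substitution list. It is the unit the lineage-assignment
metric scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GeneNameError(ValueError):
    """Raised when a germline gene call cannot be parsed."""


@dataclass
class SequenceRead:
    """A raw (or UMI-trimmed) nucleotide read."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class Mutation:
    """A somatic substitution: germline base ``ref`` replaced by ``alt`` at
    1-based position ``pos`` in the (gapped) germline alignment coordinate
    system. Identity is the exact triple — two sequences share a mutation only
    when position, reference and alternate base all agree."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("mutation position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("mutation ref and alt must differ")
        for base in (self.ref, self.alt):
            if base not in "ACGT":
                raise ValueError(f"mutation bases must be A/C/G/T, got {base!r}")

    def __str__(self) -> str:  # "123:G>A" — used by the TSV dialect
        return f"{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "Mutation":
        m = re.fullmatch(r"(\d+):([ACGT])>([ACGT])", s.strip())
        if m is None:
            raise ValueError(f"cannot parse mutation {s!r}")
        return cls(pos=int(m.group(1)), ref=m.group(2), alt=m.group(3))


@dataclass
class Rearrangement:
    """One annotated antibody rearrangement record."""

    sequence_id: str
    v_gene: str
    j_gene: str
    junction_nt: str
    cdr3_aa: str
    d_gene: str | None = None
    donor_id: str | None = None
    uaid: str | None = None
    sequence_alignment: str | None = None
    germline_alignment: str | None = None
    mutations: list[Mutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (
            self.sequence_alignment is not None
            and self.germline_alignment is not None
            and len(self.sequence_alignment) != len(self.germline_alignment)
        ):
            raise ValueError(
                f"{self.sequence_id}: sequence_alignment and germline_alignment "
                "must have equal length"
            )

    @property
    def cdr3_nt(self) -> str:
        """Junction nucleotides with the two anchor codons (conserved C and W)
        stripped — the nucleotide-level CDR3."""
        return self.junction_nt[3:-3]


_GENE_RE = re.compile(r"^([A-Za-z]+\d+)")


def strip_allele(gene_call: str) -> str:
    """Drop the IMGT allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return gene_call.split("*", 1)[0].strip()


def gene_family(gene_call: str) -> str:
    """Family token of an IMGT-style gene call.

    The allele is stripped and the text before the first hyphen is returned
    (``IGHV3-23*01`` -> ``IGHV3``). Genes without a hyphen (J genes) are their
    own family (``IGHJ6*02`` -> ``IGHJ6``).
    """
    name = strip_allele(gene_call)
    name = name.split("-", 1)[0]
    m = _GENE_RE.fullmatch(name)
    if m is None:
        raise GeneNameError(f"cannot parse gene call {gene_call!r}")
    return m.group(1)
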