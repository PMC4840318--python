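"""Reading and writing repertoire data.

Sequences move as FASTA/FASTQ (Biopython-backed); annotated rearrangements
move as AIRR-style tab-separated tables with the community column names
(``sequence_id``, ``v_call``, ``j_call``, ``junction``, ``junction_aa``,
``sequence_alignment``, ``germline_alignment``, ...). Somatic substitutions
are serialized in a compact ``pos:ref>alt`` comma list so a written table
round-trips losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Mutation, Rearrangement, SequenceRead

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed sequence file."""


class SchemaError(ValueError):
    """Rearrangement table is missing required columns."""


REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "junction", "junction_aa")

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SequenceRead]:
    """Read a FASTA file into :class:`SequenceRead` records, order preserved."""
    reads: list[SequenceRead] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: entry {rec.id!r} has an empty sequence")
        reads.append(SequenceRead(id=rec.id, seq=seq))
    if not reads:
        raise ParseError(f"{path}: no FASTA records found")
    return reads


def read_fastq(path: str | Path) -> list[SequenceRead]:
    reads: list[SequenceRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: entry {rec.id!r} has an empty sequence")
        reads.append(
            SequenceRead(id=rec.id, seq=seq, qual=list(rec.letter_annotations["phred_quality"]))
        )
    if not reads:
        raise ParseError(f"{path}: no FASTQ records found")
    return reads


def write_fasta(reads: list[SequenceRead], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[SequenceRead], path: str | Path) -> None:
    records = []
    for r in reads:
        qual = r.qual if r.qual is not None else [40] * len(r.seq)
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# AIRR-style rearrangement tables


def _row_get(row, col) -> str | None:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return None
    s = str(val).strip()
    return s or None


def read_rearrangements(path: str | Path) -> list[Rearrangement]:
    """Read an AIRR-style rearrangement TSV.

    Rows missing any of ``v_call``, ``j_call`` or ``junction_aa`` are dropped
    with a logged count; the remainder map onto :class:`Rearrangement`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[Rearrangement] = []
    n_dropped = 0
    for _, row in df.iterrows():
        v_call = _row_get(row, "v_call")
        j_call = _row_get(row, "j_call")
        junction = _row_get(row, "junction")
        junction_aa = _row_get(row, "junction_aa")
        if not (v_call and j_call and junction and junction_aa):
            n_dropped += 1
            continue
        cdr3_aa = _row_get(row, "cdr3_aa") or junction_aa[1:-1]
        mut_field = _row_get(row, "mutations")
        mutations = (
            [Mutation.from_string(tok) for tok in mut_field.split(",")] if mut_field else []
        )
        seq_aln = _row_get(row, "sequence_alignment")
        germ_aln = _row_get(row, "germline_alignment")
        if not mutations and seq_aln and germ_aln:
            mutations = derive_mutations(seq_aln, germ_aln)
        records.append(
            Rearrangement(
                sequence_id=_row_get(row, "sequence_id"),
                v_gene=v_call,
                d_gene=_row_get(row, "d_call"),
                j_gene=j_call,
                junction_nt=junction,
                cdr3_aa=cdr3_aa,
                donor_id=_row_get(row, "donor_id"),
                uaid=_row_get(row, "uaid"),
                sequence_alignment=seq_aln,
                germline_alignment=germ_aln,
                mutations=mutations,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows lacking v_call/j_call/junction_aa", path, n_dropped)
    return records


def write_rearrangements(records: list[Rearrangement], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "v_call": r.v_gene,
                "d_call": r.d_gene,
                "j_call": r.j_gene,
                "junction": r.junction_nt,
                "junction_aa": "C" + r.cdr3_aa + "W" if r.cdr3_aa else None,
                "cdr3_aa": r.cdr3_aa,
                "donor_id": r.donor_id,
                "uaid": r.uaid,
                "sequence_alignment": r.sequence_alignment,
                "germline_alignment": r.germline_alignment,
                "mutations": ",".join(str(m) for m in r.mutations) or None,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation derivation

_GAPS = {"-", "."}
_BASES = {"A", "C", "G", "T"}


def derive_mutations(sequence_alignment: str, germline_alignment: str) -> list[Mutation]:
    """Somatic substitutions between an aligned observed sequence and its
    aligned germline.

    One :class:`Mutation` per alignment column where both strings hold an
    unambiguous base (A/C/G/T) and the bases differ. Positions are 1-based
    alignment-column indices. Gap columns and N bases yield nothing: the
    substitution list deliberately ignores indels, which are rare in somatic
    hypermutation and are not part of the shared-mutation bonus.
    """
    if len(sequence_alignment) != len(germline_alignment):
        raise ValueError("aligned sequence and germline must have equal length")
    muts: list[Mutation] = []
    for i, (s, g) in enumerate(zip(sequence_alignment.upper(), germline_alignment.upper()), 1):
        if s in _BASES and g in _BASES and s != g:
            muts.append(Mutation(pos=i, ref=g, alt=s))
    return muts
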