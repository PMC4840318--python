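"""UMI (unique antibody identifier) consensus error correction.

Each transcript is tagged with a random barcode before amplification, so
reads sharing a barcode are copies of one molecule. Collapsing each barcode
bin to a per-column plurality consensus removes both amplification bias
(every molecule counts once, however hard it amplified) and sequencing error
(independent errors are voted out). Bins with a single read are discarded —
with one observation, error and signal cannot be told apart.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .records import SequenceRead

logger = logging.getLogger(__name__)

__all__ = [
    "UAIDBin",
    "ConsensusRecord",
    "extract_uaid",
    "bin_by_uaid",
    "filter_bins",
    "build_consensus",
    "correct_repertoire",
]


@dataclass
class UAIDBin:
    uaid: str
    reads: list[SequenceRead]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class ConsensusRecord:
    uaid: str
    seq: str
    support: int  # number of reads that voted


def extract_uaid(read: SequenceRead, uaid_length: int = 20) -> tuple[str, SequenceRead] | None:
    """Split a read into its leading barcode and the trimmed remainder.

    Returns None (with a logged warning) for reads too short to carry both a
    barcode and at least one transcript base.
    """
    if len(read.seq) <= uaid_length:
        logger.warning("read %s shorter than UAID length %d; skipped", read.id, uaid_length)
        return None
    uaid = read.seq[:uaid_length]
    trimmed = SequenceRead(id=read.id, seq=read.seq[uaid_length:],
                           qual=read.qual[uaid_length:] if read.qual else None)
    return uaid, trimmed


def bin_by_uaid(extracted: Iterable[tuple[str, SequenceRead]]) -> list[UAIDBin]:
    """Group UAID-extracted reads into one bin per distinct barcode."""
    bins: dict[str, list[SequenceRead]] = {}
    for uaid, read in extracted:
        bins.setdefault(uaid, []).append(read)
    return [UAIDBin(uaid=u, reads=r) for u, r in bins.items()]


def filter_bins(bins: Sequence[UAIDBin], min_bin_size: int = 2) -> list[UAIDBin]:
    """Drop bins smaller than ``min_bin_size`` (default: discard singletons)."""
    kept = [b for b in bins if b.size >= min_bin_size]
    n_discarded = len(bins) - len(kept)
    if n_discarded:
        logger.info("discarded %d bins below size %d", n_discarded, min_bin_size)
    return kept


def _column_consensus(bases: list[str], germ_base: str | None) -> str:
    counts = Counter(bases)
    top = max(counts.values())
    tied = sorted(b for b, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    if germ_base is not None and germ_base in tied:
        return germ_base
    return tied[0]  # lexicographically smallest tied base


def build_consensus(bin: UAIDBin, germline_v_seq: str | None = None) -> ConsensusRecord:
    """Per-column plurality consensus of a bin.

    Reads are anchored at their start and voting runs over the modal read
    length (copies of one transcript differ in length only through rare
    indel errors). The germline V sequence casts no votes; it only breaks
    exact ties at columns it covers.
    """
    if not bin.reads:
        raise ValueError("cannot build a consensus from an empty bin")
    lengths = Counter(len(r.seq) for r in bin.reads)
    top = max(lengths.values())
    length = min(L for L, c in lengths.items() if c == top)
    consensus = []
    for col in range(length):
        bases = [r.seq[col] for r in bin.reads if col < len(r.seq)]
        germ = germline_v_seq[col] if germline_v_seq and col < len(germline_v_seq) else None
        consensus.append(_column_consensus(bases, germ))
    return ConsensusRecord(uaid=bin.uaid, seq="".join(consensus), support=bin.size)


def correct_repertoire(
    reads: Sequence[SequenceRead],
    uaid_length: int = 20,
    germline_lookup: Callable[[UAIDBin], str | None] | None = None,
    min_bin_size: int = 2,
) -> list[ConsensusRecord]:
    """End-to-end correction: extract barcodes, bin, drop singletons, build
    one consensus per surviving bin.

    ``germline_lookup`` maps a bin to the germline V sequence used as the
    consensus tiebreaker (e.g. via a quick gene assignment of one read);
    omit it to break ties lexicographically.
    """
    extracted = [e for r in reads if (e := extract_uaid(r, uaid_length)) is not None]
    bins = bin_by_uaid(extracted)
    bins = filter_bins(bins, min_bin_size=min_bin_size)
    out = []
    for b in sorted(bins, key=lambda b: b.uaid):
        germ = germline_lookup(b) if germline_lookup else None
        out.append(build_consensus(b, germ))
    return out
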