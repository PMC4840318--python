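"""Ground-truth repertoire simulation.

The generator emulates an IgG+ memory heavy-chain repertoire at desk scale:

* naive ancestors drawn from the built-in germline catalog with stochastic
  junctions (conserved Cys-anchored prefix, random N-region codons, a
  germline-encoded J suffix ending in the conserved Trp);
* clonal lineages expanded from each ancestor under substitution-dominated
  somatic hypermutation (star topology by default; an optional two-level
  topology gives clade members shared intermediate mutations);
* lineage sizes drawn from a truncated discrete power law, producing the
  singleton-dominated size spectrum memory repertoires show;
* multi-donor pools in which no true lineage ever spans donors;
* read libraries with per-transcript random UMIs (unique antibody
  identifiers), heavy-tailed log-normal amplification, and uniform per-base
  sequencing error.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from . import germlines
from .io import derive_mutations
from .records import Rearrangement, SequenceRead

__all__ = [
    "SimConfig",
    "SimTruth",
    "sample_naive_rearrangement",
    "expand_lineage",
    "simulate_repertoire",
    "simulate_reads",
    "unique_labeling_probability",
]

_SENSE_CODONS = sorted(standard_dna_table.forward_table)
# deterministic reverse translation: lexicographically smallest codon per residue
_AA_TO_CODON: dict[str, str] = {}
for codon in _SENSE_CODONS:
    aa = standard_dna_table.forward_table[codon]
    _AA_TO_CODON.setdefault(aa, codon)
_AA_TO_CODON["W"] = "TGG"

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the synthetic repertoire.

    Defaults: 50 lineages with truncated power-law sizes (exponent 2.0,
    max 100), star-topology hypermutation at 0.02 substitutions/base per
    member, junction lengths ~ Normal(17, 3) amino acids clipped to [10, 26],
    one donor, 20-nt UMIs, log-normal amplification (mu 1.0, sigma 1.5) and
    0.5% per-base sequencing error.
    """

    n_lineages: int = 50
    alpha: float = 2.0  # power-law exponent of the lineage-size law (> 1)
    max_lineage_size: int = 100
    shm_sub_rate: float = 0.02  # per-base substitution probability per member
    shm_indel_rate: float = 0.0  # per-sequence indel probability (kept rare)
    topology: str = "star"  # "star" | "two_level"
    junction_len_mean: float = 17.0  # amino acids, including both anchors
    junction_len_sd: float = 3.0
    junction_len_range: tuple[int, int] = (10, 26)
    n_donors: int = 1
    uaid_length: int = 20
    amplification_mu: float = 1.0  # log-normal copy-count parameters
    amplification_sigma: float = 1.5
    seq_error_rate: float = 0.005
    v_weights: dict[str, float] | None = None  # optional non-uniform V usage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        for name in ("shm_sub_rate", "shm_indel_rate", "seq_error_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth labels: sequence_id -> true lineage, donor, transcript."""

    lineage_of: dict[str, str] = field(default_factory=dict)
    donor_of: dict[str, str] = field(default_factory=dict)
    transcript_of: dict[str, str] = field(default_factory=dict)


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _sample_junction(config: SimConfig, rng: np.random.Generator, j_name: str) -> str:
    """Junction nucleotides: CAR prefix + random sense codons + J suffix."""
    suffix_aa = germlines.J_JUNCTION_SUFFIX_AA[j_name]
    lo, hi = config.junction_len_range
    lo = max(lo, len(germlines.V_JUNCTION_PREFIX_AA) + len(suffix_aa) + 1)
    length = int(round(rng.normal(config.junction_len_mean, config.junction_len_sd)))
    length = min(max(length, lo), hi)
    n_middle = length - len(germlines.V_JUNCTION_PREFIX_AA) - len(suffix_aa)
    middle = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_middle)
    )
    suffix_nt = "".join(_AA_TO_CODON[a] for a in suffix_aa)
    return germlines.V_JUNCTION_PREFIX_NT + middle + suffix_nt


def sample_naive_rearrangement(
    config: SimConfig, rng: np.random.Generator, sequence_id: str = "naive"
) -> Rearrangement:
    """Draw one unmutated ancestor: random V and J, stochastic junction."""
    v_names = sorted(germlines.V_GENES)
    if config.v_weights:
        w = np.array([config.v_weights.get(v, 0.0) for v in v_names])
        v_name = v_names[rng.choice(len(v_names), p=w / w.sum())]
    else:
        v_name = v_names[rng.integers(0, len(v_names))]
    j_names = sorted(germlines.J_GENES)
    j_name = j_names[rng.integers(0, len(j_names))]
    junction = _sample_junction(config, rng, j_name)
    seq = germlines.V_GENES[v_name] + junction + germlines.J_GENES[j_name]
    return Rearrangement(
        sequence_id=sequence_id,
        v_gene=v_name,
        j_gene=j_name,
        junction_nt=junction,
        cdr3_aa=_translate(junction)[1:-1],
        sequence_alignment=seq,
        germline_alignment=seq,
        mutations=[],
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-base substitutions at the given rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def _apply_indel(seq: str, junction_end: int, rng: np.random.Generator) -> str:
    """Single in-frame 3-nt indel placed downstream of the junction, so
    anchors and coordinates upstream stay intact (indel mutations are rare
    and deliberately simple here)."""
    pos = int(rng.integers(junction_end, len(seq) - 3))
    pos -= pos % 3
    if rng.random() < 0.5:
        return seq[:pos] + seq[pos + 3 :]
    ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
    return seq[:pos] + ins + seq[pos:]


def _derived_member(
    ancestor: Rearrangement, seq: str, sequence_id: str
) -> Rearrangement:
    junction_len = len(ancestor.junction_nt)
    junction = seq[germlines.V_LENGTH : germlines.V_LENGTH + junction_len]
    germ = ancestor.germline_alignment
    muts = derive_mutations(seq, germ) if len(seq) == len(germ) else []
    return Rearrangement(
        sequence_id=sequence_id,
        v_gene=ancestor.v_gene,
        j_gene=ancestor.j_gene,
        junction_nt=junction,
        cdr3_aa=_translate(junction)[1:-1],
        sequence_alignment=seq,
        germline_alignment=germ if len(seq) == len(germ) else None,
        mutations=muts,
    )


def expand_lineage(
    ancestor: Rearrangement,
    size: int,
    config: SimConfig,
    rng: np.random.Generator,
    id_prefix: str = "M",
) -> list[Rearrangement]:
    """Expand one ancestor into ``size`` hypermutated members.

    Star topology mutates every member independently from the ancestor.
    The two-level topology first draws intermediate ancestors (one per ~4
    members) and mutates members from their intermediate, so clade members
    share the intermediate's substitutions — exercising the shared-mutation
    bonus the way real lineages do.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    anc_seq = ancestor.sequence_alignment
    junction_end = germlines.V_LENGTH + len(ancestor.junction_nt)
    if config.topology == "two_level" and size > 2:
        n_inter = max(1, math.ceil(size / 4))
        intermediates = [
            _mutate(anc_seq, config.shm_sub_rate, rng) for _ in range(n_inter)
        ]
        parents = [intermediates[i % n_inter] for i in range(size)]
    else:
        parents = [anc_seq] * size
    members = []
    for i, parent in enumerate(parents, 1):
        seq = _mutate(parent, config.shm_sub_rate, rng)
        if config.shm_indel_rate > 0 and rng.random() < config.shm_indel_rate:
            seq = _apply_indel(seq, junction_end, rng)
        members.append(_derived_member(ancestor, seq, f"{id_prefix}{i:04d}"))
    return members


def _sample_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.arange(1, config.max_lineage_size + 1)
    probs = sizes.astype(np.float64) ** -config.alpha
    probs /= probs.sum()
    return rng.choice(sizes, size=config.n_lineages, p=probs)


def simulate_repertoire(config: SimConfig) -> tuple[list[Rearrangement], SimTruth]:
    """Full truth-labeled repertoire: ancestors, power-law lineage sizes,
    round-robin donor assignment (no true lineage spans donors)."""
    rng = np.random.default_rng(config.seed)
    sizes = _sample_sizes(config, rng)
    records: list[Rearrangement] = []
    truth = SimTruth()
    seq_counter = 0
    for li, size in enumerate(sizes, 1):
        lineage_id = f"T{li:05d}"
        donor_id = f"D{(li - 1) % config.n_donors + 1}"
        ancestor = sample_naive_rearrangement(config, rng, sequence_id=lineage_id)
        for member in expand_lineage(ancestor, int(size), config, rng):
            seq_counter += 1
            member.sequence_id = f"S{seq_counter:06d}"
            member.donor_id = donor_id
            records.append(member)
            truth.lineage_of[member.sequence_id] = lineage_id
            truth.donor_of[member.sequence_id] = donor_id
            truth.transcript_of[member.sequence_id] = member.sequence_alignment
    return records, truth


def simulate_reads(
    records: list[Rearrangement], config: SimConfig
) -> tuple[list[SequenceRead], dict[str, str]]:
    """UMI-tagged read library from a set of transcripts.

    Each transcript gets one random barcode, a log-normal copy count, and
    independent per-base errors on every copy (barcode included — barcode
    errors create spurious singleton bins, as in real libraries). Returns the
    reads and a read-id -> transcript-id truth map.
    """
    rng = np.random.default_rng([config.seed, 7])
    reads: list[SequenceRead] = []
    read_truth: dict[str, str] = {}
    for rec in records:
        uaid = "".join(_BASES[i] for i in rng.integers(0, 4, size=config.uaid_length))
        copies = max(1, int(rng.lognormal(config.amplification_mu, config.amplification_sigma)))
        transcript = uaid + (rec.sequence_alignment or rec.junction_nt)
        for c in range(1, copies + 1):
            seq = transcript
            if config.seq_error_rate > 0:
                n_err = rng.binomial(len(seq), config.seq_error_rate)
                if n_err:
                    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                    pos = rng.choice(len(arr), size=n_err, replace=False)
                    for p in pos:
                        choices = [b for b in b"ACGT" if b != arr[p]]
                        arr[p] = choices[rng.integers(0, 3)]
                    seq = arr.tobytes().decode("ascii")
            read_id = f"{rec.sequence_id}.r{c}"
            reads.append(SequenceRead(id=read_id, seq=seq))
            read_truth[read_id] = rec.sequence_id
    return reads, read_truth


def unique_labeling_probability(
    n_transcripts: int, barcode_length: int, method: str = "exact"
) -> float:
    """Probability that every one of ``n_transcripts`` transcripts draws a
    distinct random barcode of the given length (the birthday problem over
    ``4**barcode_length`` labels).

    ``method="exact"`` evaluates the product ``prod_{i<N} (1 - i/4^L)``;
    ``method="approx"`` uses ``exp(-N(N-1)/(2*4^L))``. In the regime of
    interest (20-nt barcodes, repertoire-scale pools) the two agree to at
    least six decimals.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    space = 4**barcode_length
    if n_transcripts > space:
        return 0.0
    if method == "approx":
        return math.exp(-n_transcripts * (n_transcripts - 1) / (2 * space))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'approx'")
    log_p = math.fsum(math.log1p(-i / space) for i in range(n_transcripts))
    return math.exp(log_p)
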