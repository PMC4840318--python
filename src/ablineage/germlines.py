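"""Built-in synthetic germline catalog for simulation and testing.

Twelve heavy-chain V genes spanning five families plus six J genes, with
nucleotide sequences generated deterministically at import time from a fixed
seed. Genes within a family share a family base sequence with ~8%
gene-specific substitutions, mimicking the family structure real IMGT
catalogs have. These are synthetic stand-ins — not real IMGT alleles — sized
and named like the real thing so every downstream component (family parsing,
germline consensus tiebreaking, mutation coordinates) exercises realistic
inputs without bundling reference data.
"""

from __future__ import annotations

import numpy as np

V_LENGTH = 270  # multiple of 3, ends immediately before the junction's conserved Cys codon
J_LENGTH = 45  # multiple of 3, starts immediately after the junction's conserved Trp codon

_BASES = np.array(list("ACGT"))

# gene name -> family is encoded in the name itself (text before the hyphen)
_V_NAMES = [
    "IGHV1-2*01",
    "IGHV1-18*01",
    "IGHV1-69*01",
    "IGHV2-5*01",
    "IGHV3-7*01",
    "IGHV3-23*01",
    "IGHV3-30*01",
    "IGHV3-48*01",
    "IGHV4-34*01",
    "IGHV4-39*01",
    "IGHV4-59*01",
    "IGHV5-51*01",
]
_J_NAMES = ["IGHJ1*01", "IGHJ2*01", "IGHJ3*01", "IGHJ4*01", "IGHJ5*01", "IGHJ6*01"]

# junction amino-acid suffix contributed by each J gene; the conserved Trp is
# last. Short junctions are therefore mostly germline-encoded, as in real
# repertoires, which is what makes coincidental cross-donor matches possible.
J_JUNCTION_SUFFIX_AA = {
    "IGHJ1*01": "QHW",
    "IGHJ2*01": "DLW",
    "IGHJ3*01": "DIW",
    "IGHJ4*01": "FDYW",
    "IGHJ5*01": "FDSW",
    "IGHJ6*01": "MDVW",
}

# junction prefix contributed by the V gene end: conserved Cys + 'AR'
V_JUNCTION_PREFIX_AA = "CAR"
V_JUNCTION_PREFIX_NT = "TGTGCTCGT"  # C  A  R


def _build_catalog() -> tuple[dict[str, str], dict[str, str]]:
    rng = np.random.default_rng(20160422)
    families: dict[str, np.ndarray] = {}
    v_genes: dict[str, str] = {}
    for name in _V_NAMES:
        fam = name.split("-")[0]
        if fam not in families:
            families[fam] = rng.integers(0, 4, size=V_LENGTH)
        base = families[fam].copy()
        mask = rng.random(V_LENGTH) < 0.08
        base[mask] = (base[mask] + rng.integers(1, 4, size=mask.sum())) % 4
        v_genes[name] = "".join(_BASES[base])
    j_genes: dict[str, str] = {}
    for name in _J_NAMES:
        j_genes[name] = "".join(_BASES[rng.integers(0, 4, size=J_LENGTH)])
    return v_genes, j_genes


V_GENES, J_GENES = _build_catalog()
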