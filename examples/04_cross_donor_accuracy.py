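"""Cross-donor discrimination: an accuracy test without ground truth.

True clonal lineages descend from one naive B cell, so they can never span
donors. Pooling several donors and counting sequences assigned to a lineage
dominated by a different donor therefore upper-bounds the assignment error,
and the coincidental matches that do occur concentrate among short, low-
diversity CDR3s.
"""

from ablineage import (
    SimConfig,
    assign_lineages,
    cross_donor_contamination,
    short_hcdr3_enrichment,
    simulate_repertoire,
)

config = SimConfig(seed=5, n_lineages=2400, alpha=2.0, n_donors=8)
records, truth = simulate_repertoire(config)
partition = assign_lineages(records)
contamination = cross_donor_contamination(partition, truth.donor_of)
frac_short_bad, frac_short_good = short_hcdr3_enrichment(records, partition, truth.donor_of)

print(f"pooled sequences:       {len(records)} from 8 donors")
print(f"contamination:          {contamination:.4f}")
print(f"short CDR3 (<15 aa) among incorrect: {frac_short_bad:.2f}")
print(f"short CDR3 (<15 aa) among correct:   {frac_short_good:.2f}")
# Contamination ~1% or less mirrors the discrimination a stringent assigner
# achieves; the enrichment of short CDR3s among the 'incorrect' sequences
# shows those few are genuine junctional coincidences, not loose clustering.
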