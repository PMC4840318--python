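# ablineage

Unseeded clonal-lineage assignment for antibody repertoire (AIRR-seq) data.

A clonal lineage is the set of antibody sequences descending from a single
naive B cell. Grouping a whole heavy-chain repertoire into lineages — with
no "seed" antibody to search around — is the natural unit for studying
responses to infection and vaccination, but it demands a distance measure
that tolerates heavy somatic hypermutation without merging unrelated clones.
`ablineage` implements such a measure, the clustering built on it, the
UMI-based error correction the raw data needs first, a ground-truth
repertoire simulator, and the evaluation machinery to test all of it.

## The distance metric

For a pair of heavy-chain records with CDR3 sequences $c_1, c_2$:

$$
d = \frac{\max\!\Big(0,\; \mathrm{edit}(c_1,c_2) \;+\; 10\,[V_1 \neq V_2] \;+\; 8\,[J_1 \neq J_2] \;-\; 0.35\, s \Big)}{\min(|c_1|, |c_2|)}
$$

where $\mathrm{edit}$ is a weighted Levenshtein distance with indels costing
twice a substitution (indel somatic mutations are rare), computed gaplessly
when $|c_1| = |c_2|$ (gaps between same-length CDR3s produce spuriously low
scores); $[V_1 \neq V_2]$ and $[J_1 \neq J_2]$ compare germline gene calls
with alleles stripped; and $s$ counts shared somatic substitutions — the
same position, the same base change, in both sequences. Pairs from
different V-gene families short-circuit to a large sentinel distance.

Repertoires are then hierarchically clustered (average linkage) and the tree
is cut at a threshold calibrated from data: all-vs-all scores are bimodal
(related pairs near 0, unrelated pairs ≳ 1) and the cutoff is placed at the
low-frequency trough between the modes.

Upstream of clustering, reads tagged with 20-nt unique antibody identifiers
(UAIDs/UMIs) are binned by barcode, singleton bins discarded, and each bin
collapsed to a plurality consensus with the germline V region breaking exact
ties — removing amplification bias and sequencing error together.

## Worked example

```bash
python examples/01_assign_lineages.py
```

```
sequences:            583
true lineages:        50
assigned lineages:    50
pairwise precision:   1.000
pairwise recall:      1.000
clonality fraction:   0.978
```

A simulated 50-lineage repertoire (583 sequences, star-topology
hypermutation) is assigned with default parameters. Precision is the
fraction of co-clustered pairs that are truly clonally related, recall the
fraction of truly related pairs kept together; both reach 1.000 here, i.e.
the partition reproduces the ground truth exactly. The clonality fraction
(0.978) is the share of sequences in lineages with at least two members.

The other scripts in `examples/` each demonstrate one capability: threshold
calibration from the score histogram, UMI consensus correction, cross-donor
discrimination, lineage networks, and barcode-collision math. The
command-line interface wires the same steps into a pipeline:

```bash
ablineage simulate --out-rearr rearr.tsv --out-truth truth.tsv --seed 1
ablineage assign --input rearr.tsv --out clones.tsv
ablineage evaluate --rearr rearr.tsv --clones clones.tsv --truth truth.tsv --report report.json
```

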