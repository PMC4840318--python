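# Methods

## The model

An antibody clonal lineage is the set of heavy-chain sequences descended
from one naive B cell. Members share the V(D)J recombination event — hence
the germline V and J genes and, approximately, the CDR3 — and accumulate
somatic substitutions as the clone matures. `ablineage` treats lineage
assignment as clustering under an antibody-specific dissimilarity that
encodes exactly these expectations.

### Pairwise distance

For records with CDR3s `c1`, `c2` (amino acid by default; a nucleotide mode
uses the junction with anchor codons stripped):

1. **CDR3 edit distance.** Weighted Levenshtein with substitution cost 1 and
   indel cost 2, reflecting the rarity of indel somatic mutations. When the
   CDR3s have equal length the comparison is forced gapless: an optimal
   gapped alignment of equal-length strings can exploit register shifts and
   return a deceptively low score (`ABCDEF` vs `BCDEFA`: 4 gapped, 6
   gapless).
2. **Germline penalties.** +10 if the V genes differ, +8 if the J genes
   differ, at the gene level with alleles stripped — allele calls are the
   least reliable annotation level, and mis-assignment of the gene itself
   happens often enough that mismatches are penalized rather than forbidden.
3. **Shared-mutation bonus.** −0.35 per substitution present in both records
   as the identical `(position, ref, alt)` triple in germline-alignment
   coordinates. This is the signal that holds highly mutated relatives
   together when their CDR3s have diverged. No cap is applied; the adjusted
   score is floored at 0 before normalization (negative dissimilarities are
   meaningless to linkage clustering). Shared-mutation counting does not
   require identical V calls — a V mismatch is already penalized separately.
4. **Normalization.** The adjusted score is divided by the shorter CDR3
   length, making the threshold scale-free across junction lengths.

Cross-V-family pairs are almost never clonal; with the family pre-screen on
(default) they score a finite sentinel (100.0) without further computation.
A finite sentinel keeps every linkage computation well defined while sitting
orders of magnitude above any plausible threshold. The metric is symmetric
and zero on identity but deliberately **not** a metric in the mathematical
sense — penalties and bonuses break the triangle inequality — which linkage
clustering does not require.

Bulk all-vs-all scoring runs in a numba-compiled kernel over integer-encoded
records; a pure-Python reference path computes identical values (asserted
exactly in the tests) and serves readability.

### Clustering

Agglomerative clustering (scipy, average linkage by default) on the
condensed distance matrix, cut so that all merges at height ≤ threshold are
applied. Average linkage was chosen because single linkage chains clusters
through coincidental near pairs and complete linkage shatters large, highly
mutated clones; the option remains configurable. With pre-clustering by V
gene or V family, each group is clustered separately; because cross-family
pairs carry the sentinel distance, family pre-clustering provably reproduces
the global partition whenever sentinel ≫ threshold (asserted on simulation).

### Threshold calibration

All-vs-all scores of a repertoire sample (default 1000 sequences) are
binned at width 0.05 on the normalized-score axis. Sentinel scores are
excluded — they carry no boundary information and would distort the search.
Counts are smoothed with a centred 5-bin moving average; local maxima are
located; the related/unrelated mode pair is chosen as the pair of maxima
with the deepest valley between them (maximizing `min(heights) − valley`),
and the threshold is the bin-center of the minimum strictly between the two,
leftmost on ties. Selecting modes by valley depth rather than by raw height
matters in practice: the broad unrelated mode is ragged, and two of its
bumps can individually out-rank the compact related mode near zero. A
unimodal histogram raises a calibration error instructing a manual choice
rather than guessing. The shipped default threshold (0.35) is an
implementation default for running without calibration; the calibrated value
is preferred and is non-inferior on simulation (tested over 10 seeds).

### UMI consensus correction

Reads are split into a leading barcode (default 20 nt) and payload, binned
by barcode, and singleton bins are discarded — a single observation cannot
distinguish error from signal. Each surviving bin is collapsed by per-column
plurality over reads anchored at their start, voting across the modal read
length (bin members are copies of one transcript; length differences arise
only from rare indel errors, and an external MSA can be plugged in where
that assumption fails). The germline V sequence casts no votes; it resolves
exact ties at columns it covers, with a lexicographic fallback elsewhere —
the deterministic choice for the case the procedure leaves open. An optional
bin-purity check is deliberately absent: 20-nt barcodes make collisions rare
(the exact birthday product gives 97.2% unique labeling at a 250,000
transcript pool), so no collision-splitting is attempted.

## The simulator

The generator emulates an IgG+ memory heavy-chain repertoire:

* **Germlines.** A synthetic catalog of 12 V genes in 5 families and 6 J
  genes (270/45 nt), generated at import from a fixed seed with ~8%
  intra-family divergence. Synthetic stand-ins, not IMGT alleles.
* **Junctions.** Length ~ Normal(17, 3) aa clipped to [10, 26], matching the
  observed heavy-chain CDR3 length distribution. The junction is a conserved
  `CAR` prefix, random sense codons in the middle, and a germline-encoded
  J-specific suffix ending in the conserved Trp. Short junctions are thus
  mostly germline-encoded with little random content — which is why
  coincidental cross-donor matches concentrate there, as in real data.
* **Hypermutation.** Star topology by default: each member draws independent
  substitutions at 0.02/base from the naive ancestor, a modest, realistic
  intra-clone divergence (memory clones span roughly 2–10% pairwise).
  A two-level topology adds intermediate ancestors so clade members share
  mutations, exercising the shared-mutation bonus. Indels are off by default
  and, when enabled, are placed as rare in-frame events outside the
  junction. Junction mutations that create stop codons are retained ('*' in
  the CDR3); real pipelines drop non-functional sequences upstream, which is
  out of scope here.
* **Lineage sizes.** Truncated discrete power law `P(s) ∝ s^(−α)`,
  `s ≤ 100`. The general default `α = 2.0` balances related and unrelated
  pair mass (useful for calibration and recovery studies); `α = 3.0`
  reproduces the singleton-dominated spectrum of real memory repertoires
  (~83% singleton lineages, tested over 20 seeds).
* **Donors.** Lineages are assigned round-robin, so no true lineage spans
  donors — the invariant the cross-donor accuracy proxy relies on.
* **Reads.** One random barcode per transcript, log-normal copy counts
  (default μ=1.0, σ=1.5; raising σ reproduces bins of >1000 reads), uniform
  per-base substitution error (default 0.5%) applied to the whole read,
  barcode included.

Everything is deterministic under the configured seed.

### What the simulator does not capture

No selection or affinity maturation dynamics, no biased mutation hotspots
(mutations are uniform), no isotypes or light chains, no non-functional
sequence contamination, and germlines are synthetic. Passing tests therefore
demonstrate the algorithmic properties of the pipeline — separation of
related and unrelated score modes, error suppression, donor discrimination
under junctional coincidence — not performance on any particular real
dataset. Benchmarks that require external sequence collections (curated
broadly neutralizing antibody panels with known lineages, concordance with
seeded assignment tools, real-repertoire clonality plateaus and singleton
fractions) are out of desk scope; the package ships the evaluation
machinery and simulated stand-ins instead.

## Evaluation definitions

* **Clonality fraction:** sequences in lineages of size ≥ 2 over all
  sequences.
* **Cross-donor contamination:** a sequence is incorrect when its donor
  differs from its lineage's modal donor (ties broken lexicographically for
  determinism). A stricter rule — every member of any multi-donor lineage is
  incorrect — is available behind a flag; the modal rule is the default
  because the strict rule double-counts the majority members of a lineage
  that captured one stray sequence.
* **Pairwise precision/recall:** pair counting against simulation truth;
  undefined ratios (0/0) are reported as `None`, never coerced to 0 or 1.
* **LOOCV pools:** one pool per donor containing seeded-random draws from
  every other donor; on simulation, pool clonality matches single-donor sets
  of the same per-donor depth and sits below single-donor sets of the full
  pooled depth — the directional signature of donor-aware assignment.
* **Lineage graphs:** identical sequences collapse to weighted nodes; each
  node gains an edge to every node at its minimum distance (one edge per
  co-nearest neighbor). The graph need not be connected.
* **Germline usage:** sequence level counts every record; lineage level
  counts each lineage once via its modal family, removing lineage-size
  influence.

## Numerical and scale choices

Test and acceptance runs use desk-scale problem sizes chosen to make the
statistics stable: ~120–200 sequences per calibration repertoire across 10
seeds, 500–1300 sequences for parameter recovery, ~7900 sequences for the
8-donor contamination study, and 100 transcripts × 1–50 copies for consensus
accuracy. The edit-distance oracle check is exhaustive over all 4-letter
strings to length 3 and samples 4000 longer pairs to length 6. Histogram
bin width (0.05), smoothing window (5 bins), and the lexicographic/leftmost
tie-breaks throughout are fixed so every result is reproducible bit-for-bit
under a seed.

## Known limitations

The distance is not a true metric (documented, not asserted). Consensus
building assumes pre-oriented, merged reads and does not cluster
near-identical barcodes ("UMI networks"). Frameshift-indel repair, V(D)J
annotation, and light-chain pairing are upstream/out of scope — the package
consumes annotated rearrangement tables (AIRR-style TSV) and FASTA/FASTQ
reads.
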