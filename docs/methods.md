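# Methods

## Scope and model

`gretarget` implements an integrative prioritization of transcription-factor
(TF) direct target genes. The object of inference is ordinal, not
probabilistic: given a set of differentially expressed (DE) genes and four
independent layers of regulatory evidence — TF ChIP peaks, classed
open-chromatin regions, enhancer-target association scores and binding-motif
occurrences — the pipeline orders the DE genes from most to least likely to
be bound-and-regulated directly. No error model is attached to the ordering;
the rank product is used purely as an ordering statistic (its value for a
gene ranked r₁ and r₂ out of n is (r₁/n)(r₂/n), which is small only when
both lines of evidence agree), not as a calibrated p-value.

### Peak-to-gene association

A peak is associated with a gene when the peak anchor lies within
`window_bp` of the gene's TSS; the window is symmetric, inclusive at
exactly `window_bp`, and defaults to 150 kb (100 kb in the NAS-only mode).
The anchor is the peak center, `floor((start+end)/2)` — upstream sources
rarely state their anchor convention, so the center was chosen as the most
widely used one and a `nearest_edge` alternative is exposed in
`WindowConfig` for sensitivity analysis. Associations with
|distance| ≤ 3000 bp are *proximal*; *distal* therefore covers
3001 bp..window. Both cutoffs are inclusive on the proximal side so that
the two ranges partition the window exactly. A peak may associate with
several genes and vice versa; each (peak, gene) pair is counted as one
association throughout (including in the distal-fraction summary).

Intervals are 0-based half-open everywhere; two intervals overlap when
they share at least one base (`a.start < b.end and b.start < a.end`). No
minimum-overlap fraction is imposed. Chromosome names are compared
verbatim.

### Annotation scores

* **Open Chromatin Score**: each GRE contributes the *maximum*
  chromatin-class weight among the accessible regions it overlaps; the
  gene's score is the sum over its GREs. The max rule prevents stacked or
  redundant annotations from double-counting a single element; a `sum`
  rule is available by flag. An open-chromatin region whose class is
  missing from the weight table is a configuration error, never a silent
  zero.
* **Enhancer-Target Score**: the sum of enhancer-gene association scores
  over all (GRE, enhancer) overlap pairs whose enhancer is annotated to
  that same gene. The enhancer input is a 5-column TSV
  (`chrom, start, end, target_gene, association_score`); converting a raw
  GeneHancer-style dump into that dialect is left to an explicit external
  step (a documented stub marks the boundary).
* **Motif number**: the count of primary-motif hits with exact p < 10⁻⁴
  across the gene's GRE sequences. Hits are counted, not p-weighted.

Each feature is min-max scaled across the ranked gene set
(`(x − min)/(max − min)`; an all-constant feature scales to all zeros
rather than dividing by zero), and the Normalized Annotation Score (NAS) is
the sum of the three scaled features. Genes whose window catches no peak
stay in the ranking with all-zero annotation scores, so the rank-product
denominator n always equals the DE gene count.

DEC, the differential-expression change, is |log₂FC| by default; signed
log₂FC and −log₁₀ p_adj variants are selectable in `RankConfig` and the
choice is recorded in the output table's metadata. Ranks use mean
(fractional) ties; the final table is sorted by rank product with a
gene-id tie-break, which makes the pipeline a pure function of its inputs
— permuting input rows cannot change the output.

### Motif scanning and exact p-values

Scanning scores each window with log₂-odds against a 0-order background,
with a pseudocount of 0.1 (as a fraction of the background composition)
added to the PWM probabilities. The p-value of a score is exact under the
background model: per-column scores are discretized to integers at 1/1000
bit, and the null distribution of the integer total under i.i.d.
background letters is built by dynamic programming (one convolution per
column). The scanner sums the *same* integers, so a reported hit's p-value
can never disagree with its score, and a hit is retained when
p < threshold strictly (default 10⁻⁴; 10⁻³ is the "lenient" match level
used by the composite-element statistics). Discretization is the only
approximation in this component; for motifs of length ≤ 8 the table is
checked against exhaustive enumeration of all 4^L words in the test suite.
Letters with zero probability after pseudocounting (only possible with a
zero pseudocount) are clamped at −30 bits, which keeps the DP range finite
while pushing any word containing them far below practical thresholds.

The background defaults to the 0-order composition of the scanned
sequences themselves, symmetrized A/T and C/G to match double-stranded
scanning; a uniform background is selectable. Both strands are scanned by
default and offsets of minus-strand hits are reported in forward-strand
coordinates. Windows containing ambiguous bases are skipped (policy
configurable for single-kmer scoring).

### Regulatory potential and the function-prediction test

A gene's regulatory potential is `RP = Σᵢ exp(−(offset + k·dᵢ/s))` over its
associated peaks, with offset = 0.5, k = 4 and decay scale s = 100 kb, all
three exposed as parameters. This exponential distance decay follows the
established binding-and-expression target analysis form: a peak on the TSS
contributes e^−0.5 ≈ 0.607 and the contribution falls by e^−4 per decay
scale. The activator/repressor ("function prediction") test ranks all genes
by RP from high to low (gene-id tie-break), traces each group's cumulative
fraction along the ranking, and applies a two-sample Kolmogorov–Smirnov
test to the rank positions of the up- (down-)regulated genes against the
non-DE background. The test is one-sided by default — the alternative is
that the DE group concentrates at the top of the ranking, i.e. carries more
binding — because that is the question the cumulative curves pose; a
two-sided option exists. The background is the non-DE genes; an `all`
option substitutes every gene outside the tested group. Running the KS test
on rank positions (rather than raw scores) makes the curves and p-values
invariant under any strictly monotone transformation of RP, and the
deterministic tie-break keeps tied-at-zero genes exchangeable under label
permutation, which is what makes the type-I calibration below meaningful.

### Expression filters and DE-list comparison

Bulk: a gene is expressed when its normalized count exceeds 3 (strictly)
in at least 80% of the samples of *every* treatment group; the 80% is
compared as an exact rational (count·denominator ≥ numerator·n), never as
a rounded float. Single-cell: RPKM strictly above 1 in at least one cell.
DE-list overlap intersects two DE gene sets by stable gene id and splits
the intersection into concordant-up, concordant-down and discordant by
direction; the operation is symmetric and rejects duplicate ids.

## The synthetic universe

The generator emulates the *structure* of the real inputs at desk scale.
Defaults (the conditions every recovery experiment runs under): 1000 genes
on 4 chromosomes of 50 Mb (≈200 kb mean TSS spacing, comparable to human
gene density), 50 planted direct-target genes, Poisson peak counts with
mean 5 per direct target and 0.5 per background gene, peak widths uniform
200–1000 bp, and peak-TSS distances from a mixture with 5% proximal mass
(uniform 0–3 kb) and a distal lognormal body (median 20 kb, σ = 0.8,
truncated to the window) — mirroring the empirically dominant distal mode
of nuclear-receptor binding. Direct-target peaks receive open-chromatin
overlap with probability 0.9 (background 0.2), an enhancer link to their
gene with probability 0.8 (background 0.1, lognormal scores, median 10)
and a planted motif consensus with probability 0.8 (background 0.05).
Effect sizes: |log₂FC| ~ N(3.0, 0.7) for direct targets, N(1.2, 0.4) for
the 30% of background genes made indirectly DE; 60% of effects are
upregulation; adjusted p-values are sampled log-uniformly below 0.05 for
DE genes and uniformly above it otherwise. Sequences are 0-order with 41%
GC; the default planted motif is a 15-bp palindromic nuclear-receptor-like
PWM (two 6-bp half sites at 0.85 per consensus base around a degenerate
3-bp spacer).

Every output stream draws from its own RNG, split from the master seed by
a fixed label (`default_rng([seed, crc32(label)])`), so adding an output
file never perturbs the others and equal seeds give byte-identical files.
`null_generate` permutes the per-gene (log₂FC, p_adj) pairs across genes
with an independent stream, giving datasets with identical marginals but
no association between DE labels and regulatory features — the null for
the KS type-I calibration. The truth object records the planted target
sets, each peak's owner gene, every planted motif instance (offset,
strand), and the planted expression sets, which is sufficient to score any
ranking without re-reading the configuration.

What the generator does **not** emulate: higher-order sequence
composition, peak-width/signal correlation, chromatin-state spatial
autocorrelation, enhancer sharing between genes, mappability artefacts,
and correlated DE noise. Recovery results on this universe therefore
demonstrate the internal correctness and discriminative mechanics of the
pipeline — that the ranking recovers a planted signal of realistic shape —
not field performance on real data.

## Validation experiments and problem sizes

The suite and the reproduction script run, at fixed seeds:

* exactness: DP p-value table vs 4^L enumeration for L ≤ 8; closed forms
  (k·e^−0.5 regulatory potential, rank product extremes, min-max examples,
  one-hot motif p = 0.25^k);
* oracle equivalence of interval operations against brute-force double
  loops;
* recovery: ≥ 45/50 planted direct targets in the rank-product top 50
  under the default conditions (seed 17), and ≥ 80% of a 30-gene truth
  set among 500 genes in NAS-only mode (100 kb, hard open-chromatin
  filter, seed 17);
* calibration: over 500 label-permuted datasets (150 genes each, a
  deliberately compact configuration that keeps the full calibration
  around ten seconds), the KS test's rejection rate at α = 0.05 stays
  within 3 binomial SD of 0.05;
* determinism: byte-identical bundles at equal seeds, identical ranking
  tables under input-row permutation;
* a composite-element scan over 1000 planted 300-bp regions (plant rates
  0.4 stringent / 0.8 lenient / 0.95 auxiliary; the lenient copies carry
  three mismatches in informative columns, placing them between the two
  match thresholds) and a DE-overlap comparison over two lists with a
  planted 581-gene concordant intersection (309 up, 272 down).

## Known limitations

* The rank product is an ordering, not a significance measure; no
  permutation null for it is provided.
* The exact motif p-values assume a 0-order background; repeat-rich or
  CpG-skewed sequence will miscalibrate them somewhat (as with any
  scanner of this class).
* The lenient composite-element planting can occasionally produce a copy
  that still clears the stringent threshold (when all three mismatches hit
  least-informative alternatives), slightly inflating the stringent
  fraction; the effect is below one percentage point at the default plant
  rates.
* In the NAS-only mode, genes are dropped when no peak survives the
  open-chromatin filter; the candidate list length is therefore
  data-dependent and recovery percentages should be read against it.
* The expression filters operate on matrices as given; no normalization,
  batch handling or RPKM computation is performed.
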