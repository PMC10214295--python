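# gretarget

Rank differentially expressed genes by the strength of the evidence that a
transcription factor targets them **directly** — by integrating the
factor's ChIP binding sites, open-chromatin class annotation,
enhancer-target links and binding-motif occurrences around each gene's
transcription start site (TSS).

The package is aimed at regulatory-genomics analysts who have a
differential-expression (DE) table from a perturbation experiment (e.g. a
glucocorticoid treatment) plus publicly available binding and chromatin
resources, and want a reproducible, testable ranking of candidate direct
targets instead of an ad-hoc spreadsheet pipeline.

## The method

1. **Peak-to-gene association.** Every ChIP peak whose center lies within a
   window of a gene's TSS (150 kb by default) becomes a *responsive
   element* (GRE) of that gene. Associations within 3 kb are *proximal*,
   the rest *distal* (3001 bp up to the window edge).
2. **Annotation scores.** For each DE gene (adjusted p < 0.05):
   - *Open Chromatin Score* — sum over its GREs of the chromatin-class
     weight of the accessible regions each GRE overlaps;
   - *Enhancer-Target Score* — sum of enhancer-gene association scores over
     GREs overlapping enhancers annotated to that gene;
   - *motif number* — count of primary-motif matches at exact p < 10⁻⁴
     across the gene's GRE sequences (PWM scanning with an exact
     dynamic-programming null distribution).
3. **Normalized Annotation Score (NAS).** Each feature is min-max scaled
   across genes, `x' = (x − min x) / (max x − min x)`, and the three scaled
   features are summed: NAS ∈ [0, 3].
4. **Rank product.** Genes are ranked by differential-expression change
   (DEC = |log₂FC|, rank 1 = largest) and by NAS (rank 1 = highest), and

   `rank product = (rank_DEC / n) · (rank_NAS / n)`,  n = number of DE genes.

   The lowest rank product marks the most confident direct target.
5. **NAS-only mode.** When no DE table exists for the factor, genes are
   associated at 100 kb, GREs are hard-filtered to open-chromatin overlap,
   and candidates are ordered by NAS alone.

Around the ranking, the package also provides a distance-decayed
*regulatory potential* `RP = Σᵢ exp(−(0.5 + 4 dᵢ/100 kb))` with a
cumulative-curve Kolmogorov–Smirnov test for activator/repressor behaviour,
composite-element statistics (how many binding regions carry the primary
motif at two stringencies, or auxiliary-family motifs instead), DE-list
overlap/concordance, and bulk and single-cell expressed-gene filters.

A seeded synthetic-data generator (`gretarget.synthetic`) produces a
complete miniature input universe — annotation, peaks, classed open
chromatin, enhancer links, peak sequences with planted motif instances, DE
tables and expression matrices — with known ground truth, so every stage of
the pipeline is verifiable without downloading anything.

## Worked example

```python
import gretarget as gt

ds = gt.generate(gt.SyntheticConfig(seed=17))      # 1000 genes, 50 planted targets
table = gt.rank_direct_targets(
    ds.genes, ds.peaks, ds.open_chromatin, ds.class_weights,
    list(ds.enhancers), ds.pwm, ds.sequences)
print(table.head(5)[["gene_id", "log2fc", "n_gres", "motif_count", "nas", "rank_product"]])
```

```
gene_id  log2fc  n_gres  motif_count    nas  rank_product
   g188   4.886      11           22   2.66     1.793e-05
   g392  -4.369       8           14  1.439     0.0005647
   g556   4.975       3            4 0.6209     0.0005916
   g727  -2.879       9           16  2.498     0.0005916
   g127   3.833       6           10  1.645     0.0007171
```

All five top-ranked genes are planted direct targets; 47 of the 50 planted
targets fall in the top 50 of the 334 DE genes. The columns read exactly as
in the method: `g188` has 11 associated peaks, 22 retained motif hits, a
NAS of 2.66 out of 3, and ranks essentially first on both the effect-size
and the annotation axis (rank product 1.8 × 10⁻⁵ with n = 334).

The same dataset shows the expected binding geometry: 96.6% of the
peak-gene associations are distal (> 3 kb from the TSS), and the
regulatory-potential KS test separates both DE groups from the non-DE
background (p = 7.4 × 10⁻⁵ up, 5.6 × 10⁻⁶ down).

The same pipeline is scriptable from a shell:

```sh
gretarget simulate --out bundle/ --seed 17
gretarget rank-de --peaks bundle/peaks.bed --genes bundle/genes.tsv \
    --open-chromatin bundle/open_chromatin.bed --class-weights bundle/class_weights.tsv \
    --enhancers bundle/enhancers.tsv --motifs bundle/motifs.meme \
    --fasta bundle/peak_sequences.fasta --out ranking.tsv
```

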