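"""Seeded generator of a miniature input universe with known ground truth.

The generator emulates the structure of the real inputs the ranking
pipeline consumes — a gene annotation with TSSs, TF ChIP peaks, classed
open-chromatin regions, enhancer-target links, peak sequences with planted
motif instances, a differential-expression table, and bulk/single-cell
expression matrices — while planting a known set of "direct target" genes
whose features are enriched the way a directly bound, directly regulated
gene's would be: more peaks near the TSS (mostly distal, 3-50 kb), more
open-chromatin and enhancer overlap, more motif instances, and larger
expression changes.  Recovery of the planted truth by the ranking modules
is then a measurable quantity.

Reproducibility: every output stream draws from its own RNG, split from the
master seed by a fixed label (``default_rng([seed, crc32(label)])``), so
adding one output never perturbs the others and equal seeds give
byte-identical files.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    ClassWeightTable,
    EnhancerLink,
    GeneRecord,
    GenomicInterval,
    OpenChromatinRegion,
    PWM,
    ValidationError,
    classify_de,
    write_bed,
    write_class_weights,
    write_enhancer_table,
    write_fasta,
    write_gene_table,
    write_meme_motifs,
)
from .motif import reverse_complement

_BASES = np.array(list("ACGT"))


def default_gbs_pwm(pseudocount: float = 0.1) -> PWM:
    """A 15-bp palindromic nuclear-receptor-like motif (two strong half sites
    separated by a 3-bp degenerate spacer), used as the default planted motif."""
    strong = 0.85
    weak = 0.05
    consensus = "AGAACATTTTGTTCT"
    spacer = {6, 7, 8}
    rows = []
    for i, base in enumerate(consensus):
        if i in spacer:
            rows.append([0.25, 0.25, 0.25, 0.25])
        else:
            row = [weak] * 4
            row["ACGT".index(base)] = strong
            rows.append(row)
    return PWM(motif_id="GBS_synth", matrix=np.array(rows), pseudocount=pseudocount)


@dataclass(frozen=True)
class DistanceProfile:
    """Peak-to-TSS distance mixture: a small proximal mass plus a distal
    lognormal body (median ~20 kb) truncated to the association window."""

    proximal_prob: float = 0.05
    proximal_max_bp: int = 3000
    lognorm_mu: float = math.log(20_000)
    lognorm_sigma: float = 0.8
    max_bp: int = 150_000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        prox = rng.random(n) < self.proximal_prob
        d = np.empty(n, dtype=np.int64)
        d[prox] = rng.integers(0, self.proximal_max_bp + 1, size=int(prox.sum()))
        body = rng.lognormal(self.lognorm_mu, self.lognorm_sigma, size=int((~prox).sum()))
        d[~prox] = np.clip(body.astype(np.int64), self.proximal_max_bp + 1, self.max_bp)
        return d


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic universe (defaults = the conditions
    every recovery test and the acceptance script run under)."""

    n_genes: int = 1000
    n_chroms: int = 4
    genome_span_bp: int = 50_000_000        # per chromosome
    n_direct_targets: int = 50
    peak_rate_direct: float = 5.0           # expected peaks per direct-target gene
    peak_rate_background: float = 0.5
    distance_profile: DistanceProfile = field(default_factory=DistanceProfile)
    peak_width_range: tuple[int, int] = (200, 1000)
    oc_overlap_prob_direct: float = 0.9
    oc_overlap_prob_background: float = 0.2
    n_random_oc: int = 300
    class_frequencies: Mapping[str, float] = field(default_factory=lambda: {
        "active_enhancer": 0.45,
        "active_promoter": 0.20,
        "weak_enhancer": 0.20,
        "other_open": 0.15,
    })
    enhancer_link_prob_direct: float = 0.8
    enhancer_link_prob_background: float = 0.1
    enhancer_score_lognorm: tuple[float, float] = (math.log(10.0), 0.6)
    motif_plant_prob_direct: float = 0.8
    motif_plant_prob_background: float = 0.05
    pwm: PWM = field(default_factory=default_gbs_pwm)
    lfc_effect_direct: tuple[float, float] = (3.0, 0.7)    # mean, sd of |log2FC|
    lfc_effect_indirect: tuple[float, float] = (1.2, 0.4)
    frac_indirect_de: float = 0.3
    up_prob: float = 0.6
    gc_content: float = 0.41
    n_samples_per_group: int = 4
    frac_bulk_unexpressed: float = 0.1
    n_cells: int = 100
    sc_expressed_frac: float = 0.68
    seed: int = 17

    def __post_init__(self) -> None:
        probs = (self.oc_overlap_prob_direct, self.oc_overlap_prob_background,
                 self.enhancer_link_prob_direct, self.enhancer_link_prob_background,
                 self.motif_plant_prob_direct, self.motif_plant_prob_background,
                 self.frac_indirect_de, self.up_prob, self.gc_content,
                 self.frac_bulk_unexpressed, self.sc_expressed_frac,
                 self.distance_profile.proximal_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if not 0 < self.n_direct_targets < self.n_genes:
            raise ValidationError("need 0 < n_direct_targets < n_genes")
        margin = self.distance_profile.max_bp + self.peak_width_range[1] + 1000
        if self.genome_span_bp <= 2 * margin:
            raise ValidationError(
                "genome_span_bp too small for the distance profile (peaks would "
                "fall outside the chromosome)")
        if abs(sum(self.class_frequencies.values()) - 1.0) > 1e-9:
            raise ValidationError("class_frequencies must sum to 1")
        if self.peak_rate_direct < 0 or self.peak_rate_background < 0:
            raise ValidationError("peak rates must be non-negative")

    def rng(self, label: str) -> np.random.Generator:
        """The labeled per-stream RNG (see module docstring)."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class SyntheticTruth:
    direct_target_ids: frozenset[str]
    indirect_de_ids: frozenset[str]
    planted_motif_positions: Mapping[str, tuple[tuple[int, str], ...]]
    peak_owner: Mapping[str, str]      # peak name -> gene it was planted for
    sc_expressed_ids: frozenset[str]
    bulk_unexpressed_ids: frozenset[str]
    generator_config: SyntheticConfig

    def __post_init__(self) -> None:
        if self.direct_target_ids & self.indirect_de_ids:
            raise ValidationError("direct and indirect truth sets must be disjoint")


@dataclass(frozen=True)
class SyntheticDataset:
    genes: tuple[GeneRecord, ...]
    peaks: tuple[GenomicInterval, ...]
    open_chromatin: tuple[OpenChromatinRegion, ...]
    class_weights: ClassWeightTable
    enhancers: tuple[EnhancerLink, ...]
    sequences: Mapping[str, str]
    pwm: PWM
    counts: pd.DataFrame
    sample_groups: Mapping[str, str]
    rpkm: pd.DataFrame
    truth: SyntheticTruth


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Produce the full input bundle plus its ground truth."""
    cfg = cfg or SyntheticConfig()
    margin = cfg.distance_profile.max_bp + cfg.peak_width_range[1] + 1000

    # --- gene annotation ---------------------------------------------------
    rng = cfg.rng("genes")
    width = len(str(cfg.n_genes - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    chroms = [f"chr{(i % cfg.n_chroms) + 1}" for i in range(cfg.n_genes)]
    tss = rng.integers(margin, cfg.genome_span_bp - margin, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")

    # --- truth labels ------------------------------------------------------
    rng = cfg.rng("labels")
    direct_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_direct_targets, replace=False))
    is_direct = np.zeros(cfg.n_genes, dtype=bool)
    is_direct[direct_idx] = True
    is_indirect = (~is_direct) & (rng.random(cfg.n_genes) < cfg.frac_indirect_de)

    # --- DE statistics -----------------------------------------------------
    rng = cfg.rng("de")
    log2fc = rng.normal(0.0, 0.3, size=cfg.n_genes)
    padj = rng.uniform(0.05, 1.0, size=cfg.n_genes)
    for mask, (mu, sd), lo_exp, hi_exp in (
        (is_direct, cfg.lfc_effect_direct, 2.0, 8.0),
        (is_indirect, cfg.lfc_effect_indirect, 1.5, 4.0),
    ):
        k = int(mask.sum())
        mag = np.clip(rng.normal(mu, sd, size=k), 0.2, None)
        sign = np.where(rng.random(k) < cfg.up_prob, 1.0, -1.0)
        log2fc[mask] = mag * sign
        padj[mask] = 10.0 ** (-rng.uniform(lo_exp, hi_exp, size=k))

    genes = tuple(
        GeneRecord(
            gene_id=gene_ids[i], chrom=chroms[i], strand=str(strands[i]),
            tss=int(tss[i]), symbol=gene_ids[i].upper(),
            log2fc=float(log2fc[i]), padj=float(padj[i]),
            de_status=classify_de(float(log2fc[i]), float(padj[i])))
        for i in range(cfg.n_genes)
    )

    # --- peaks -------------------------------------------------------------
    rng = cfg.rng("peaks")
    peaks: list[GenomicInterval] = []
    peak_owner: list[int] = []          # index of the gene a peak was planted for
    for i in range(cfg.n_genes):
        rate = cfg.peak_rate_direct if is_direct[i] else cfg.peak_rate_background
        n_peaks = int(rng.poisson(rate))
        if n_peaks == 0:
            continue
        d = cfg.distance_profile.sample(rng, n_peaks)
        sign = np.where(rng.random(n_peaks) < 0.5, 1, -1)
        widths = rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1,
                              size=n_peaks)
        for j in range(n_peaks):
            center = int(tss[i] + sign[j] * d[j])
            w = int(widths[j])
            start = center - w // 2
            peaks.append(GenomicInterval(chroms[i], start, start + w,
                                         name=f"peak_{len(peaks):05d}"))
            peak_owner.append(i)

    # --- open chromatin ----------------------------------------------------
    rng = cfg.rng("chromatin")
    class_names = list(cfg.class_frequencies)
    class_probs = np.array([cfg.class_frequencies[c] for c in class_names])
    oc_regions: list[OpenChromatinRegion] = []
    for peak, owner in zip(peaks, peak_owner):
        p = cfg.oc_overlap_prob_direct if is_direct[owner] else cfg.oc_overlap_prob_background
        if rng.random() < p:
            left = int(rng.integers(100, 501))
            right = int(rng.integers(100, 501))
            cls = class_names[int(rng.choice(len(class_names), p=class_probs))]
            oc_regions.append(OpenChromatinRegion(
                GenomicInterval(peak.chrom, max(0, peak.center - left), peak.center + right),
                chromatin_class=cls))
    for _ in range(cfg.n_random_oc):
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        start = int(rng.integers(0, cfg.genome_span_bp - 2000))
        length = int(rng.integers(200, 1500))
        cls = class_names[int(rng.choice(len(class_names), p=class_probs))]
        oc_regions.append(OpenChromatinRegion(
            GenomicInterval(chrom, start, start + length), chromatin_class=cls))
    class_weights = ClassWeightTable(dict(cfg.class_frequencies))

    # --- enhancer links ----------------------------------------------------
    rng = cfg.rng("enhancers")
    mu, sd = cfg.enhancer_score_lognorm
    enhancers: list[EnhancerLink] = []
    for peak, owner in zip(peaks, peak_owner):
        p = cfg.enhancer_link_prob_direct if is_direct[owner] else cfg.enhancer_link_prob_background
        if rng.random() < p:
            pad_l = int(rng.integers(0, 301))
            pad_r = int(rng.integers(0, 301))
            enhancers.append(EnhancerLink(
                GenomicInterval(peak.chrom, max(0, peak.start - pad_l), peak.end + pad_r),
                target_gene=gene_ids[owner],
                association_score=float(rng.lognormal(mu, sd))))

    # --- peak sequences with planted motif instances -----------------------
    rng = cfg.rng("sequences")
    consensus = cfg.pwm.consensus
    L = len(consensus)
    sequences: dict[str, str] = {}
    planted: dict[str, tuple[tuple[int, str], ...]] = {}
    for peak, owner in zip(peaks, peak_owner):
        seq = _random_sequence(rng, len(peak), cfg.gc_content)
        p = cfg.motif_plant_prob_direct if is_direct[owner] else cfg.motif_plant_prob_background
        if len(seq) >= L and rng.random() < p:
            offset = int(rng.integers(0, len(seq) - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:offset] + inst + seq[offset + L:]
            planted[peak.name] = ((offset, strand),)
        sequences[peak.name] = seq

    # --- bulk count matrix --------------------------------------------------
    rng = cfg.rng("expression")
    samples = [f"treated_{k + 1}" for k in range(cfg.n_samples_per_group)] + \
              [f"ctrl_{k + 1}" for k in range(cfg.n_samples_per_group)]
    groups = {s: ("treated" if s.startswith("treated") else "ctrl") for s in samples}
    unexpressed = (~is_direct) & (rng.random(cfg.n_genes) < cfg.frac_bulk_unexpressed)
    base = rng.lognormal(math.log(100.0), 1.0, size=cfg.n_genes)
    base[unexpressed] = rng.uniform(0.0, 2.0, size=int(unexpressed.sum()))
    noise = rng.lognormal(0.0, 0.25, size=(cfg.n_genes, len(samples)))
    counts = base[:, None] * noise
    de_mask = is_direct | is_indirect
    counts[de_mask, :cfg.n_samples_per_group] *= 2.0 ** log2fc[de_mask, None]
    counts_df = pd.DataFrame(np.round(counts, 3), index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"

    # --- single-cell RPKM matrix -------------------------------------------
    rng = cfg.rng("sc")
    n_sc = int(round(cfg.sc_expressed_frac * cfg.n_genes))
    sc_idx = np.sort(rng.choice(cfg.n_genes, size=n_sc, replace=False))
    sc_expressed = np.zeros(cfg.n_genes, dtype=bool)
    sc_expressed[sc_idx] = True
    rpkm = np.zeros((cfg.n_genes, cfg.n_cells))
    detected = rng.random((cfg.n_genes, cfg.n_cells)) < 0.4
    vals = rng.lognormal(math.log(5.0), 1.0, size=(cfg.n_genes, cfg.n_cells))
    rpkm[sc_expressed] = np.where(detected[sc_expressed], vals[sc_expressed], 0.0)
    # guarantee the planted-expressed genes clear the strict RPKM > 1 filter
    rpkm[sc_expressed, 0] = np.maximum(rpkm[sc_expressed, 0], 1.5)
    low = rng.uniform(0.0, 0.9, size=(cfg.n_genes, cfg.n_cells))
    dropout = rng.random((cfg.n_genes, cfg.n_cells)) < 0.9
    rpkm[~sc_expressed] = np.where(dropout[~sc_expressed], 0.0, low[~sc_expressed])
    rpkm_df = pd.DataFrame(np.round(rpkm, 3), index=gene_ids,
                           columns=[f"cell_{k + 1}" for k in range(cfg.n_cells)])
    rpkm_df.index.name = "gene_id"

    truth = SyntheticTruth(
        direct_target_ids=frozenset(gene_ids[i] for i in np.nonzero(is_direct)[0]),
        indirect_de_ids=frozenset(gene_ids[i] for i in np.nonzero(is_indirect)[0]),
        planted_motif_positions=planted,
        peak_owner={p.name: gene_ids[o] for p, o in zip(peaks, peak_owner)},
        sc_expressed_ids=frozenset(gene_ids[i] for i in sc_idx),
        bulk_unexpressed_ids=frozenset(gene_ids[i] for i in np.nonzero(unexpressed)[0]),
        generator_config=cfg,
    )
    return SyntheticDataset(
        genes=genes, peaks=tuple(peaks), open_chromatin=tuple(oc_regions),
        class_weights=class_weights, enhancers=tuple(enhancers),
        sequences=sequences, pwm=cfg.pwm, counts=counts_df,
        sample_groups=groups, rpkm=rpkm_df, truth=truth)


def null_generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Same marginals as :func:`generate`, but the DE table is decoupled from
    the regulatory features: the per-gene (log2FC, padj) pairs are permuted
    across genes by an independent stream.  Peaks, chromatin, enhancers,
    sequences and matrices are byte-identical to the plain dataset at the
    same seed."""
    cfg = cfg or SyntheticConfig()
    ds = generate(cfg)
    rng = cfg.rng("null")
    perm = rng.permutation(len(ds.genes))
    stats = [(g.log2fc, g.padj) for g in ds.genes]
    genes = tuple(
        replace(g, log2fc=stats[perm[i]][0], padj=stats[perm[i]][1],
                de_status=classify_de(stats[perm[i]][0], stats[perm[i]][1]))
        for i, g in enumerate(ds.genes)
    )
    return replace(ds, genes=genes)


def zbtb16_mode_config(seed: int = 17) -> SyntheticConfig:
    """Conditions for the NAS-only recovery experiment: 500 genes, 30 planted
    targets, distances drawn within the 100 kb window of that mode."""
    return SyntheticConfig(
        n_genes=500,
        n_direct_targets=30,
        distance_profile=DistanceProfile(max_bp=100_000),
        seed=seed,
    )


def write_bundle(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle stream as the plain-text formats the readers accept."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "peaks": out / "peaks.bed",
        "open_chromatin": out / "open_chromatin.bed",
        "class_weights": out / "class_weights.tsv",
        "enhancers": out / "enhancers.tsv",
        "sequences": out / "peak_sequences.fasta",
        "motifs": out / "motifs.meme",
        "counts": out / "counts.tsv",
        "sample_groups": out / "sample_groups.tsv",
        "rpkm": out / "rpkm.tsv",
        "truth": out / "truth.tsv",
        "planted_motifs": out / "planted_motifs.tsv",
        "peak_owner": out / "peak_owner.tsv",
    }
    write_gene_table(list(ds.genes), paths["genes"])
    write_bed(ds.peaks, paths["peaks"])
    write_bed(ds.open_chromatin, paths["open_chromatin"])
    write_class_weights(ds.class_weights, paths["class_weights"])
    write_enhancer_table(list(ds.enhancers), paths["enhancers"])
    write_fasta(ds.sequences, paths["sequences"])
    write_meme_motifs([ds.pwm], paths["motifs"])
    ds.counts.to_csv(paths["counts"], sep="\t")
    pd.DataFrame({"sample": list(ds.sample_groups),
                  "group": list(ds.sample_groups.values())}
                 ).to_csv(paths["sample_groups"], sep="\t", index=False)
    ds.rpkm.to_csv(paths["rpkm"], sep="\t")

    roles = {}
    for g in ds.truth.direct_target_ids:
        roles[g] = "direct"
    for g in ds.truth.indirect_de_ids:
        roles[g] = "indirect"
    truth_df = pd.DataFrame({
        "gene_id": [g.gene_id for g in ds.genes],
        "role": [roles.get(g.gene_id, "none") for g in ds.genes],
        "sc_expressed": [int(g.gene_id in ds.truth.sc_expressed_ids) for g in ds.genes],
        "bulk_unexpressed": [int(g.gene_id in ds.truth.bulk_unexpressed_ids) for g in ds.genes],
    })
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    rows = [(name, off, strand)
            for name, inst in sorted(ds.truth.planted_motif_positions.items())
            for off, strand in inst]
    pd.DataFrame(rows, columns=["peak_name", "offset", "strand"]).to_csv(
        paths["planted_motifs"], sep="\t", index=False)
    pd.DataFrame(sorted(ds.truth.peak_owner.items()),
                 columns=["peak_name", "gene_id"]).to_csv(
        paths["peak_owner"], sep="\t", index=False)
    return paths
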