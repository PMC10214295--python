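"""Per-gene annotation scores, min-max scaling, NAS and the rank product.

The direct-target ranking combines, for every differentially expressed
gene, three annotation features of its associated binding regions (GREs):

* **Open Chromatin Score** — sum over the gene's GREs of the chromatin-class
  weight of the accessible regions each GRE overlaps (per GRE the maximum
  overlapped class weight, so stacked annotations are not double counted);
* **Enhancer-Target Score** — sum of enhancer-gene association scores over
  GREs overlapping enhancers annotated to that gene;
* **motif number** — count of primary-motif matches at p < 1e-4 across the
  gene's GREs.

Each feature is min-max scaled to [0, 1] across genes; their sum is the
Normalized Annotation Score (NAS, in [0, 3]).  Genes are ranked separately
by differential-expression change (DEC, |log2FC| by default) and by NAS
(rank 1 = highest in both), and the rank product

    rank_product = (rank_DEC / n) * (rank_NAS / n)

orders the genes: the lowest rank product marks the most confident direct
target.  The NAS-only mode ranks genes by NAS alone at a 100 kb window
after a hard open-chromatin filter — the variant used when no
differential-expression table exists for the factor's perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import motif as motif_mod
from .intervals import (
    GRE,
    WindowConfig,
    assign_peaks_to_genes,
    build_interval_index,
    filter_by_open_chromatin,
    gres_by_gene,
    overlapping_records,
    TF_MODE_WINDOW_BP,
)
from .io_formats import (
    ClassWeightTable,
    EnhancerLink,
    GeneRecord,
    GenomicInterval,
    OpenChromatinRegion,
    PWM,
    ValidationError,
)


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


def open_chromatin_score(
    gres_of_gene: Sequence[GRE],
    oc_index: Mapping,
    weights: ClassWeightTable,
    rule: str = "max",
) -> float:
    """Chromatin-class-weighted accessibility score of one gene.

    ``oc_index`` is a per-chromosome interval index over
    :class:`OpenChromatinRegion` (see :func:`build_interval_index`).  Each
    GRE contributes the max (or, with rule="sum", the sum) of the weights of
    the open-chromatin regions it overlaps; non-overlapping GREs contribute 0.
    """
    if rule not in ("max", "sum"):
        raise ValidationError(f"unknown rule {rule!r}")
    total = 0.0
    for gre in gres_of_gene:
        ws = []
        for region in overlapping_records(oc_index, gre.peak):
            cls = region.chromatin_class
            if cls not in weights:
                raise ConfigurationError(f"chromatin class {cls!r} missing from weight table")
            ws.append(weights[cls])
        if ws:
            total += max(ws) if rule == "max" else sum(ws)
    return total


def enhancer_target_score(
    gres_of_gene: Sequence[GRE],
    enh_index: Mapping,
    gene_id: str,
) -> float:
    """Sum of association scores over (GRE, enhancer) overlaps targeting the gene."""
    total = 0.0
    for gre in gres_of_gene:
        for link in overlapping_records(enh_index, gre.peak):
            if link.target_gene == gene_id:
                total += link.association_score
    return total


def motif_number(
    gres_of_gene: Sequence[GRE],
    hits_by_sequence: Mapping[str, Sequence[motif_mod.MotifHit]],
) -> int:
    """Retained primary-motif hit count across a gene's GREs (keyed by peak name)."""
    count = 0
    for gre in gres_of_gene:
        if gre.peak.name is None:
            raise ValidationError("motif counting requires named peaks")
        count += len(hits_by_sequence.get(gre.peak.name, ()))
    return count


def feature_scale(values: Sequence[float]) -> np.ndarray:
    """Min-max scaling to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("feature_scale needs at least one value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def normalized_annotation_score(norm_oc: float, norm_enh: float, norm_motif: float) -> float:
    """Sum of the three scaled features, in [0, 3]."""
    for name, x in (("norm_oc", norm_oc), ("norm_enh", norm_enh), ("norm_motif", norm_motif)):
        if not 0.0 <= x <= 1.0:
            raise ValidationError(f"{name} = {x} outside [0, 1]")
    return norm_oc + norm_enh + norm_motif


def rank_product(dec: Sequence[float], nas: Sequence[float]) -> pd.DataFrame:
    """Normalized rank product of two descending rankings.

    Rank 1 = largest value in each vector; ties get mean (fractional) ranks.
    Returns a frame with rank_dec, rank_nas and rank_product in (0, 1].
    """
    dec = np.asarray(dec, dtype=float)
    nas = np.asarray(nas, dtype=float)
    if dec.shape != nas.shape:
        raise ValidationError(f"length mismatch: {dec.shape} vs {nas.shape}")
    if dec.size == 0:
        raise ValidationError("rank_product needs at least one gene")
    n = dec.size
    rank_dec = rankdata(-dec, method="average")
    rank_nas = rankdata(-nas, method="average")
    return pd.DataFrame({
        "rank_dec": rank_dec,
        "rank_nas": rank_nas,
        "rank_product": (rank_dec / n) * (rank_nas / n),
    })


@dataclass(frozen=True)
class RankConfig:
    """Knobs of the direct-target ranking."""

    window: WindowConfig = field(default_factory=WindowConfig)
    dec: str = "abs_log2fc"          # or "signed_log2fc", "neglog10_padj"
    oc_rule: str = "max"             # per-GRE open-chromatin contribution
    motif_p_threshold: float = motif_mod.DEFAULT_P_THRESHOLD
    motif_background: str = "estimate"   # or "uniform"

    def __post_init__(self) -> None:
        if self.dec not in ("abs_log2fc", "signed_log2fc", "neglog10_padj"):
            raise ValidationError(f"unknown DEC definition {self.dec!r}")
        if self.motif_background not in ("estimate", "uniform"):
            raise ValidationError(f"unknown background mode {self.motif_background!r}")


def _dec_value(gene: GeneRecord, mode: str) -> float:
    if gene.log2fc is None or gene.padj is None:
        raise ValidationError(f"gene {gene.gene_id} lacks DE statistics")
    if mode == "abs_log2fc":
        return abs(gene.log2fc)
    if mode == "signed_log2fc":
        return gene.log2fc
    return float(-np.log10(max(gene.padj, 1e-300)))


def _scan_peak_sequences(
    pwm: PWM,
    sequences: Mapping[str, str],
    gres: Sequence[GRE],
    cfg: RankConfig,
) -> dict[str, list[motif_mod.MotifHit]]:
    needed = sorted({g.peak.name for g in gres if g.peak.name is not None})
    missing = [name for name in needed if name not in sequences]
    if missing:
        raise ConfigurationError(f"no sequence for peak(s) {missing[:3]}{'...' if len(missing) > 3 else ''}")
    subset = {name: sequences[name] for name in needed}
    bg = np.full(4, 0.25) if cfg.motif_background == "uniform" else None
    return motif_mod.scan_regions(pwm, subset, p_threshold=cfg.motif_p_threshold,
                                  background=bg)


def rank_direct_targets(
    de_genes: Sequence[GeneRecord],
    peaks: Sequence[GenomicInterval],
    oc_regions: Sequence[OpenChromatinRegion],
    class_weights: ClassWeightTable,
    enhancer_links: Sequence[EnhancerLink],
    pwm: PWM,
    sequences: Mapping[str, str],
    cfg: RankConfig | None = None,
) -> pd.DataFrame:
    """End-to-end direct-target ranking of differentially expressed genes.

    Only genes with de_status in {up, down} enter the ranking; genes whose
    window catches no peak stay in with all-zero annotation scores (worst
    NAS rank), so n in the rank-product denominator is the DE gene count.
    Output is sorted by ascending rank_product (ties by gene_id) and keeps
    every intermediate column for audit.
    """
    cfg = cfg or RankConfig()
    de = sorted((g for g in de_genes if g.is_de), key=lambda g: g.gene_id)
    if not de:
        raise ValidationError("no differentially expressed genes to rank")
    gres = assign_peaks_to_genes(peaks, de, cfg.window)
    per_gene = gres_by_gene(gres)
    oc_index = build_interval_index(oc_regions)
    enh_index = build_interval_index(list(enhancer_links))
    hits = _scan_peak_sequences(pwm, sequences, gres, cfg)

    rows = []
    for g in de:
        glist = per_gene.get(g.gene_id, [])
        rows.append({
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "log2fc": g.log2fc,
            "padj": g.padj,
            "de_status": g.de_status,
            "n_gres": len(glist),
            "open_chromatin_score": open_chromatin_score(glist, oc_index, class_weights, cfg.oc_rule),
            "enhancer_target_score": enhancer_target_score(glist, enh_index, g.gene_id),
            "motif_count": motif_number(glist, hits),
            "dec": _dec_value(g, cfg.dec),
        })
    table = pd.DataFrame(rows)
    table["norm_oc"] = feature_scale(table["open_chromatin_score"])
    table["norm_enh"] = feature_scale(table["enhancer_target_score"])
    table["norm_motif"] = feature_scale(table["motif_count"])
    table["nas"] = table["norm_oc"] + table["norm_enh"] + table["norm_motif"]
    rp = rank_product(table["dec"].to_numpy(), table["nas"].to_numpy())
    table = pd.concat([table, rp], axis=1)
    table = table.sort_values(["rank_product", "gene_id"], kind="mergesort").reset_index(drop=True)
    table.attrs["dec_definition"] = cfg.dec
    table.attrs["oc_rule"] = cfg.oc_rule
    table.attrs["window_bp"] = cfg.window.window_bp
    return table


def rank_tf_targets_nas_only(
    genes: Sequence[GeneRecord],
    peaks: Sequence[GenomicInterval],
    oc_sets: Sequence[Sequence[OpenChromatinRegion]],
    class_weights: ClassWeightTable,
    enhancer_links: Sequence[EnhancerLink] = (),
    pwm: PWM | None = None,
    sequences: Mapping[str, str] | None = None,
    cfg: RankConfig | None = None,
) -> pd.DataFrame:
    """NAS-only target list: 100 kb window, hard open-chromatin filter.

    No differential-expression table is required.  GREs not overlapping open
    chromatin (in every supplied set) are discarded and genes with no
    surviving GRE drop out of the candidate list.  Remaining genes are
    scored on the available annotation features and sorted by NAS from high
    to low (ties by gene_id).  Enhancer links and motif inputs are optional;
    absent features contribute zero to the NAS.
    """
    cfg = cfg or RankConfig(window=WindowConfig(window_bp=TF_MODE_WINDOW_BP))
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    if not gene_list:
        raise ValidationError("no genes supplied")
    gres = assign_peaks_to_genes(peaks, gene_list, cfg.window)
    gres = filter_by_open_chromatin(gres, oc_sets, mode="intersection")
    per_gene = gres_by_gene(gres)
    if not per_gene:
        raise ValidationError("no gene retains an open-chromatin-overlapping peak")
    all_oc = [r for s in oc_sets for r in s]
    oc_index = build_interval_index(all_oc)
    enh_index = build_interval_index(list(enhancer_links))
    hits: Mapping[str, Sequence[motif_mod.MotifHit]] = {}
    if pwm is not None and sequences is not None:
        hits = _scan_peak_sequences(pwm, sequences, gres, cfg)

    rows = []
    for g in gene_list:
        glist = per_gene.get(g.gene_id)
        if not glist:
            continue
        rows.append({
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "n_gres": len(glist),
            "open_chromatin_score": open_chromatin_score(glist, oc_index, class_weights, cfg.oc_rule),
            "enhancer_target_score": enhancer_target_score(glist, enh_index, g.gene_id),
            "motif_count": motif_number(glist, hits) if hits else 0,
        })
    table = pd.DataFrame(rows)
    table["norm_oc"] = feature_scale(table["open_chromatin_score"])
    table["norm_enh"] = feature_scale(table["enhancer_target_score"])
    table["norm_motif"] = feature_scale(table["motif_count"])
    table["nas"] = table["norm_oc"] + table["norm_enh"] + table["norm_motif"]
    table["rank_nas"] = rankdata(-table["nas"].to_numpy(), method="average")
    table = table.sort_values(["rank_nas", "gene_id"], kind="mergesort").reset_index(drop=True)
    table.attrs["window_bp"] = cfg.window.window_bp
    return table
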