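"""Interval algebra and peak-to-gene association.

A ChIP peak becomes a gene's responsive element (GRE) when its anchor point
falls within a symmetric window around the gene's TSS (150 kb by default;
100 kb in the NAS-only TF-target mode).  Associations closer than the
proximal cutoff (3 kb, inclusive) are "proximal", the rest "distal" —
i.e. distal covers 3001 bp up to the window edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import (
    GeneRecord,
    GenomicInterval,
    OpenChromatinRegion,
    ValidationError,
)

PROXIMAL_CUTOFF_BP = 3000
DEFAULT_WINDOW_BP = 150_000
TF_MODE_WINDOW_BP = 100_000


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry for peak-to-gene association.

    anchor: "peak_center" measures floor((start+end)/2) − TSS;
    "nearest_edge" measures the signed distance from the TSS to the closest
    peak boundary (0 when the TSS lies inside the peak).
    """

    window_bp: int = DEFAULT_WINDOW_BP
    proximal_cutoff_bp: int = PROXIMAL_CUTOFF_BP
    anchor: str = "peak_center"

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.proximal_cutoff_bp <= 0:
            raise ValidationError("window and proximal cutoff must be positive")
        if self.proximal_cutoff_bp >= self.window_bp:
            raise ValidationError("proximal_cutoff_bp must be < window_bp")
        if self.anchor not in ("peak_center", "nearest_edge"):
            raise ValidationError(f"unknown anchor {self.anchor!r}")


@dataclass(frozen=True)
class GRE:
    """A (peak, gene) association within the TSS window."""

    peak: GenomicInterval
    gene_id: str
    signed_distance: int
    abs_distance: int
    locality: str

    def __post_init__(self) -> None:
        if self.abs_distance != abs(self.signed_distance):
            raise ValidationError("abs_distance must equal |signed_distance|")
        if self.locality not in ("proximal", "distal"):
            raise ValidationError(f"invalid locality {self.locality!r}")


def classify_locality(abs_distance: int, cutoff: int = PROXIMAL_CUTOFF_BP) -> str:
    """Proximal iff the distance is within the cutoff (inclusive at the cutoff)."""
    if abs_distance < 0:
        raise ValidationError("abs_distance must be >= 0")
    return "proximal" if abs_distance <= cutoff else "distal"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap: [a.start, a.end) and [b.start, b.end) share >= 1 base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _signed_distance(peak: GenomicInterval, tss: int, anchor: str) -> int:
    if anchor == "peak_center":
        return peak.center - tss
    # nearest_edge: 0 if the TSS lies inside the peak, else signed gap to the
    # closest boundary (sign by genome coordinate, peak minus TSS)
    if peak.start <= tss < peak.end:
        return 0
    if tss < peak.start:
        return peak.start - tss
    return (peak.end - 1) - tss


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    cfg: WindowConfig | None = None,
) -> list[GRE]:
    """Associate every peak with every gene whose TSS window contains its anchor.

    A peak may associate with several genes and a gene with several peaks.
    The window is inclusive at exactly ``window_bp``.  Output order is
    deterministic: sorted by gene_id, then by peak position.
    """
    cfg = cfg or WindowConfig()
    if not genes:
        warnings.warn("assign_peaks_to_genes called with an empty gene list")
        return []
    peaks_sorted = sorted(
        peaks, key=lambda p: (p.chrom, p.center, p.start, p.end, p.name or "")
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks_sorted:
        by_chrom.setdefault(p.chrom, []).append(p)

    anchors: dict[str, np.ndarray] = {}
    margins: dict[str, int] = {}
    for chrom, plist in by_chrom.items():
        anchors[chrom] = np.array([p.center for p in plist], dtype=np.int64)
        # candidate pruning is by center; the nearest-edge anchor can sit up to
        # half the widest peak away from the center, so widen and filter exactly
        margins[chrom] = max(len(p) for p in plist) // 2 + 1

    out: list[GRE] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        plist = by_chrom.get(gene.chrom)
        if not plist:
            continue
        centers = anchors[gene.chrom]
        margin = margins[gene.chrom]
        lo = np.searchsorted(centers, gene.tss - cfg.window_bp - margin, side="left")
        hi = np.searchsorted(centers, gene.tss + cfg.window_bp + margin, side="right")
        for peak in plist[lo:hi]:
            d = _signed_distance(peak, gene.tss, cfg.anchor)
            if abs(d) <= cfg.window_bp:
                out.append(GRE(
                    peak=peak, gene_id=gene.gene_id, signed_distance=d,
                    abs_distance=abs(d),
                    locality=classify_locality(abs(d), cfg.proximal_cutoff_bp)))
    return out


def distal_fraction(gres: Sequence[GRE]) -> float:
    """Fraction of associations classified distal."""
    if not gres:
        raise ValidationError("distal_fraction is undefined for an empty GRE list")
    return sum(g.locality == "distal" for g in gres) / len(gres)


def build_interval_index(
    regions: Iterable[GenomicInterval | OpenChromatinRegion],
) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over regions (data = the original record)."""
    trees: dict[str, IntervalTree] = {}
    for rec in regions:
        iv = getattr(rec, "interval", rec)  # OpenChromatinRegion / EnhancerLink wrap one
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)
    return trees


def overlapping_records(index: dict[str, IntervalTree], iv: GenomicInterval) -> list:
    tree = index.get(iv.chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def filter_by_open_chromatin(
    gres: Sequence[GRE],
    oc_sets: Sequence[Sequence[OpenChromatinRegion]],
    mode: str = "intersection",
) -> list[GRE]:
    """Keep GREs whose peak lies in open chromatin.

    mode="any": the peak overlaps >= 1 region of >= 1 set.
    mode="intersection": the peak overlaps >= 1 region in EVERY set (the
    "common between cell types" criterion).
    """
    if mode not in ("any", "intersection"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not oc_sets:
        raise ValidationError("at least one open-chromatin set is required")
    indexes = [build_interval_index(s) for s in oc_sets]
    kept = []
    for gre in gres:
        flags = [bool(overlapping_records(idx, gre.peak)) for idx in indexes]
        if (any(flags) if mode == "any" else all(flags)):
            kept.append(gre)
    return kept


def gres_by_gene(gres: Sequence[GRE]) -> dict[str, list[GRE]]:
    out: dict[str, list[GRE]] = {}
    for gre in gres:
        out.setdefault(gre.gene_id, []).append(gre)
    return out


def write_gre_table(gres: Sequence[GRE], path) -> None:
    """Serialize associations as TSV (peak coords, gene, distance, locality)."""
    import pandas as pd

    pd.DataFrame({
        "chrom": [g.peak.chrom for g in gres],
        "start": [g.peak.start for g in gres],
        "end": [g.peak.end for g in gres],
        "peak_name": [g.peak.name or "" for g in gres],
        "gene_id": [g.gene_id for g in gres],
        "signed_distance": [g.signed_distance for g in gres],
        "abs_distance": [g.abs_distance for g in gres],
        "locality": [g.locality for g in gres],
    }).to_csv(path, sep="\t", index=False)
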