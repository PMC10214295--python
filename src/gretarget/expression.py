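"""Expression-based filters and DE-list comparison.

Covers the steps flanking the ranking pipeline: which genes count as
expressed in bulk RNA-seq (normalized counts > 3 in at least 80% of the
samples of every treatment group) and in single cells (RPKM > 1 in at
least one cell), and the overlap/concordance of two differential-expression
gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GeneRecord, ValidationError


@dataclass(frozen=True)
class DEOverlapResult:
    shared_genes: frozenset[str]
    n_shared: int
    n_concordant_up: int
    n_concordant_down: int
    n_discordant: int

    def __post_init__(self) -> None:
        if self.n_shared != self.n_concordant_up + self.n_concordant_down + self.n_discordant:
            raise ValidationError("overlap counts do not add up")


def _direction_map(records: Sequence[GeneRecord], label: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for g in records:
        if g.de_status not in ("up", "down"):
            continue
        if g.gene_id in out:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in set {label}")
        out[g.gene_id] = g.de_status
    return out


def de_overlap(set_a: Sequence[GeneRecord], set_b: Sequence[GeneRecord]) -> DEOverlapResult:
    """Intersection of two DE gene lists with direction concordance.

    Only records with de_status up/down participate.  Symmetric in its
    arguments.
    """
    a = _direction_map(set_a, "A")
    b = _direction_map(set_b, "B")
    shared = sorted(set(a) & set(b))
    up = sum(1 for g in shared if a[g] == "up" and b[g] == "up")
    down = sum(1 for g in shared if a[g] == "down" and b[g] == "down")
    return DEOverlapResult(
        shared_genes=frozenset(shared),
        n_shared=len(shared),
        n_concordant_up=up,
        n_concordant_down=down,
        n_discordant=len(shared) - up - down,
    )


def expressed_gene_filter(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    min_count: float = 3.0,
    min_frac: float = 0.8,
) -> set[str]:
    """Genes expressed in every treatment group of a bulk count matrix.

    ``counts`` is genes × samples (index = gene ids).  A gene passes in a
    group when its normalized count exceeds ``min_count`` (strict >) in at
    least ``min_frac`` of the group's samples; the fraction comparison is
    exact-rational (>=), never subject to float rounding of min_frac · n.
    The gene must pass in EVERY group.
    """
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ValidationError(f"sample(s) without group assignment: {missing[:3]}")
    frac = Fraction(min_frac).limit_denominator(10**6)
    by_group: dict[str, list[str]] = {}
    for sample in counts.columns:
        by_group.setdefault(groups[sample], []).append(sample)
    if not by_group:
        raise ValidationError("no samples")
    for grp, samples in by_group.items():
        if not samples:
            raise ValidationError(f"group {grp!r} is empty")
    passing = pd.Series(True, index=counts.index)
    for samples in by_group.values():
        n = len(samples)
        n_pass = (counts[samples] > min_count).sum(axis=1)
        # n_pass / n >= frac, compared in integers
        passing &= n_pass * frac.denominator >= frac.numerator * n
    return set(counts.index[passing])


def sc_expressed_filter(
    rpkm: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_cells: int = 1,
) -> set[str]:
    """Genes expressed in a single-cell RPKM matrix (genes × cells).

    A gene counts as expressed with RPKM strictly above ``min_rpkm`` in at
    least ``min_cells`` cells.
    """
    n_cells = (rpkm > min_rpkm).sum(axis=1)
    return set(rpkm.index[n_cells >= min_cells])


def write_gene_set(genes: set[str], path) -> None:
    pd.Series(sorted(genes), name="gene_id").to_csv(path, sep="\t", index=False)


def write_overlap_summary(result: DEOverlapResult, path) -> None:
    pd.DataFrame([{
        "n_shared": result.n_shared,
        "n_concordant_up": result.n_concordant_up,
        "n_concordant_down": result.n_concordant_down,
        "n_discordant": result.n_discordant,
    }]).to_csv(path, sep="\t", index=False)
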