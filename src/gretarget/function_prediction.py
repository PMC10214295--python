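"""Regulatory potential and the cumulative-curve activator/repressor test.

Each gene's regulatory potential is a distance-decayed sum over its
associated binding regions,

    RP = sum_i exp(-(offset + k * d_i / decay_scale)),

so a region on the TSS contributes exp(-offset) (~0.61 with the default
offset 0.5) and the contribution decays exponentially with distance
(defaults k = 4, decay_scale = 100 kb: a region a full decay-scale away
contributes exp(-4.5)).  Ranking genes by this score from high to low and
cumulating each DE group along the ranking gives the activator/repressor
curves; a one-sided two-sample Kolmogorov-Smirnov test on the rank
positions of the up- (down-) regulated genes against the non-DE background
asks whether the factor's binding concentrates near that group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GRE, gres_by_gene
from .io_formats import GeneRecord, ValidationError

DEFAULT_DECAY_SCALE_BP = 100_000
DEFAULT_OFFSET = 0.5
DEFAULT_SLOPE = 4.0


@dataclass(frozen=True)
class RegulatoryPotential:
    gene_id: str
    score: float
    n_gres: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError("regulatory potential cannot be negative")
        if (self.score == 0) != (self.n_gres == 0):
            raise ValidationError("score is zero iff the gene has no associated regions")


def regulatory_potential(
    gres_of_gene: Sequence[GRE],
    decay_scale: float = DEFAULT_DECAY_SCALE_BP,
    offset: float = DEFAULT_OFFSET,
    slope: float = DEFAULT_SLOPE,
) -> RegulatoryPotential:
    """Distance-decayed score for one gene's associated regions (0 when none)."""
    if not gres_of_gene:
        return RegulatoryPotential(gene_id="", score=0.0, n_gres=0)
    gene_ids = {g.gene_id for g in gres_of_gene}
    if len(gene_ids) > 1:
        raise ValidationError(f"GREs of several genes mixed: {sorted(gene_ids)}")
    d = np.array([g.abs_distance for g in gres_of_gene], dtype=float)
    score = float(np.exp(-(offset + slope * d / decay_scale)).sum())
    return RegulatoryPotential(gene_id=gene_ids.pop(), score=score, n_gres=len(gres_of_gene))


def regulatory_potential_table(
    gres: Sequence[GRE],
    genes: Sequence[GeneRecord],
    decay_scale: float = DEFAULT_DECAY_SCALE_BP,
    offset: float = DEFAULT_OFFSET,
    slope: float = DEFAULT_SLOPE,
) -> pd.DataFrame:
    """Per-gene scores over a full gene set; genes without regions score 0."""
    per_gene = gres_by_gene(gres)
    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        glist = per_gene.get(g.gene_id, [])
        rp = regulatory_potential(glist, decay_scale, offset, slope)
        rows.append((g.gene_id, rp.score, rp.n_gres, g.de_status))
    return pd.DataFrame(rows, columns=["gene_id", "score", "n_gres", "de_status"])


@dataclass(frozen=True)
class FunctionPredictionResult:
    curves: pd.DataFrame       # rank, cum_up, cum_down, cum_background
    ks_stat_up: float
    ks_p_up: float
    ks_stat_down: float
    ks_p_down: float
    n_up: int
    n_down: int
    n_background: int


def function_prediction(
    scores: Mapping[str, float],
    de_status: Mapping[str, str],
    alternative: str = "greater",
    background: str = "not_de",
) -> FunctionPredictionResult:
    """Cumulative target-enrichment curves and KS tests against background.

    Genes are ranked by score from high to low (ties broken by gene_id for
    determinism) and each group's cumulative fraction is traced along the
    ranking.  ``alternative="greater"`` tests the one-sided hypothesis that
    the DE group carries systematically higher regulatory potential (smaller
    ranks) than background; "two-sided" is also accepted.
    ``background="all"`` uses every gene outside the tested group instead of
    the non-DE genes only.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if background not in ("not_de", "all"):
        raise ValidationError(f"unknown background {background!r}")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    rank_of = {g: i + 1 for i, g in enumerate(order)}
    groups = {"up": [], "down": [], "not_de": []}
    for g in order:
        status = de_status.get(g, "untested")
        if status in groups:
            groups[status].append(rank_of[g])
    for name in ("up", "down", "not_de"):
        if len(groups[name]) < 2:
            raise ValidationError(f"group {name!r} needs >= 2 genes, has {len(groups[name])}")

    n = len(order)
    ranks = np.arange(1, n + 1)
    curves = pd.DataFrame({"rank": ranks})
    for name, col in (("up", "cum_up"), ("down", "cum_down"), ("not_de", "cum_background")):
        member = np.zeros(n)
        member[np.array(groups[name]) - 1] = 1.0
        curves[col] = np.cumsum(member) / member.sum()

    def bg_ranks(excluded: str) -> np.ndarray:
        if background == "not_de":
            return np.array(groups["not_de"], dtype=float)
        keep = [rank_of[g] for g in order
                if de_status.get(g, "untested") != excluded]
        return np.array(keep, dtype=float)

    def ks(group: str) -> tuple[float, float]:
        # data1 = DE-group ranks; "greater" = their empirical CDF dominates,
        # i.e. the group sits at the top of the ranking
        res = stats.ks_2samp(np.array(groups[group], dtype=float), bg_ranks(group),
                             alternative=alternative if alternative != "two-sided" else "two-sided")
        return float(res.statistic), float(res.pvalue)

    stat_up, p_up = ks("up")
    stat_down, p_down = ks("down")
    return FunctionPredictionResult(
        curves=curves, ks_stat_up=stat_up, ks_p_up=p_up,
        ks_stat_down=stat_down, ks_p_down=p_down,
        n_up=len(groups["up"]), n_down=len(groups["down"]),
        n_background=len(groups["not_de"]))


def write_function_prediction(result: FunctionPredictionResult, curves_path, ks_path) -> None:
    result.curves.to_csv(curves_path, sep="\t", index=False)
    pd.DataFrame([{
        "ks_stat_up": result.ks_stat_up, "ks_p_up": result.ks_p_up,
        "ks_stat_down": result.ks_stat_down, "ks_p_down": result.ks_p_down,
        "n_up": result.n_up, "n_down": result.n_down,
        "n_background": result.n_background,
    }]).to_csv(ks_path, sep="\t", index=False)


def plot_function_prediction(result: FunctionPredictionResult, path) -> None:
    """Cumulative-curve figure (requires matplotlib, an optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    c = result.curves
    ax.plot(c["rank"], c["cum_up"], color="crimson",
            label=f"up (KS p={result.ks_p_up:.2g})")
    ax.plot(c["rank"], c["cum_down"], color="purple",
            label=f"down (KS p={result.ks_p_down:.2g})")
    ax.plot(c["rank"], c["cum_background"], "k--", label="background (non-DE)")
    ax.set_xlabel("genes ranked by regulatory potential (high → low)")
    ax.set_ylabel("cumulative fraction of group")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
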