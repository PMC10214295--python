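"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by the most literal method
available (double loops, exhaustive enumeration) and is kept free of the
package code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_assignments(peaks, genes, window_bp):
    """All (gene_id, peak) pairs with |peak center - TSS| <= window, by full scan."""
    out = set()
    for g in genes:
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            center = (p.start + p.end) // 2
            if abs(center - g.tss) <= window_bp:
                out.add((g.gene_id, p.chrom, p.start, p.end, p.name))
    return out


def brute_force_overlap(iv_a, iv_b) -> bool:
    """Shared-base test by literal enumeration of covered positions."""
    if iv_a.chrom != iv_b.chrom:
        return False
    return bool(set(range(iv_a.start, iv_a.end)) & set(range(iv_b.start, iv_b.end)))


def brute_force_oc_filter(gres, oc_sets, mode):
    kept = []
    for gre in gres:
        flags = []
        for regions in oc_sets:
            flags.append(any(
                r.interval.chrom == gre.peak.chrom
                and gre.peak.start < r.interval.end
                and r.interval.start < gre.peak.end
                for r in regions))
        ok = any(flags) if mode == "any" else all(flags)
        if ok:
            kept.append(gre)
    return kept


def naive_log_odds(matrix, background, pseudocount, kmer) -> float:
    """Per-position log2 odds summation from first principles."""
    total = 0.0
    for i, base in enumerate(kmer):
        b = "ACGT".index(base)
        col = [matrix[i][j] + pseudocount * background[j] for j in range(4)]
        p = col[b] / sum(col)
        total += math.log2(p / background[b])
    return total


def enumerate_pvalues(int_scores, background):
    """score -> Pr[score >= s] by exhausting all 4^L words."""
    L = len(int_scores)
    pmf: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=L):
        s = int(sum(int_scores[i][b] for i, b in enumerate(word)))
        p = float(np.prod([background[b] for b in word]))
        pmf[s] = pmf.get(s, 0.0) + p
    sf = {}
    acc = 0.0
    for s in sorted(pmf, reverse=True):
        acc += pmf[s]
        sf[s] = acc
    return sf


def brute_force_enhancer_score(gres, links, gene_id) -> float:
    total = 0.0
    for gre in gres:
        for link in links:
            if link.target_gene != gene_id:
                continue
            iv = link.interval
            if (iv.chrom == gre.peak.chrom and gre.peak.start < iv.end
                    and iv.start < gre.peak.end):
                total += link.association_score
    return total


def brute_force_regulatory_potential(distances, decay_scale, offset, slope) -> float:
    return sum(math.exp(-(offset + slope * d / decay_scale)) for d in distances)
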