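"""PWM scanning with exact p-values and composite-element statistics.

Scores are log2 odds against a 0-order background.  P-values are exact under
that background: the null score distribution is computed by dynamic
programming over integer-discretized per-column scores (default granularity
1/1000 bit), the same integers the scanner sums, so scan scores and the
p-value table can never disagree.  Discretization is the only approximation;
for motifs of length <= 8 the table is testable against exhaustive
enumeration of all 4^L words.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import DNA_ALPHABET, PWM, ValidationError

DEFAULT_GRANULARITY_BITS = 1e-3  # score discretization step, in bits
DEFAULT_P_THRESHOLD = 1e-4       # stringent motif-retention threshold
LENIENT_P_THRESHOLD = 1e-3       # "less canonical" match threshold
_MAX_TABLE_CELLS = 200_000_000
_MIN_LOG_ODDS_BITS = -30.0  # floor for zero-probability letters (pseudocount 0)

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA_ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3 (A,C,G,T); anything else becomes -1."""
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float      # log2-odds
    p_value: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class CompositeStats:
    """Per-region motif-content fractions over a set of binding regions."""

    n_regions: int
    frac_stringent_primary: float
    frac_lenient_primary: float
    frac_any_auxiliary: float
    frac_auxiliary_given_no_primary: float


def log_odds_matrix(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    """Per-position log2(P/background) with pseudocounted probabilities, shape (L, 4)."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    probs = pwm.probabilities()
    with np.errstate(divide="ignore"):
        lom = np.log2(probs / bg[None, :])
    return np.maximum(lom, _MIN_LOG_ODDS_BITS)


def log_odds_score(
    pwm: PWM,
    kmer: str,
    background: np.ndarray | None = None,
    ambiguous: str = "skip",
) -> float | None:
    """Score one word of length L; returns None for ambiguous bases under "skip".

    ambiguous="background" scores an N as a perfectly background-like letter
    (contribution 0).
    """
    if len(kmer) != pwm.length:
        raise ValidationError(f"kmer length {len(kmer)} != motif length {pwm.length}")
    lom = log_odds_matrix(pwm, background)
    idx = encode_sequence(kmer)
    if np.any(idx < 0):
        if ambiguous == "skip":
            return None
        if ambiguous != "background":
            raise ValidationError(f"unknown ambiguous-base policy {ambiguous!r}")
    total = 0.0
    for i, b in enumerate(idx):
        if b >= 0:
            total += lom[i, b]
    return float(total)


class ScoreDistribution:
    """Exact null distribution of the integer-discretized PWM score.

    Holds the survival function p(s) = Pr[score >= s] over the full
    attainable integer score range under i.i.d. background letters.
    """

    def __init__(self, int_scores: np.ndarray, background: np.ndarray, scale: float):
        self.int_scores = int_scores          # (L, 4) integer column scores
        self.scale = scale                    # integer units per bit
        L = int_scores.shape[0]
        col_min = int_scores.min(axis=1)
        col_max = int_scores.max(axis=1)
        self.min_score = int(col_min.sum())
        self.max_score = int(col_max.sum())
        span = self.max_score - self.min_score + 1
        if span * 1.0 > _MAX_TABLE_CELLS:
            raise ResourceWarning(
                "discretized score range too wide; use a coarser granularity")
        pmf = np.zeros(span)
        pmf[0] = 1.0
        width = 1  # occupied prefix of the pmf array, in offset units
        offset_base = 0
        for i in range(L):
            new_width = width + int(col_max[i] - col_min[i])
            new = np.zeros(new_width)
            for b in range(4):
                shift = int(int_scores[i, b] - col_min[i])
                new[shift:shift + width] += background[b] * pmf[:width]
            pmf = new
            width = new_width
            offset_base += int(col_min[i])
        assert offset_base == self.min_score
        self.pmf = pmf
        total = pmf.sum()
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"null pmf mass {total} != 1")
        # survival: Pr[score >= min_score + i]
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        """Pr[score >= int_score] under the background model."""
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            return 0.0
        return float(self.sf[int_score - self.min_score])

    def score_cutoff(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is strictly below the threshold.

        Returns max_score + 1 when no attainable score is that significant.
        """
        idx = np.searchsorted(-self.sf, -p_threshold, side="right")
        return self.min_score + int(idx)


def _integer_scores(pwm: PWM, background: np.ndarray, granularity_bits: float) -> tuple[np.ndarray, float]:
    scale = 1.0 / granularity_bits
    lom = log_odds_matrix(pwm, background)
    return np.rint(lom * scale).astype(np.int64), scale


def exact_pvalue_table(
    pwm: PWM,
    background: np.ndarray | None = None,
    granularity_bits: float = DEFAULT_GRANULARITY_BITS,
) -> ScoreDistribution:
    """Exact score → p mapping under i.i.d. background letters."""
    if granularity_bits <= 0:
        raise ValidationError("granularity must be positive")
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    int_scores, scale = _integer_scores(pwm, bg, granularity_bits)
    return ScoreDistribution(int_scores, bg, scale)


def estimate_background(seqs: Iterable[str]) -> np.ndarray:
    """0-order background frequencies over a set of sequences (both implicit strands).

    Counts are symmetrized A/T and C/G, matching a scanner that looks at both
    strands; ambiguous bases are ignored.  Falls back to uniform for empty input.
    """
    counts = np.zeros(4)
    for seq in seqs:
        idx = encode_sequence(seq)
        counts += np.bincount(idx[idx >= 0], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    sym = np.array([at, cg, cg, at])
    return sym / sym.sum()


def _window_int_scores(idx: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window plus a validity mask (no ambiguous base)."""
    L = int_scores.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(idx < 0, 0, idx)
    for i in range(L):
        scores += int_scores[i, safe[i:i + n]]
        valid &= idx[i:i + n] >= 0
    return scores, valid


def scan_sequence(
    pwm: PWM,
    seq: str,
    sequence_id: str = "seq",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    background: np.ndarray | None = None,
    table: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """All motif matches with p < p_threshold, sorted by offset (then strand).

    Offsets are 0-based positions of the window on the forward strand, for
    minus-strand hits too.  Windows containing ambiguous bases are skipped.
    Sequences shorter than the motif yield no hits.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValidationError("p_threshold must lie in (0, 1)")
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    if table is None:
        table = exact_pvalue_table(pwm, bg)
    cutoff = table.score_cutoff(p_threshold)
    L = pwm.length
    hits: list[MotifHit] = []

    def collect(idx: np.ndarray, strand: str, seq_len: int) -> None:
        scores, valid = _window_int_scores(idx, table.int_scores)
        for j in np.nonzero(valid & (scores >= cutoff))[0]:
            offset = int(j) if strand == "+" else seq_len - L - int(j)
            hits.append(MotifHit(
                sequence_id=sequence_id, offset=offset, strand=strand,
                score=float(scores[j] / table.scale),
                p_value=table.pvalue(int(scores[j]))))

    fwd = encode_sequence(seq)
    collect(fwd, "+", len(seq))
    if both_strands:
        collect(encode_sequence(reverse_complement(seq)), "-", len(seq))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    pwm: PWM,
    seqs: Mapping[str, str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    background: np.ndarray | None = None,
) -> dict[str, list[MotifHit]]:
    """Scan many regions with one shared p-value table.

    By default the 0-order background is estimated from the scanned
    sequences themselves; pass ``background`` to override (e.g. uniform).
    """
    bg = estimate_background(seqs.values()) if background is None else np.asarray(background, dtype=float)
    table = exact_pvalue_table(pwm, bg)
    return {
        name: scan_sequence(pwm, s, sequence_id=name, p_threshold=p_threshold,
                            both_strands=both_strands, background=bg, table=table)
        for name, s in seqs.items()
    }


def _region_flags(region_ids: Sequence[str], hits: Mapping[str, Sequence] | Iterable[str]) -> set[str]:
    if isinstance(hits, Mapping):
        return {r for r in region_ids if hits.get(r)}
    return set(hits)


def composite_element_stats(
    region_ids: Sequence[str],
    primary_stringent: Mapping[str, Sequence] | Iterable[str],
    primary_lenient: Mapping[str, Sequence] | Iterable[str],
    auxiliary: Mapping[str, Sequence] | Iterable[str],
) -> CompositeStats:
    """Fractions of regions carrying the primary motif (two stringencies) and
    any auxiliary-family motif, plus the auxiliary fraction among regions
    lacking even a lenient primary match.

    Hit inputs may be mappings region → hit list, or plain sets of region ids.
    """
    if not region_ids:
        raise ValidationError("composite stats are undefined over zero regions")
    if len(set(region_ids)) != len(region_ids):
        raise ValidationError("region ids must be unique")
    n = len(region_ids)
    s = _region_flags(region_ids, primary_stringent)
    l = _region_flags(region_ids, primary_lenient) | s  # a stringent hit is a lenient hit
    a = _region_flags(region_ids, auxiliary)
    no_primary = [r for r in region_ids if r not in l]
    frac_aux_no_primary = (
        sum(r in a for r in no_primary) / len(no_primary) if no_primary else 0.0
    )
    return CompositeStats(
        n_regions=n,
        frac_stringent_primary=len(s & set(region_ids)) / n,
        frac_lenient_primary=len(l & set(region_ids)) / n,
        frac_any_auxiliary=len(a & set(region_ids)) / n,
        frac_auxiliary_given_no_primary=frac_aux_no_primary,
    )


def merge_hit_sets(*hit_maps: Mapping[str, Sequence[MotifHit]]) -> dict[str, list[MotifHit]]:
    """Union of several per-region hit maps (e.g. the auxiliary-family motifs)."""
    out: dict[str, list[MotifHit]] = {}
    for m in hit_maps:
        for region, hits in m.items():
            out.setdefault(region, []).extend(hits)
    return out


def write_hits_table(hits: Mapping[str, Sequence[MotifHit]], path) -> None:
    import pandas as pd

    rows = [
        (h.sequence_id, h.offset, h.strand, h.score, h.p_value)
        for hs in hits.values() for h in hs
    ]
    pd.DataFrame(rows, columns=["sequence_id", "offset", "strand", "score", "p"]).to_csv(
        path, sep="\t", index=False)
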