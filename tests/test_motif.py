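import math

import numpy as np
import pytest

from gretarget import motif as M
from gretarget.io_formats import PWM
from gretarget.synthetic import default_gbs_pwm

from oracles import enumerate_pvalues, naive_log_odds


def random_pwm(rng, length, motif_id="rand", concentration=0.7):
    return PWM(motif_id, rng.dirichlet(np.ones(4) * concentration, size=length))


# --- log-odds scoring --------------------------------------------------------

def test_log_odds_one_hot_single_column():
    pwm = PWM("a", np.array([[1.0, 0.0, 0.0, 0.0]]), pseudocount=0.1)
    p = pwm.probabilities()[0, 0]
    assert M.log_odds_score(pwm, "A") == pytest.approx(math.log2(p / 0.25))


def test_log_odds_uniform_column_is_zero():
    pwm = PWM("u", np.full((1, 4), 0.25))
    assert M.log_odds_score(pwm, "C") == pytest.approx(0.0)


def test_log_odds_matches_naive_oracle(rng):
    for _ in range(20):
        L = int(rng.integers(1, 10))
        pwm = random_pwm(rng, L)
        kmer = "".join(rng.choice(list("ACGT"), size=L))
        expected = naive_log_odds(pwm.matrix, pwm.background, pwm.pseudocount, kmer)
        assert M.log_odds_score(pwm, kmer) == pytest.approx(expected, abs=1e-10)


def test_log_odds_ambiguous_base_policies():
    pwm = PWM("a", np.full((2, 4), 0.25))
    assert M.log_odds_score(pwm, "AN") is None
    assert M.log_odds_score(pwm, "AN", ambiguous="background") == pytest.approx(0.0)


# --- exact p-value table -----------------------------------------------------

@pytest.mark.parametrize("length", [1, 3, 6])
def test_dp_equals_enumeration(rng, length):
    pwm = random_pwm(rng, length)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    table = M.exact_pvalue_table(pwm, background=bg)
    oracle = enumerate_pvalues(table.int_scores.tolist(), bg)
    for s, p in oracle.items():
        assert table.pvalue(s) == pytest.approx(p, abs=1e-12)


def test_one_hot_pvalue_closed_form():
    for k in (2, 5, 8):
        mat = np.zeros((k, 4))
        mat[:, 2] = 1.0
        pwm = PWM("hot", mat)
        table = M.exact_pvalue_table(pwm)
        assert table.pvalue(table.max_score) == pytest.approx(0.25 ** k, rel=1e-12)


def test_pvalue_edge_behavior(rng):
    table = M.exact_pvalue_table(random_pwm(rng, 5))
    assert table.pvalue(table.min_score) == 1.0
    assert table.pvalue(table.min_score - 100) == 1.0
    # survival function is non-increasing in score
    ps = [table.pvalue(s) for s in range(table.min_score, table.max_score + 1, 50)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_granularity_must_be_positive(rng):
    with pytest.raises(M.ValidationError):
        M.exact_pvalue_table(random_pwm(rng, 3), granularity_bits=0)


# --- scanning ----------------------------------------------------------------

def test_scan_finds_planted_consensus(rng):
    pwm = random_pwm(rng, 8, concentration=0.05)  # sharp columns
    cons = pwm.consensus
    seq = "".join(rng.choice(list("ACGT"), size=10)) + cons + \
          "".join(rng.choice(list("ACGT"), size=30))
    hits = M.scan_sequence(pwm, seq, p_threshold=1e-3, both_strands=False)
    assert any(h.offset == 10 and h.strand == "+" for h in hits)


def test_scan_reverse_complement_strand_symmetry(rng):
    pwm = random_pwm(rng, 9, concentration=0.05)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    fwd = M.scan_sequence(pwm, seq, p_threshold=1e-2)
    rc = M.scan_sequence(pwm, M.reverse_complement(seq), p_threshold=1e-2)
    # mirrored hit sets: same offsets after reflection, strands swapped
    mirror = {(len(seq) - pwm.length - h.offset, "+-"["+-".index(h.strand) ^ 1], round(h.score, 6))
              for h in rc}
    assert {(h.offset, h.strand, round(h.score, 6)) for h in fwd} == mirror


def test_planted_reverse_complement_found_with_same_p(rng):
    pwm = random_pwm(rng, 8, concentration=0.05)
    cons = pwm.consensus
    seq = "".join(rng.choice(list("ACGT"), size=15)) + M.reverse_complement(cons) + \
          "".join(rng.choice(list("ACGT"), size=15))
    hits = M.scan_sequence(pwm, seq, p_threshold=1e-3)
    minus = [h for h in hits if h.strand == "-" and h.offset == 15]
    plus_ref = M.scan_sequence(pwm, cons, p_threshold=1e-3, both_strands=False)
    assert minus and plus_ref
    assert minus[0].p_value == pytest.approx(plus_ref[0].p_value)


def test_raising_threshold_never_removes_hits(rng):
    pwm = random_pwm(rng, 7)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    strict = M.scan_sequence(pwm, seq, p_threshold=1e-4)
    loose = M.scan_sequence(pwm, seq, p_threshold=1e-2)
    key = lambda h: (h.offset, h.strand)
    assert {key(h) for h in strict} <= {key(h) for h in loose}


def test_scan_short_sequence_empty(rng):
    pwm = random_pwm(rng, 10)
    assert M.scan_sequence(pwm, "ACGT") == []


def test_scan_skips_ambiguous_windows(rng):
    pwm = random_pwm(rng, 4, concentration=0.05)
    seq = pwm.consensus[:2] + "N" + pwm.consensus[3:]
    assert all("N" not in seq[h.offset:h.offset + 4]
               for h in M.scan_sequence(pwm, seq, p_threshold=0.99))


def test_false_positive_rate_matches_null_expectation(rng):
    """Hit counts on background sequence follow the exact-null rate."""
    pwm = default_gbs_pwm()
    bg = np.full(4, 0.25)
    table = M.exact_pvalue_table(pwm, background=bg)
    cutoff = table.score_cutoff(1e-4)
    alpha = table.pvalue(cutoff)       # achieved per-window level (<= 1e-4)
    n_seqs, length = 200, 500
    n_windows = length - pwm.length + 1
    total = 0
    for _ in range(n_seqs):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        total += len(M.scan_sequence(pwm, seq, p_threshold=1e-4, background=bg, table=table))
    expected = 2 * n_seqs * n_windows * alpha
    assert abs(total - expected) <= 3 * math.sqrt(expected)


# --- composite-element statistics -------------------------------------------

def test_composite_stats_small_example():
    regions = ["r1", "r2", "r3", "r4"]
    stats = M.composite_element_stats(
        regions,
        primary_stringent=set(),
        primary_lenient={"r1", "r3"},
        auxiliary={"r1", "r2"},
    )
    assert stats.frac_lenient_primary == 0.5
    assert stats.frac_any_auxiliary == 0.5
    # r2 and r4 lack the primary; only r2 has an auxiliary motif
    assert stats.frac_auxiliary_given_no_primary == 0.5


def test_composite_stats_all_stringent():
    regions = ["a", "b"]
    stats = M.composite_element_stats(regions, set(regions), set(regions), set())
    assert stats.frac_stringent_primary == 1.0
    assert stats.frac_lenient_primary == 1.0


def test_composite_stats_stringent_subset_of_lenient():
    # stringent hits count as lenient even if the lenient map omits them
    stats = M.composite_element_stats(["a", "b"], {"a"}, set(), set())
    assert stats.frac_stringent_primary <= stats.frac_lenient_primary


def test_composite_stats_errors():
    with pytest.raises(M.ValidationError):
        M.composite_element_stats([], set(), set(), set())
    with pytest.raises(M.ValidationError):
        M.composite_element_stats(["a", "a"], set(), set(), set())


def test_composite_stats_simulation_recovery(rng):
    """Planted per-region motif-content probabilities are recovered at n=1000."""
    n = 1000
    p_str, p_len, p_aux = 0.4, 0.8, 0.95
    regions = [f"r{i}" for i in range(n)]
    lenient = {r for r in regions if rng.random() < p_len}
    stringent = {r for r in lenient if rng.random() < p_str / p_len}
    aux = {r for r in regions if rng.random() < p_aux}
    stats = M.composite_element_stats(regions, stringent, lenient, aux)
    for got, p in ((stats.frac_stringent_primary, p_str),
                   (stats.frac_lenient_primary, p_len),
                   (stats.frac_any_auxiliary, p_aux)):
        assert abs(got - p) <= 3 * math.sqrt(p * (1 - p) / n)
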