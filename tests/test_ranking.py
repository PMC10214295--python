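import numpy as np
import pandas as pd
import pytest

from gretarget import intervals as iv
from gretarget import ranking as rk
from gretarget.io_formats import (
    ClassWeightTable,
    EnhancerLink,
    GeneRecord,
    GenomicInterval,
    OpenChromatinRegion,
    PWM,
)
from gretarget.motif import MotifHit
from gretarget.synthetic import default_gbs_pwm

from oracles import brute_force_enhancer_score


def _gre(peak_start, peak_end, gene_id="g1", chrom="chr1", name=None):
    peak = GenomicInterval(chrom, peak_start, peak_end, name=name)
    d = peak.center - 0
    return iv.GRE(peak, gene_id, d, abs(d), iv.classify_locality(abs(d)))


def _oc_index(regions):
    return iv.build_interval_index(regions)


# --- open chromatin score ----------------------------------------------------

def test_oc_score_single_overlap():
    gre = _gre(100, 300)
    regions = [OpenChromatinRegion(GenomicInterval("chr1", 150, 400), "enh")]
    weights = ClassWeightTable({"enh": 0.8})
    assert rk.open_chromatin_score([gre], _oc_index(regions), weights) == pytest.approx(0.8)


def test_oc_score_additive_over_gres():
    gres = [_gre(100, 300), _gre(1000, 1200)]
    regions = [OpenChromatinRegion(GenomicInterval("chr1", 0, 2000), "enh")]
    weights = ClassWeightTable({"enh": 0.8})
    assert rk.open_chromatin_score(gres, _oc_index(regions), weights) == pytest.approx(1.6)


def test_oc_score_max_rule_over_stacked_regions():
    gre = _gre(100, 300)
    regions = [OpenChromatinRegion(GenomicInterval("chr1", 50, 350), "weak"),
               OpenChromatinRegion(GenomicInterval("chr1", 150, 250), "strong")]
    weights = ClassWeightTable({"weak": 0.3, "strong": 0.9})
    idx = _oc_index(regions)
    assert rk.open_chromatin_score([gre], idx, weights, rule="max") == pytest.approx(0.9)
    assert rk.open_chromatin_score([gre], idx, weights, rule="sum") == pytest.approx(1.2)


def test_oc_score_no_overlap_contributes_zero():
    gre = _gre(100, 300)
    regions = [OpenChromatinRegion(GenomicInterval("chr1", 5000, 6000), "enh")]
    assert rk.open_chromatin_score([gre], _oc_index(regions), ClassWeightTable({"enh": 1.0})) == 0.0


def test_oc_score_unknown_class_rejected():
    gre = _gre(100, 300)
    regions = [OpenChromatinRegion(GenomicInterval("chr1", 150, 250), "mystery")]
    with pytest.raises(rk.ConfigurationError, match="mystery"):
        rk.open_chromatin_score([gre], _oc_index(regions), ClassWeightTable({"enh": 1.0}))


# --- enhancer target score ---------------------------------------------------

def test_enhancer_score_targeting_gene():
    gre = _gre(100, 300, gene_id="g1")
    links = [EnhancerLink(GenomicInterval("chr1", 200, 500), "g1", 12.5)]
    assert rk.enhancer_target_score([gre], iv.build_interval_index(links), "g1") == pytest.approx(12.5)


def test_enhancer_score_other_gene_ignored():
    gre = _gre(100, 300, gene_id="g1")
    links = [EnhancerLink(GenomicInterval("chr1", 200, 500), "g2", 12.5)]
    assert rk.enhancer_target_score([gre], iv.build_interval_index(links), "g1") == 0.0


def test_enhancer_score_matches_brute_force(rng):
    gres = [_gre(int(s), int(s) + 400, name=f"p{k}")
            for k, s in enumerate(rng.integers(0, 100_000, size=30))]
    links = [EnhancerLink(GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 3000))),
                          rng.choice(["g1", "g2", "g3"]), float(rng.uniform(0, 20)))
             for s in rng.integers(0, 100_000, size=40)]
    got = rk.enhancer_target_score(gres, iv.build_interval_index(links), "g1")
    assert got == pytest.approx(brute_force_enhancer_score(gres, links, "g1"))


# --- motif number ------------------------------------------------------------

def test_motif_number_counts_hits():
    gres = [_gre(0, 200, name="pA"), _gre(1000, 1200, name="pB")]
    hit = lambda sid, off: MotifHit(sid, off, "+", 5.0, 1e-5)
    hits = {"pA": [hit("pA", 3)], "pB": [hit("pB", 1), hit("pB", 9), hit("pB", 20)]}
    assert rk.motif_number(gres, hits) == 4
    assert rk.motif_number(gres, {}) == 0


# --- feature scaling / NAS / rank product ------------------------------------

def test_feature_scale_examples():
    assert np.allclose(rk.feature_scale([2, 4, 6]), [0, 0.5, 1])
    assert np.allclose(rk.feature_scale([5, 5, 5]), [0, 0, 0])


def test_feature_scale_matches_formula(rng):
    v = rng.uniform(-10, 10, size=40)
    expected = (v - v.min()) / (v.max() - v.min())
    assert np.allclose(rk.feature_scale(v), expected)


def test_nas_examples():
    assert rk.normalized_annotation_score(0.5, 1.0, 0.25) == pytest.approx(1.75)
    assert rk.normalized_annotation_score(0, 0, 0) == 0.0
    with pytest.raises(rk.ValidationError):
        rk.normalized_annotation_score(1.2, 0, 0)


def test_rank_product_extremes():
    dec = np.arange(10, 0, -1)        # gene 0 is rank 1 on DEC
    nas = np.arange(10, 0, -1)        # and rank 1 on NAS
    rp = rk.rank_product(dec, nas)
    assert rp["rank_product"].iloc[0] == pytest.approx(0.01)
    assert rp["rank_product"].iloc[-1] == pytest.approx(1.0)


def test_rank_product_tie_handling():
    # two genes tied at the top share fractional rank 1.5
    rp = rk.rank_product([5, 5, 1], [3, 2, 1])
    assert rp["rank_dec"].tolist() == [1.5, 1.5, 3.0]
    assert rp["rank_product"].iloc[0] == pytest.approx((1.5 / 3) * (1 / 3))


def test_rank_product_bounds(rng):
    n = 25
    rp = rk.rank_product(rng.normal(size=n), rng.normal(size=n))
    assert (rp["rank_product"] >= 1 / n**2 - 1e-12).all()
    assert (rp["rank_product"] <= 1.0 + 1e-12).all()


def test_rank_product_length_mismatch():
    with pytest.raises(rk.ValidationError):
        rk.rank_product([1, 2], [1, 2, 3])


# --- end-to-end ranking ------------------------------------------------------

def _tiny_universe():
    """Three DE genes; g1 dominates every feature and the effect size."""
    genes = [
        GeneRecord("g1", "chr1", "+", 100_000, log2fc=4.0, padj=1e-6, de_status="up"),
        GeneRecord("g2", "chr1", "+", 500_000, log2fc=1.0, padj=1e-3, de_status="up"),
        GeneRecord("g3", "chr1", "+", 900_000, log2fc=-0.5, padj=1e-2, de_status="down"),
    ]
    pwm = default_gbs_pwm()
    cons = pwm.consensus
    peaks, seqs = [], {}
    # g1: two peaks, motif planted, open chromatin + enhancer
    for k, d in enumerate((5_000, 20_000)):
        name = f"p1_{k}"
        peaks.append(GenomicInterval("chr1", 100_000 + d - 200, 100_000 + d + 200, name=name))
        seqs[name] = "ACGT" * 20 + cons + "ACGT" * 20
    # g2: one peak, no motif
    peaks.append(GenomicInterval("chr1", 520_000, 520_400, name="p2"))
    seqs["p2"] = "ACGT" * 100
    oc = [OpenChromatinRegion(GenomicInterval("chr1", 104_500, 105_500), "enh")]
    weights = ClassWeightTable({"enh": 0.9})
    links = [EnhancerLink(GenomicInterval("chr1", 119_500, 120_500), "g1", 15.0)]
    return genes, peaks, oc, weights, links, pwm, seqs


def test_dominant_gene_ranks_first():
    genes, peaks, oc, weights, links, pwm, seqs = _tiny_universe()
    table = rk.rank_direct_targets(genes, peaks, oc, weights, links, pwm, seqs)
    assert table["gene_id"].iloc[0] == "g1"
    assert table["rank_product"].iloc[0] == pytest.approx((1 / 3) * (1 / 3))
    # audit columns all present
    for col in ("open_chromatin_score", "enhancer_target_score", "motif_count",
                "norm_oc", "norm_enh", "norm_motif", "nas", "dec",
                "rank_dec", "rank_nas", "rank_product"):
        assert col in table.columns


def test_gene_without_peaks_stays_in_ranking():
    genes, peaks, oc, weights, links, pwm, seqs = _tiny_universe()
    table = rk.rank_direct_targets(genes, peaks, oc, weights, links, pwm, seqs)
    row = table[table["gene_id"] == "g3"].iloc[0]
    assert row["n_gres"] == 0
    assert row["nas"] == 0.0
    assert len(table) == 3  # n matches the DE gene count


def test_ranking_invariant_under_input_permutation(small_dataset):
    ds = small_dataset
    args = (ds.genes, ds.peaks, ds.open_chromatin, ds.class_weights,
            list(ds.enhancers), ds.pwm, ds.sequences)
    t1 = rk.rank_direct_targets(*args)
    shuffled = (tuple(reversed(ds.genes)), tuple(reversed(ds.peaks)),
                tuple(reversed(ds.open_chromatin)), ds.class_weights,
                list(reversed(ds.enhancers)), ds.pwm,
                dict(reversed(list(ds.sequences.items()))))
    t2 = rk.rank_direct_targets(*shuffled)
    pd.testing.assert_frame_equal(t1, t2)


def test_no_de_genes_is_an_error():
    genes = [GeneRecord("g1", "chr1", "+", 100, de_status="untested")]
    with pytest.raises(rk.ValidationError):
        rk.rank_direct_targets(genes, [], [], ClassWeightTable({"a": 1.0}), [],
                               default_gbs_pwm(), {})


# --- NAS-only (TF) mode ------------------------------------------------------

def _tf_universe():
    genes = [GeneRecord("g1", "chr1", "+", 100_000),
             GeneRecord("g2", "chr1", "+", 400_000)]
    peaks = [GenomicInterval("chr1", 104_800, 105_200, name="p1"),
             GenomicInterval("chr1", 404_800, 405_200, name="p2")]
    oc = [OpenChromatinRegion(GenomicInterval("chr1", 104_900, 105_100), "enh")]
    weights = ClassWeightTable({"enh": 1.0})
    return genes, peaks, oc, weights


def test_tf_mode_hard_filter_excludes_closed_genes():
    genes, peaks, oc, weights = _tf_universe()
    table = rk.rank_tf_targets_nas_only(genes, peaks, [oc], weights)
    # g2's only peak is not in open chromatin -> not a candidate at all
    assert table["gene_id"].tolist() == ["g1"]


def test_tf_mode_window_widening_monotonicity(small_dataset):
    ds = small_dataset
    def candidates(window):
        cfg = rk.RankConfig(window=iv.WindowConfig(window_bp=window))
        t = rk.rank_tf_targets_nas_only(ds.genes, ds.peaks, [ds.open_chromatin],
                                        ds.class_weights, cfg=cfg)
        return set(t["gene_id"])
    assert candidates(100_000) <= candidates(150_000)
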