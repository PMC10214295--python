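"""Canned end-to-end experiments on the synthetic universe.

These compose the public modules into the recovery, calibration and
comparison experiments the package's validation is built on; the test suite
and the reproduction script both call them, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from . import expression, intervals, motif, ranking, synthetic
from .function_prediction import function_prediction, regulatory_potential_table
from .io_formats import GeneRecord


def direct_target_recovery(seed: int = 17, top_k: int | None = None) -> dict:
    """Rank-product recovery of the planted direct targets under the default
    conditions (1000 genes, 50 planted targets)."""
    ds = synthetic.generate(synthetic.SyntheticConfig(seed=seed))
    table = ranking.rank_direct_targets(
        ds.genes, ds.peaks, ds.open_chromatin, ds.class_weights,
        list(ds.enhancers), ds.pwm, ds.sequences)
    truth = ds.truth.direct_target_ids
    k = top_k or len(truth)
    recovered = len(set(table.head(k)["gene_id"]) & truth)
    return {"recovered": recovered, "n_planted": len(truth), "k": k,
            "n_de": len(table), "table": table, "dataset": ds}


def nas_only_recovery(seed: int = 17) -> dict:
    """NAS-only (100 kb window, hard open-chromatin filter) recovery of a
    30-gene planted truth set among 500 genes."""
    cfg = synthetic.zbtb16_mode_config(seed=seed)
    ds = synthetic.generate(cfg)
    table = ranking.rank_tf_targets_nas_only(
        ds.genes, ds.peaks, [ds.open_chromatin], ds.class_weights,
        list(ds.enhancers), ds.pwm, ds.sequences)
    truth = ds.truth.direct_target_ids
    k = len(truth)
    recovered = len(set(table.head(k)["gene_id"]) & truth)
    return {"recovered": recovered, "n_planted": len(truth), "k": k,
            "n_candidates": len(table), "table": table, "dataset": ds}


def function_prediction_experiment(seed: int = 17) -> dict:
    """Regulatory-potential KS test and the distal/proximal split under the
    default planted conditions."""
    ds = synthetic.generate(synthetic.SyntheticConfig(seed=seed))
    gres = intervals.assign_peaks_to_genes(ds.peaks, ds.genes)
    rp = regulatory_potential_table(gres, ds.genes)
    res = function_prediction(dict(zip(rp["gene_id"], rp["score"])),
                              {g.gene_id: g.de_status for g in ds.genes})
    return {"result": res, "distal_fraction": intervals.distal_fraction(gres),
            "n_gres": len(gres)}


NULL_CALIBRATION_CONFIG = synthetic.SyntheticConfig(
    n_genes=150, n_chroms=2, genome_span_bp=20_000_000,
    n_direct_targets=10, n_cells=10, n_random_oc=20)


def null_ks_rejection_rate(n_datasets: int = 500, seed: int = 17,
                           alpha: float = 0.05) -> dict:
    """Type-I error of the KS function-prediction test over datasets whose DE
    labels were permuted independently of the regulatory features."""
    base = int(seed) * 100_000
    rej_up = rej_down = 0
    for k in range(n_datasets):
        cfg = dataclasses.replace(NULL_CALIBRATION_CONFIG, seed=base + k)
        ds = synthetic.null_generate(cfg)
        gres = intervals.assign_peaks_to_genes(ds.peaks, ds.genes)
        rp = regulatory_potential_table(gres, ds.genes)
        res = function_prediction(dict(zip(rp["gene_id"], rp["score"])),
                                  {g.gene_id: g.de_status for g in ds.genes})
        rej_up += res.ks_p_up < alpha
        rej_down += res.ks_p_down < alpha
    return {"rate_up": rej_up / n_datasets, "rate_down": rej_down / n_datasets,
            "n_datasets": n_datasets, "alpha": alpha}


def composite_element_experiment(seed: int = 17, n_regions: int = 1000,
                                 p_stringent: float = 0.4,
                                 p_lenient: float = 0.8,
                                 p_auxiliary: float = 0.95) -> dict:
    """Plant primary-motif content at two stringencies plus auxiliary-family
    motifs into background regions, re-detect everything by scanning, and
    summarize the per-region fractions."""
    rng = np.random.default_rng([seed, 811])
    primary = synthetic.default_gbs_pwm()
    aux = _auxiliary_pwm()
    region_len = 300
    half = region_len // 2
    seqs: dict[str, str] = {}
    for i in range(n_regions):
        seq = synthetic._random_sequence(rng, region_len, 0.41)
        r = rng.random()
        # primary copies go in the left half, auxiliary in the right, so the
        # plants never overwrite each other
        if r < p_stringent:
            seq = _plant(seq, primary.consensus, rng, 0, half)
        elif r < p_lenient:
            seq = _plant(seq, _degrade(primary, 3, rng), rng, 0, half)
        if rng.random() < p_auxiliary:
            seq = _plant(seq, aux.consensus, rng, half, region_len)
        seqs[f"r{i:04d}"] = seq
    stringent_hits = motif.scan_regions(primary, seqs, p_threshold=motif.DEFAULT_P_THRESHOLD)
    lenient_hits = motif.scan_regions(primary, seqs, p_threshold=motif.LENIENT_P_THRESHOLD)
    aux_hits = motif.scan_regions(aux, seqs, p_threshold=motif.DEFAULT_P_THRESHOLD)
    stats = motif.composite_element_stats(
        list(seqs), stringent_hits, lenient_hits, aux_hits)
    return {"stats": stats,
            "planted": {"stringent": p_stringent, "lenient": p_lenient,
                        "auxiliary": p_auxiliary}}


def paired_de_overlap(n_shared_up: int = 309, n_shared_down: int = 272,
                      n_only_a: int = 892, n_only_b: int = 2566,
                      seed: int = 17) -> dict:
    """Two DE gene lists with a planted concordance structure, compared with
    :func:`gretarget.expression.de_overlap`.

    The default sizes mirror a two-dataset design in which 581 genes are
    shared (309 concordant-up, 272 concordant-down) and the remainders are
    private to either list.
    """
    rng = np.random.default_rng([seed, 977])

    def rec(gid: str, direction: str) -> GeneRecord:
        mag = float(rng.uniform(0.5, 4.0))
        lfc = mag if direction == "up" else -mag
        return GeneRecord(gid, "chr1", "+", 100, log2fc=lfc,
                          padj=float(rng.uniform(1e-8, 0.049)), de_status=direction)

    a, b = [], []
    for i in range(n_shared_up):
        a.append(rec(f"shared_up_{i}", "up"))
        b.append(rec(f"shared_up_{i}", "up"))
    for i in range(n_shared_down):
        a.append(rec(f"shared_dn_{i}", "down"))
        b.append(rec(f"shared_dn_{i}", "down"))
    for i in range(n_only_a):
        a.append(rec(f"a_only_{i}", "up" if rng.random() < 0.5 else "down"))
    for i in range(n_only_b):
        b.append(rec(f"b_only_{i}", "up" if rng.random() < 0.5 else "down"))
    return {"result": expression.de_overlap(a, b), "set_a": a, "set_b": b}


def _auxiliary_pwm():
    """A sharp 8-bp auxiliary-family motif distinct from the primary one."""
    consensus = "TGACTCAG"
    rows = []
    for base in consensus:
        row = [0.04] * 4
        row["ACGT".index(base)] = 0.88
        rows.append(row)
    return synthetic.PWM(motif_id="AUX_synth", matrix=np.array(rows))


def _plant(seq: str, instance: str, rng: np.random.Generator,
           lo: int, hi: int) -> str:
    offset = int(rng.integers(lo, hi - len(instance) + 1))
    return seq[:offset] + instance + seq[offset + len(instance):]


def _degrade(pwm, n_mismatches: int, rng: np.random.Generator) -> str:
    """Mismatch informative consensus columns so the copy scores inside the
    lenient band but (almost always) below the stringent threshold."""
    instance = pwm.consensus
    informative = [i for i in range(pwm.length) if pwm.matrix[i].max() > 0.5]
    pos = rng.choice(informative, size=n_mismatches, replace=False)
    out = list(instance)
    for i in pos:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)
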