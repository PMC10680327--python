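"""Downstream summaries: fractions, target genes, expression comparison,
PCA classification, TF-overlap trend."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from m3escan.cohort_analysis import (
    ExpressionTable,
    assign_target_genes,
    compare_target_expression,
    fraction_report,
    pca_classification,
    tf_overlap_trend,
)
from m3escan.enhancers import Enhancer, EnhancerSet, M3E, TE, call_active_enhancers, \
    call_m3es
from m3escan.genome_io import Gene, GeneModel, GenomicInterval, PeakSet
from m3escan.quant import SignalMatrix, build_signal_matrix
from m3escan.simulate import SimConfig, generate_cohort, generate_expression, \
    plant_tf_peaks
from m3escan.variants import call_vm3es


def iv(c, s, e):
    return GenomicInterval(c, s, e)


# ---------------------------------------------------------------------------
# fractions


def make_enh_set(sid, n_te, n_m3e):
    enh = []
    pos = 10_000
    for i in range(n_te + n_m3e):
        enh.append(Enhancer(iv("chr1", pos, pos + 500),
                            M3E if i < n_m3e else TE))
        pos += 10_000
    return EnhancerSet(sid, enh)


def test_fraction_ratios():
    es = make_enh_set("a", 540, 60)
    m3es = [e.interval for e in es.of_class(M3E)]
    me3_peaks = PeakSet("a", "H3K4me3", m3es + [iv("chr2", 0, 500)])
    rep = fraction_report({"a": es}, {"a": me3_peaks}, {"a": me3_peaks})
    row = rep.iloc[0]
    assert row["m3e_fraction_of_enhancers"] == pytest.approx(0.10)
    assert row["h3k4me3_peak_fraction_on_m3es"] == pytest.approx(60 / 61)


def test_fraction_zero_enhancers_flagged():
    es = EnhancerSet("a", [])
    rep = fraction_report({"a": es}, {"a": PeakSet("a", "H3K4me3", [])},
                          {"a": PeakSet("a", "H3K4me3", [])})
    assert rep.iloc[0]["flag"] == "zero enhancers"
    assert math.isnan(rep.iloc[0]["m3e_fraction_of_enhancers"])


def test_m3e_fraction_recovered_from_cohort():
    cfg = SimConfig(seed=5, m3e_fraction=0.10, n_gain_vm3e=25, n_lost_vm3e=10)
    res = generate_cohort(cfg)
    model = res.genome
    fracs = []
    for s in res.cohort.samples:
        enh = call_active_enhancers(s.peaks["H3K27ac"], model)
        enh, _ = call_m3es(enh, s.peaks["H3K4me3"], model)
        fracs.append(len(enh.of_class(M3E)) / len(enh))
    assert abs(float(np.mean(fracs)) - 0.10) <= 0.03


# ---------------------------------------------------------------------------
# target genes


def gene_at(gid, chrom, tss):
    return Gene(gid, chrom, "+", tss, (tss, tss + 1000),
                (GenomicInterval(chrom, tss, tss + 100),))


def test_nearest_tss_assignment_and_ties():
    model = GeneModel([gene_at("A", "chr1", 20_000),
                       gene_at("B", "chr1", 60_000)])
    locus = iv("chr1", 9_500, 10_500)  # midpoint ~10 kb from A, 50 kb from B
    assert assign_target_genes([locus], model)[locus] == ["A"]
    # equidistant -> lexicographic tie-break
    mid = iv("chr1", 39_750, 40_250)   # midpoint 40 kb: 20 kb from each
    assert assign_target_genes([mid], model, k_nearest=1)[mid] == ["A"]
    assert assign_target_genes([mid], model, k_nearest=2)[mid] == ["A", "B"]
    # out of range -> empty
    far = iv("chr1", 9_000_000, 9_000_500)
    assert assign_target_genes([far], model, max_distance_bp=500_000)[far] == []


def test_target_assignment_matches_bruteforce():
    rng = np.random.default_rng(17)
    genes = [gene_at(f"g{i:02d}", "chr1", int(p))
             for i, p in enumerate(sorted(rng.integers(0, 1_000_000, 40)))]
    model = GeneModel(genes)
    tss = {g.gene_id: g.tss for g in genes}
    for _ in range(100):
        s = int(rng.integers(0, 1_000_000))
        locus = iv("chr1", s, s + 800)
        got = assign_target_genes([locus], model, 100_000, 2)[locus]
        mid = locus.midpoint
        expected = sorted(
            ((abs(t - mid), g) for g, t in tss.items() if abs(t - mid) <= 100_000),
        )[:2]
        assert got == [g for _, g in expected]


# ---------------------------------------------------------------------------
# expression comparison


def exact_ranksum_p(a, b):
    """Enumeration oracle: exact two-sided Mann-Whitney p for tiny samples."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_stat(idx):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for x in grp for y in rest if x > y) \
            + 0.5 * sum(1 for x in grp for y in rest if x == y)

    observed = u_stat(tuple(range(n)))
    mean_u = n * (len(b)) / 2
    dev = abs(observed - mean_u)
    total = more = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_stat(idx) - mean_u) >= dev - 1e-12:
            more += 1
    return more / total


def test_expression_comparison_exact_small_sample():
    expr = ExpressionTable(pd.DataFrame(
        {"s1": [1, 2, 3, 4, 5, 6]},
        index=[f"g{i}" for i in range(6)],
    ))
    groups = {"TE": ["g0", "g1", "g2"], "m3E": ["g3", "g4", "g5"]}
    summaries, pvals = compare_target_expression(groups, expr)
    assert summaries.loc["TE", "median"] == 2
    assert summaries.loc["m3E", "median"] == 5
    p = pvals.iloc[0]["p_value"]
    assert p == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]), abs=1e-9)
    # identical groups: no false ordering
    same = {"a": ["g0", "g1", "g2"], "b": ["g0", "g1", "g2"]}
    _, pv = compare_target_expression(same, expr)
    assert pv.iloc[0]["p_value"] == pytest.approx(1.0)


def test_missing_genes_dropped_and_counted():
    expr = ExpressionTable(pd.DataFrame({"s1": [1.0, 2.0]}, index=["g0", "g1"]))
    summaries, _ = compare_target_expression(
        {"a": ["g0", "gX"], "b": ["g1"]}, expr
    )
    assert summaries.loc["a", "n_missing"] == 1


def test_expression_generator_preserves_class_ordering(small_result):
    medians = []
    for seed in range(5):
        table = generate_expression(small_result.genome, small_result.truth,
                                    seed=seed)
        truth = small_result.truth
        model = small_result.genome
        by_class = {}
        for klass in ("TE", "m3E", "SE"):
            loci = [p.interval for p in truth.of(klass)]
            genes = set()
            for lo, gs in assign_target_genes(loci, model).items():
                genes.update(gs)
            vals = table.loc[[g for g in genes if g in table.index]].mean(axis=1)
            by_class[klass] = float(vals.median())
        medians.append(by_class["SE"] > by_class["m3E"] > by_class["TE"])
    assert sum(medians) >= 4


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_structure():
    loci = [iv("chr1", 0, 1000), iv("chr1", 5000, 6000)]
    vals = np.array([[1.0, 1.0, 8.0, 8.0],
                     [2.0, 2.0, 2.0, 2.0]])
    mat = SignalMatrix(loci, [("a", "native"), ("b", "native"),
                              ("c", "tumor"), ("d", "tumor")],
                       vals, np.ones(4))
    pca = pca_classification(mat)
    native = pca[pca.tissue == "native"]["PC1"].to_numpy()
    tumor = pca[pca.tissue == "tumor"]["PC1"].to_numpy()
    assert native.max() < tumor.min() or tumor.max() < native.min()
    # PC2 carries nothing for a rank-1 matrix
    assert np.allclose(pca["PC2"], 0, atol=1e-9)


def test_pca_matches_svd_oracle_and_is_order_invariant():
    rng = np.random.default_rng(3)
    vals = rng.gamma(2, 5, size=(10, 6))
    loci = [iv("chr1", 10_000 * i, 10_000 * i + 500) for i in range(10)]
    samples = [(f"s{j}", "native" if j % 2 else "tumor") for j in range(6)]
    mat = SignalMatrix(loci, samples, vals, np.ones(6))
    pca = pca_classification(mat, n_components=2)
    x = np.log2(vals + 1)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    recon = np.abs(pca[["PC1", "PC2"]].to_numpy())
    oracle = np.abs((s[:2, None] * vt[:2]).T)
    assert np.allclose(recon, oracle, atol=1e-9)
    # reordering samples permutes rows only (up to the fixed sign rule)
    perm = [3, 1, 5, 0, 2, 4]
    mat_p = SignalMatrix(loci, [samples[j] for j in perm], vals[:, perm],
                         np.ones(6))
    pca_p = pca_classification(mat_p, n_components=2)
    a = pca.set_index("sample_id")[["PC1", "PC2"]]
    b = pca_p.set_index("sample_id")[["PC1", "PC2"]]
    assert np.allclose(a.loc[b.index].to_numpy(), b.to_numpy(), atol=1e-9)


def test_pca_constant_matrix_warns_zero():
    loci = [iv("chr1", 0, 1000), iv("chr1", 5000, 6000)]
    mat = SignalMatrix(loci, [("a", "x"), ("b", "y")],
                       np.full((2, 2), 3.0), np.ones(2))
    with pytest.warns(UserWarning, match="constant"):
        pca = pca_classification(mat)
    assert np.allclose(pca[["PC1", "PC2"]], 0)


def test_pca_separates_tissues_on_default_cohort(default_result):
    res = default_result
    vm = call_vm3es(res.cohort, res.genome)
    frag_sets, tissues = [], []
    for p in res.cohort.pairs:
        for s in (p.native, p.tumor):
            frag_sets.append(s.fragments["H3K27ac"])
            tissues.append(s.tissue)
    mat = build_signal_matrix([v.interval for v in vm], frag_sets, tissues)
    pca = pca_classification(mat)
    t = pca[pca.tissue == "tumor"]["PC1"]
    n = pca[pca.tissue == "native"]["PC1"]
    assert t.min() > n.max() or n.min() > t.max()


# ---------------------------------------------------------------------------
# TF overlap trend


def test_tf_overlap_fractions():
    m3es = [iv("chr1", 10_000 * i, 10_000 * i + 1000) for i in range(10)]
    tf = plant_tf_peaks(m3es[:8], 1.0, seed=0)
    out = tf_overlap_trend({"t0": m3es}, tf, {"t0": m3es})
    assert out.iloc[0]["m3e_tf_fraction"] == pytest.approx(0.8)
    empty = PeakSet("tf", "TF", [])
    out = tf_overlap_trend({"t0": m3es}, empty, {"t0": m3es})
    assert out.iloc[0]["m3e_tf_fraction"] == 0.0
    out = tf_overlap_trend({"t0": []}, tf, {"t0": m3es})
    assert out.iloc[0]["flag"] == "no m3Es"


def test_tf_timecourse_recovery():
    rng = np.random.default_rng(8)
    m3es = [iv("chr1", 20_000 * i + 1000, 20_000 * i + 2000) for i in range(50)]
    sets, truth = {}, {}
    for t, f in enumerate([0.2, 0.4, 0.6, 0.8]):
        truth[f"t{t}"] = f
        sets[f"t{t}"] = m3es
    for cond, f in truth.items():
        tf = plant_tf_peaks(sets[cond], f, seed=hash(cond) % 2**31)
        out = tf_overlap_trend({cond: sets[cond]}, tf, {cond: sets[cond]})
        assert abs(out.iloc[0]["m3e_tf_fraction"] - f) <= 0.05
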