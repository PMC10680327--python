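"""Variant-locus statistics: pairwise calls, merging, recurrence testing,
threshold selection, and the three callers."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m3escan.enhancers import Enhancer, EnhancerSet, M3E
from m3escan.genome_io import GeneModel, GenomicInterval
from m3escan.simulate import SimConfig, generate_cohort, score_recovery
from m3escan.variants import (
    GAIN,
    LOST,
    NullModel,
    VariantLocus,
    bh_adjust,
    call_pairwise_variants,
    call_vels,
    call_vm3es,
    call_vsels,
    estimate_null,
    merge_cohort_variants,
    recurrence_pvalue,
    select_recurrence_threshold,
)


def iv(c, s, e):
    return GenomicInterval(c, s, e)


# ---------------------------------------------------------------------------
# pairwise calls


def test_pairwise_fc_boundaries():
    loci = [iv("chr1", 0, 1000), iv("chr1", 2000, 3000), iv("chr1", 4000, 5000)]
    calls = call_pairwise_variants(loci, [20, 10, 5], [10, 10, 20],
                                   fc_threshold=2.0, pseudocount=0.0)
    assert calls == [(loci[0], GAIN), (loci[2], LOST)]
    with pytest.raises(ValueError):
        call_pairwise_variants(loci, [1, 1, 1], [1, 1, 1], fc_threshold=1.0)


def test_raising_fc_threshold_never_adds_calls():
    rng = np.random.default_rng(0)
    loci = [iv("chr1", 10_000 * i, 10_000 * i + 1000) for i in range(200)]
    t = rng.gamma(2, 10, 200)
    n = rng.gamma(2, 10, 200)
    prev = None
    for fc in (1.5, 2.0, 3.0, 5.0):
        k = len(call_pairwise_variants(loci, t, n, fc))
        if prev is not None:
            assert k <= prev
        prev = k


# ---------------------------------------------------------------------------
# merging and recurrence


def test_merge_stratifies_by_direction_and_counts_patients():
    a, b = iv("chr1", 100, 200), iv("chr1", 150, 260)
    merged = merge_cohort_variants({"p1": [(a, GAIN)], "p2": [(b, GAIN)]})
    assert len(merged) == 1
    assert merged[0].interval.key() == ("chr1", 100, 260)
    assert merged[0].recurrence == 2

    merged = merge_cohort_variants({"p1": [(a, GAIN)], "p2": [(b, LOST)]})
    assert sorted(v.direction for v in merged) == [GAIN, LOST]
    assert all(v.recurrence == 1 for v in merged)

    # one patient with two overlapping calls still counts once
    merged = merge_cohort_variants({"p1": [(a, GAIN), (b, GAIN)], "p2": []})
    assert merged[0].recurrence == 1


def test_estimate_null_ratio_and_clamp():
    assert estimate_null([20] * 10, [1000] * 10).p0 == pytest.approx(0.02)
    assert estimate_null([0] * 10, [1000] * 10).p0 == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        estimate_null([1], [0])


def test_background_rate_recovered_from_generator():
    """Cohorts generated at background perturbation rate 0.02 should yield a
    null estimate close to it (the paired latent cancels, so noise-only
    calls are rare)."""
    estimates = []
    for seed in range(20):
        cfg = SimConfig(seed=seed, n_pairs=8, n_enhancers_per_sample=300,
                        n_genes=150, n_gain_vm3e=0, n_lost_vm3e=0,
                        n_se_clusters=0, n_chroms=2, chrom_length_bp=5_000_000)
        res = generate_cohort(cfg)
        from m3escan.variants import _pair_loci_and_signal

        calls = tested = 0
        for pair in res.cohort.pairs:
            loci = [p.interval for p in res.truth.loci if p.klass != "SE"]
            t, n = _pair_loci_and_signal(pair, loci)
            calls += len(call_pairwise_variants(loci, t, n, 2.0))
            tested += len(loci)
        estimates.append(estimate_null([calls], [tested]).p0)
    assert abs(float(np.mean(estimates)) - 0.02) <= 0.005


# ---------------------------------------------------------------------------
# p-values and BH


def binom_tail_oracle(k, n, p):
    """Term-by-term summation of the binomial upper tail."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def test_recurrence_pvalue_closed_forms():
    assert recurrence_pvalue(1, 1, NullModel(0.5)) == pytest.approx(0.5)
    assert recurrence_pvalue(3, 3, NullModel(0.5)) == pytest.approx(0.125)
    assert recurrence_pvalue(8, 39, NullModel(0.05)) == pytest.approx(
        binom_tail_oracle(8, 39, 0.05), rel=1e-12
    )
    with pytest.raises(ValueError):
        recurrence_pvalue(0, 5, NullModel(0.5))
    with pytest.raises(ValueError):
        NullModel(0.0)


def test_recurrence_pvalue_monotonicity():
    null = NullModel(0.05)
    ps = [recurrence_pvalue(k, 20, null) for k in range(1, 21)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    by_p0 = [recurrence_pvalue(5, 20, NullModel(p)) for p in (0.01, 0.05, 0.2, 0.5)]
    assert all(a < b for a, b in zip(by_p0, by_p0[1:]))


def test_bh_examples():
    assert bh_adjust([0.05]) == [0.05]
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


def test_bh_matches_statsmodels_reference():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(13)
    for _ in range(200):
        n = int(rng.integers(1, 40))
        p = rng.uniform(1e-8, 1.0, size=n)
        got = bh_adjust(p.tolist())
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, ref)


# ---------------------------------------------------------------------------
# threshold selection


def make_locus(k, q, direction=GAIN, n=20, pos=None):
    pos = pos if pos is not None else k * 1000
    v = VariantLocus(iv("chr1", pos, pos + 500), direction, k, n)
    v.p_value, v.q_value = q, q
    return v


def test_threshold_all_significant_gives_min_recurrence():
    loci = [make_locus(k, 1e-6, pos=k * 1000) for k in (4, 7, 9)]
    assert select_recurrence_threshold(loci, GAIN) == 4


def test_threshold_fraction_table():
    """Significant fractions by recurrence {5: .50, 6: .70, 7: .85, 8: .92}
    select threshold 8."""
    loci = []
    pos = 0
    # (total, significant) at exactly r, chosen so the cumulative fractions
    # among recurrence >= r are 0.50 / 0.70 / 0.85 / 0.92 for r = 5..8
    spec_counts = {5: (500, 150), 6: (300, 180), 7: (150, 124), 8: (50, 46)}
    for r, (total, sig) in spec_counts.items():
        for i in range(total):
            q = 0.001 if i < sig else 0.5
            loci.append(make_locus(r, q, pos=pos))
            pos += 1000
    fracs = {}
    ks = np.array([v.recurrence for v in loci])
    sigs = np.array([v.q_value < 0.05 for v in loci])
    for r in (5, 6, 7, 8):
        fracs[r] = sigs[ks >= r].mean()
    assert fracs[5] == pytest.approx(0.50, abs=0.02)
    assert fracs[8] == pytest.approx(0.92, abs=0.01)
    assert select_recurrence_threshold(loci, GAIN) == 8


def test_threshold_matches_exhaustive_scan():
    rng = np.random.default_rng(21)
    loci = [
        make_locus(int(k), float(q), pos=i * 1000)
        for i, (k, q) in enumerate(zip(rng.integers(1, 15, 200),
                                       rng.uniform(0, 0.2, 200)))
    ]
    got = select_recurrence_threshold(loci, GAIN)
    ks = np.array([v.recurrence for v in loci])
    sig = np.array([v.q_value < 0.05 for v in loci])
    expected = None
    for r in range(ks.min(), ks.max() + 1):
        m = ks >= r
        if m.any() and sig[m].mean() >= 0.90:
            expected = r
            break
    assert got == expected


def test_raising_cutoff_never_lowers_threshold():
    rng = np.random.default_rng(3)
    loci = [
        make_locus(int(k), float(q), pos=i * 1000)
        for i, (k, q) in enumerate(zip(rng.integers(1, 15, 300),
                                       rng.uniform(0, 0.15, 300)))
    ]
    prev = 0
    for cutoff in (0.5, 0.7, 0.9, 0.99):
        r = select_recurrence_threshold(loci, GAIN, cutoff)
        if r is None:
            r = 10**9
        assert r >= prev
        prev = r


def test_empty_stratum_raises():
    with pytest.raises(ValueError, match="no loci"):
        select_recurrence_threshold([make_locus(3, 0.01)], LOST)


# ---------------------------------------------------------------------------
# callers


def test_call_vels_recovers_planted_and_bounds_background():
    cfg = SimConfig(seed=1, n_gain_vm3e=40, n_lost_vm3e=0)
    res = generate_cohort(cfg)
    vels = call_vels(res.cohort, res.genome)
    gains = [v for v in vels if v.direction == GAIN]
    score = score_recovery(vels, res.truth)
    assert score.sensitivity == 1.0
    assert score.confusion["false_calls"] <= 2
    assert all(v.recurrence <= v.n_pairs for v in gains)


def test_call_vels_refuses_tiny_cohort(default_result):
    from m3escan.genome_io import Cohort

    tiny = Cohort(default_result.cohort.pairs[:1])
    with pytest.raises(ValueError, match="at least 3"):
        call_vels(tiny, default_result.genome)


def test_vm3e_two_stage_composition(counts_cohort_builder):
    locus = iv("chr1", 1000, 2000)
    model = GeneModel([])

    def m3e_sets(cohort):
        return {
            s.sample_id: EnhancerSet(s.sample_id, [Enhancer(locus, M3E)])
            for s in cohort.samples
        }

    # mean tumor 6, mean native 3 -> cohort FC 2.0 >= 1.5 with stage-1
    # support (pair 1 FC = 10/2 = 5 >= 2) -> gain Vm3E
    cohort = counts_cohort_builder(locus, [2, 4, 3], [10, 4, 4])
    got = call_vm3es(cohort, model, pseudocount=0.0, m3e_sets=m3e_sets(cohort))
    assert len(got) == 1 and got[0].direction == GAIN
    assert got[0].cohort_fc == pytest.approx(2.0)
    assert got[0].class_label == "Vm3E"

    # cohort FC 1.4 < 1.5 -> not called despite stage-1 support
    cohort = counts_cohort_builder(locus, [2, 4, 4], [7, 4, 3])
    got = call_vm3es(cohort, model, pseudocount=0.0, m3e_sets=m3e_sets(cohort))
    assert got == []

    # cohort FC >= 1.5 but no per-pair FC >= 2 supporter -> not called
    cohort = counts_cohort_builder(locus, [10, 10, 10], [16, 16, 16])
    got = call_vm3es(cohort, model, pseudocount=0.0, m3e_sets=m3e_sets(cohort))
    assert got == []

    # symmetric lost call: cohort FC <= 1/1.5 with a lost supporter
    cohort = counts_cohort_builder(locus, [10, 8, 9], [2, 8, 8])
    got = call_vm3es(cohort, model, pseudocount=0.0, m3e_sets=m3e_sets(cohort))
    assert len(got) == 1 and got[0].direction == LOST


def test_vm3e_recovery_on_default_cohort(default_result):
    res = default_result
    calls = call_vm3es(res.cohort, res.genome)
    score = score_recovery(calls, res.truth)
    assert score.sensitivity >= 0.9
    assert score.precision >= 0.9
    gains = sum(1 for v in calls if v.direction == GAIN)
    losts = sum(1 for v in calls if v.direction == LOST)
    assert gains >= 45 and losts >= 18


def test_vsel_fixed_recurrence_threshold():
    cfg = SimConfig(seed=2, n_pairs=10, n_se_clusters=4, n_gain_vsel=2,
                    recurrence_rate=0.8, n_gain_vm3e=10, n_lost_vm3e=5)
    res = generate_cohort(cfg)
    vsels = call_vsels(res.cohort, res.genome, recurrence_threshold=5)
    planted = [p for p in res.truth.of("SE", variant_only=True)]
    assert len(planted) == 2
    score = score_recovery(vsels, res.truth)
    assert score.sensitivity == 1.0
    assert all(v.recurrence >= 5 for v in vsels)
    # recurrence below the fixed threshold is never returned
    strict = call_vsels(res.cohort, res.genome, recurrence_threshold=11)
    assert strict == []


def test_vsel_empty_se_sets(default_result):
    res = default_result
    empty = {s.sample_id: EnhancerSet(s.sample_id, [])
             for s in res.cohort.samples}
    assert call_vsels(res.cohort, res.genome, se_sets=empty) == []
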