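"""Variant enhancer locus statistics.

The core procedure: call per-pair variant loci (H3K27ac fold change >= 2
between paired native and tumor tissue), merge same-direction calls across
the cohort into single coordinates, count the recurrence (distinct patients)
of each merged locus, attach an exact one-sided binomial tail p-value
against a cohort-estimated null call rate, Benjamini-Hochberg adjust per
direction, and select the smallest recurrence at which at least 90% of loci
are significant.

Three callers share this machinery:

* ``call_vels``   - all active enhancers, data-driven recurrence thresholds;
* ``call_vm3es``  - m3Es only; per-pair FC >= 2 candidates combined with a
  cohort-level mean-RPKM fold change >= 1.5 (gain) or <= 1/1.5 (lost);
* ``call_vsels``  - super enhancers, fixed recurrence threshold (default 5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enhancers import EnhancerSet, M3E, call_active_enhancers, call_m3es, \
    stitch_super_enhancers
from .genome_io import Cohort, GeneModel, GenomicInterval, PatientPair
from .intervals import count_fragments_bulk, merge
from .quant import build_signal_matrix, fold_change

__all__ = [
    "VariantLocus",
    "NullModel",
    "call_pairwise_variants",
    "merge_cohort_variants",
    "estimate_null",
    "recurrence_pvalue",
    "bh_adjust",
    "select_recurrence_threshold",
    "call_vels",
    "call_vm3es",
    "call_vsels",
    "permutation_null",
]

GAIN, LOST = "gain", "lost"
VEL, VM3E, VSEL = "VEL", "Vm3E", "VSEL"


@dataclass
class VariantLocus:
    interval: GenomicInterval
    direction: str                      # gain | lost
    recurrence: int
    n_pairs: int
    p_value: float | None = None
    q_value: float | None = None
    cohort_fc: float | None = None
    class_label: str | None = None      # VEL | Vm3E | VSEL
    member_pairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in (GAIN, LOST):
            raise ValueError(f"bad direction {self.direction!r}")
        if not (1 <= self.recurrence <= self.n_pairs):
            raise ValueError("recurrence must satisfy 1 <= k <= n_pairs")


@dataclass(frozen=True)
class NullModel:
    """Per-pair probability that a random tested locus is called variant."""

    p0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie strictly between 0 and 1")


# ---------------------------------------------------------------------------
# elementary steps


def call_pairwise_variants(
    loci: Sequence[GenomicInterval],
    tumor_rpkm: Sequence[float],
    native_rpkm: Sequence[float],
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[tuple[GenomicInterval, str]]:
    """Per-pair variant calls: gain iff FC(tumor/native) >= threshold, lost iff
    FC(native/tumor) >= threshold.  A locus is never both (threshold > 1)."""
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1 (directions would overlap)")
    if not (len(loci) == len(tumor_rpkm) == len(native_rpkm)):
        raise ValueError("signal vectors must align with loci")
    out = []
    for iv, t, n in zip(loci, tumor_rpkm, native_rpkm):
        if fold_change(t, n, pseudocount) >= fc_threshold:
            out.append((iv, GAIN))
        elif fold_change(n, t, pseudocount) >= fc_threshold:
            out.append((iv, LOST))
    return out


def merge_cohort_variants(
    pair_calls: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    n_pairs: int | None = None,
    gap: int = 0,
) -> list[VariantLocus]:
    """Merge per-pair variant calls cohort-wide, stratified by direction.

    Recurrence of a merged locus is the number of distinct patients
    contributing at least one overlapping same-direction call (never the
    number of calls).  ``n_pairs`` defaults to the number of entries in
    ``pair_calls`` and should be the QC-passing pair count.
    """
    if len(pair_calls) == 0:
        raise ValueError("need at least one pair")
    if n_pairs is None:
        n_pairs = len(pair_calls)
    out: list[VariantLocus] = []
    for direction in (GAIN, LOST):
        ivs, pids = [], []
        for pid, calls in pair_calls.items():
            for iv, d in calls:
                if d == direction:
                    ivs.append(iv)
                    pids.append(pid)
        for m in merge(ivs, gap=gap, sample_ids=pids):
            patients = sorted({sid for sid, _ in m.members})
            out.append(
                VariantLocus(
                    interval=m.interval,
                    direction=direction,
                    recurrence=len(patients),
                    n_pairs=n_pairs,
                    member_pairs=patients,
                )
            )
    out.sort(key=lambda v: (v.interval.chrom, v.interval.start, v.direction))
    return out


def estimate_null(
    n_calls_per_pair: Sequence[int], n_tested_per_pair: Sequence[int]
) -> NullModel:
    """p0 = total variant calls / total tested loci, clamped away from {0, 1}."""
    total_tested = int(sum(n_tested_per_pair))
    if total_tested <= 0:
        raise ValueError("zero tested loci")
    total_calls = int(sum(n_calls_per_pair))
    p0 = total_calls / total_tested
    lo, hi = 1.0 / total_tested, 1.0 - 1.0 / total_tested
    return NullModel(min(max(p0, lo), hi))


def recurrence_pvalue(k: int, n: int, null: NullModel) -> float:
    """Exact one-sided binomial upper tail P(X >= k), X ~ Binomial(n, p0)."""
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    # sf(k-1) = P(X >= k); scipy evaluates the regularized incomplete beta,
    # which equals the term-by-term tail sum exactly
    return float(stats.binom.sf(k - 1, n, null.p0))


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def select_recurrence_threshold(
    loci: Sequence[VariantLocus],
    direction: str,
    significant_fraction_cutoff: float = 0.90,
    q_cutoff: float = 0.05,
    inclusive: bool = True,
) -> int | None:
    """Smallest recurrence r such that among loci of the given direction with
    recurrence >= r (``inclusive``, default) or > r, at least
    ``significant_fraction_cutoff`` have q < ``q_cutoff``.

    Returns None when no r qualifies.  Raises on an empty stratum.
    """
    stratum = [v for v in loci if v.direction == direction]
    if not stratum:
        raise ValueError(f"no loci of direction {direction!r}")
    if any(v.q_value is None for v in stratum):
        raise ValueError("q-values must be computed before threshold selection")
    ks = np.asarray([v.recurrence for v in stratum])
    sig = np.asarray([v.q_value < q_cutoff for v in stratum])
    for r in range(int(ks.min()), int(ks.max()) + 1):
        mask = ks >= r if inclusive else ks > r
        if not mask.any():
            continue
        if sig[mask].mean() >= significant_fraction_cutoff:
            return r
    return None


# ---------------------------------------------------------------------------
# cohort plumbing shared by the three callers


def _pair_loci_and_signal(
    pair: PatientPair,
    loci: Sequence[GenomicInterval],
    mark: str = "H3K27ac",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus RPKM in the pair's tumor and native samples."""
    lengths_kb = np.asarray([(iv.end - iv.start) / 1000.0 for iv in loci])
    t_frags = pair.tumor.fragments[mark]
    n_frags = pair.native.fragments[mark]
    t = count_fragments_bulk(loci, t_frags) / (lengths_kb * t_frags.total_mapped / 1e6)
    n = count_fragments_bulk(loci, n_frags) / (lengths_kb * n_frags.total_mapped / 1e6)
    return t, n


def _attach_significance(
    merged: list[VariantLocus],
    n_calls_per_pair: Sequence[int],
    n_tested_per_pair: Sequence[int],
    null: NullModel | None = None,
) -> NullModel:
    """Compute p (binomial tail) and q (BH per direction) in place."""
    if null is None:
        null = estimate_null(n_calls_per_pair, n_tested_per_pair)
    for v in merged:
        v.p_value = recurrence_pvalue(v.recurrence, v.n_pairs, null)
    for direction in (GAIN, LOST):
        idx = [i for i, v in enumerate(merged) if v.direction == direction]
        if not idx:
            continue
        qs = bh_adjust([merged[i].p_value for i in idx])
        for i, q in zip(idx, qs):
            merged[i].q_value = q
    return null


def _cohort_fc_per_locus(
    cohort: Cohort,
    loci: Sequence[GenomicInterval],
    mark: str = "H3K27ac",
    pseudocount: float = 0.5,
) -> np.ndarray:
    frag_sets, tissues = [], []
    for p in cohort.pairs:
        for s in (p.native, p.tumor):
            frag_sets.append(s.fragments[mark])
            tissues.append(s.tissue)
    mat = build_signal_matrix(loci, frag_sets, tissues)
    mean_t = mat.mean_by_tissue("tumor")
    mean_n = mat.mean_by_tissue("native")
    return (mean_t + pseudocount) / (mean_n + pseudocount)


def _recurrence_pipeline(
    cohort: Cohort,
    per_pair_loci: Mapping[str, list[GenomicInterval]],
    fc_threshold: float,
    pseudocount: float,
    mark: str = "H3K27ac",
) -> tuple[list[VariantLocus], NullModel]:
    """Pairwise calls -> cohort merge -> p/q values, over given per-pair loci."""
    pair_calls: dict[str, list[tuple[GenomicInterval, str]]] = {}
    n_calls, n_tested = [], []
    for pair in cohort.pairs:
        loci = per_pair_loci[pair.patient_id]
        if loci:
            t, n = _pair_loci_and_signal(pair, loci, mark)
            calls = call_pairwise_variants(loci, t, n, fc_threshold, pseudocount)
        else:
            calls = []
        pair_calls[pair.patient_id] = calls
        n_calls.append(len(calls))
        n_tested.append(len(loci))
    merged = merge_cohort_variants(pair_calls, n_pairs=cohort.n_pairs)
    null = _attach_significance(merged, n_calls, n_tested)
    return merged, null


# ---------------------------------------------------------------------------
# the three callers


def call_vels(
    cohort: Cohort,
    model: GeneModel,
    fc_threshold: float = 2.0,
    significant_fraction_cutoff: float = 0.90,
    q_cutoff: float = 0.05,
    tss_exclusion_bp: int = 2000,
    pseudocount: float = 0.5,
) -> list[VariantLocus]:
    """Variant enhancer loci with data-driven recurrence thresholds.

    Per pair, the tested loci are the merged union of the two samples'
    TSS-distal H3K27ac peaks.  The recurrence threshold is selected per
    direction as the smallest r at which >= 90% of merged loci with
    recurrence >= r are BH-significant; loci at or above it are returned.
    """
    if cohort.n_pairs < 3:
        raise ValueError("need at least 3 pairs for recurrence statistics")
    per_pair_loci = {}
    for pair in cohort.pairs:
        enh = []
        for s in (pair.native, pair.tumor):
            enh.extend(
                call_active_enhancers(s.peaks["H3K27ac"], model,
                                      tss_exclusion_bp).intervals
            )
        per_pair_loci[pair.patient_id] = [m.interval for m in merge(enh)]
    merged, _ = _recurrence_pipeline(cohort, per_pair_loci, fc_threshold,
                                     pseudocount)
    out: list[VariantLocus] = []
    for direction in (GAIN, LOST):
        stratum = [v for v in merged if v.direction == direction]
        if not stratum:
            continue
        r = select_recurrence_threshold(
            stratum, direction, significant_fraction_cutoff, q_cutoff
        )
        if r is None:
            warnings.warn(f"no recurrence threshold reached for {direction} VELs; "
                          "returning none for this direction")
            continue
        for v in stratum:
            if v.recurrence >= r:
                v.class_label = VEL
                out.append(v)
    _fill_cohort_fc(cohort, out, pseudocount)
    return out


def call_vm3es(
    cohort: Cohort,
    model: GeneModel,
    pair_fc: float = 2.0,
    cohort_fc: float = 1.5,
    tss_exclusion_bp: int = 2000,
    pseudocount: float = 0.5,
    min_recurrence: int | None = None,
    m3e_sets: Mapping[str, EnhancerSet] | None = None,
) -> list[VariantLocus]:
    """Variant m3Es: per-pair FC >= ``pair_fc`` support plus a cohort-level
    mean-RPKM fold change of at least ``cohort_fc`` (gain) or at most
    1/``cohort_fc`` (lost).

    Stage 1 tests each pair's merged m3E loci for FC >= pair_fc in either
    direction.  Stage 2 merges all samples' m3Es into cohort loci, computes
    mean tumor and mean native H3K27ac RPKM per locus, and calls a Vm3E where
    the mean-FC threshold is met AND at least one stage-1 call of the same
    direction overlaps the locus.  Recurrence, p and q are recorded for
    reporting; ``min_recurrence`` optionally adds a recurrence filter
    (off by default).

    ``m3e_sets`` maps sample_id to a pre-computed :class:`EnhancerSet` and
    skips the internal enhancer/m3E calling when supplied.
    """
    if m3e_sets is None:
        m3e_sets = {}
        for s in cohort.samples:
            enh = call_active_enhancers(s.peaks["H3K27ac"], model, tss_exclusion_bp)
            enh, _ = call_m3es(enh, s.peaks["H3K4me3"], model, tss_exclusion_bp)
            m3e_sets[s.sample_id] = enh

    def m3e_ivs(sample) -> list[GenomicInterval]:
        return [e.interval for e in m3e_sets[sample.sample_id].of_class(M3E)]

    per_pair_loci = {}
    for pair in cohort.pairs:
        ivs = m3e_ivs(pair.native) + m3e_ivs(pair.tumor)
        per_pair_loci[pair.patient_id] = [m.interval for m in merge(ivs)]
    stage1, _ = _recurrence_pipeline(cohort, per_pair_loci, pair_fc, pseudocount)

    all_ivs = []
    for s in cohort.samples:
        all_ivs.extend(m3e_ivs(s))
    if not all_ivs:
        return []
    cohort_loci = [m.interval for m in merge(all_ivs)]
    fc = _cohort_fc_per_locus(cohort, cohort_loci, "H3K27ac", pseudocount)

    stage1_by_dir = {
        d: [v for v in stage1 if v.direction == d] for d in (GAIN, LOST)
    }
    out = []
    for iv, f in zip(cohort_loci, fc):
        if f >= cohort_fc:
            direction = GAIN
        elif f <= 1.0 / cohort_fc:
            direction = LOST
        else:
            continue
        support = [
            v for v in stage1_by_dir[direction]
            if v.interval.chrom == iv.chrom
            and min(v.interval.end, iv.end) > max(v.interval.start, iv.start)
        ]
        if not support:
            continue
        patients = sorted({pid for v in support for pid in v.member_pairs})
        v = VariantLocus(
            interval=iv, direction=direction, recurrence=len(patients),
            n_pairs=cohort.n_pairs, cohort_fc=float(f), class_label=VM3E,
            member_pairs=patients,
            p_value=min(x.p_value for x in support),
            q_value=min(x.q_value for x in support),
        )
        if min_recurrence is not None and v.recurrence < min_recurrence:
            continue
        out.append(v)
    return out


def call_vsels(
    cohort: Cohort,
    model: GeneModel,
    recurrence_threshold: int = 5,
    fc_threshold: float = 2.0,
    tss_exclusion_bp: int = 2000,
    stitch_bp: int = 12500,
    pseudocount: float = 0.5,
    se_sets: Mapping[str, EnhancerSet] | None = None,
) -> list[VariantLocus]:
    """Variant super-enhancer loci: the VEL pipeline restricted to super
    enhancers, with a fixed recurrence threshold (no data-driven selection).

    ``se_sets`` maps sample_id to a pre-computed super-enhancer set; when
    absent, super enhancers are stitched per sample from that sample's
    TSS-distal H3K27ac peaks ranked by H3K27ac RPKM.
    """
    if se_sets is None:
        se_sets = {}
        for s in cohort.samples:
            enh = call_active_enhancers(s.peaks["H3K27ac"], model, tss_exclusion_bp)
            frags = s.fragments["H3K27ac"]
            lengths_kb = np.asarray(
                [(iv.end - iv.start) / 1000.0 for iv in enh.intervals]
            )
            if len(enh):
                sig = count_fragments_bulk(enh.intervals, frags) / (
                    lengths_kb * frags.total_mapped / 1e6
                )
            else:
                sig = np.zeros(0)
            se_sets[s.sample_id] = stitch_super_enhancers(enh, sig, stitch_bp)

    per_pair_loci = {}
    any_se = False
    for pair in cohort.pairs:
        ivs = []
        for s in (pair.native, pair.tumor):
            ivs.extend(se_sets[s.sample_id].intervals)
        any_se = any_se or bool(ivs)
        per_pair_loci[pair.patient_id] = [m.interval for m in merge(ivs)]
    if not any_se:
        return []
    merged, _ = _recurrence_pipeline(cohort, per_pair_loci, fc_threshold,
                                     pseudocount)
    out = [v for v in merged if v.recurrence >= recurrence_threshold]
    for v in out:
        v.class_label = VSEL
    _fill_cohort_fc(cohort, out, pseudocount)
    return out


def _fill_cohort_fc(
    cohort: Cohort, loci: list[VariantLocus], pseudocount: float
) -> None:
    if not loci:
        return
    fc = _cohort_fc_per_locus(cohort, [v.interval for v in loci],
                              "H3K27ac", pseudocount)
    for v, f in zip(loci, fc):
        v.cohort_fc = float(f)


# ---------------------------------------------------------------------------
# alternative null for cross-checking


def permutation_null(
    cohort: Cohort,
    per_pair_loci: Mapping[str, list[GenomicInterval]],
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    n_perm: int = 20,
    seed: int = 0,
) -> NullModel:
    """Estimate the per-pair call rate with tumor/native labels shuffled.

    Swapping the two tissue labels within a random subset of patients
    destroys consistent tumor/native direction while preserving each
    sample's marginal signal distribution; the resulting call rate is an
    alternative p0 for :func:`recurrence_pvalue`.
    """
    rng = np.random.default_rng(seed)
    calls = tested = 0
    for _ in range(n_perm):
        for pair in cohort.pairs:
            loci = per_pair_loci[pair.patient_id]
            if not loci:
                continue
            t, n = _pair_loci_and_signal(pair, loci)
            if rng.random() < 0.5:
                t, n = n, t
            calls += len(call_pairwise_variants(loci, t, n, fc_threshold,
                                                pseudocount))
            tested += len(loci)
    if tested == 0:
        raise ValueError("no tested loci")
    lo, hi = 1.0 / tested, 1.0 - 1.0 / tested
    return NullModel(min(max(calls / tested, lo), hi))
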