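"""Interval algebra used by every calling stage.

All operations work on 0-based half-open intervals, so two intervals that
merely abut ([100,200) and [200,300)) do not overlap.  Distances to a TSS
are strand-ignorant coordinate differences: the TSS is a point, and the
distance to an interval is 0 when the point falls inside it, otherwise the
difference between the point and the nearest contained base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import (
    FragmentSet,
    GeneModel,
    GenomicInterval,
    intervals_by_chrom,
    sort_intervals,
)

__all__ = [
    "overlaps",
    "overlap_length",
    "merge",
    "MergedLocus",
    "min_distance_to_tss",
    "min_tss_distances",
    "count_overlapping_fragments",
    "count_fragments_bulk",
]


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share a chromosome and overlap by at least min_bp bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


@dataclass
class MergedLocus:
    """Union envelope of a set of overlapping member intervals."""

    interval: GenomicInterval
    members: list[tuple[str | None, GenomicInterval]]

    @property
    def sample_ids(self) -> set[str | None]:
        return {sid for sid, _ in self.members}


def merge(
    intervals: Sequence[GenomicInterval],
    gap: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> list[MergedLocus]:
    """Merge intervals into union envelopes, bridging gaps up to ``gap`` bases.

    With ``gap=0`` only genuinely overlapping intervals merge; abutting
    half-open intervals stay separate.  With ``gap=g > 0`` two intervals
    separated by at most g bases are bridged.  Idempotent, order-independent,
    output sorted by (chrom, start).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if sample_ids is not None and len(sample_ids) != len(intervals):
        raise ValueError("sample_ids length mismatch")
    tagged = [
        (iv, sample_ids[i] if sample_ids is not None else None)
        for i, iv in enumerate(intervals)
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[MergedLocus] = []
    cur: list[tuple[str | None, GenomicInterval]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv, sid in tagged:
        bridge = (
            cur
            and iv.chrom == cur_chrom
            and (iv.start < cur_end or (gap > 0 and iv.start - cur_end <= gap))
        )
        if bridge:
            cur.append((sid, iv))
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                out.append(
                    MergedLocus(GenomicInterval(cur_chrom, cur_start, cur_end), cur)
                )
            cur = [(sid, iv)]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur:
        out.append(MergedLocus(GenomicInterval(cur_chrom, cur_start, cur_end), cur))
    return out


def _point_to_interval_distance(point: int, start: int, end: int) -> int:
    if start <= point < end:
        return 0
    if point < start:
        return start - point
    return point - (end - 1)


def min_distance_to_tss(
    x: GenomicInterval, model: GeneModel
) -> tuple[float, str | None]:
    """Distance from the nearest TSS point to the nearest base of ``x``.

    Returns ``(math.inf, None)`` when no TSS shares the chromosome.
    """
    idx = model.tss_index(x.chrom)
    if idx is None:
        return (math.inf, None)
    tss, gene_ids = idx
    # any TSS inside [start, end) -> distance 0
    i = int(np.searchsorted(tss, x.start, side="left"))
    if i < len(tss) and tss[i] < x.end:
        return (0, gene_ids[i])
    best_d, best_g = math.inf, None
    for j in (i - 1, i):
        if 0 <= j < len(tss):
            d = _point_to_interval_distance(int(tss[j]), x.start, x.end)
            if d < best_d:
                best_d, best_g = d, gene_ids[j]
    return (best_d, best_g)


def min_tss_distances(
    intervals: Sequence[GenomicInterval], model: GeneModel
) -> np.ndarray:
    """Vectorized :func:`min_distance_to_tss` distances (inf where no TSS)."""
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        out[i] = min_distance_to_tss(iv, model)[0]
    return out


def count_overlapping_fragments(
    locus: GenomicInterval, frags: FragmentSet, min_bp: int = 1
) -> int:
    """Number of fragments overlapping ``locus`` by at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    idx = frags.index().get(locus.chrom)
    if idx is None:
        return 0
    starts, ends, ends_sorted = idx
    if min_bp == 1:
        # start < locus.end and end > locus.start
        n_start_before_end = int(np.searchsorted(starts, locus.end, side="left"))
        n_end_at_or_before_start = int(
            np.searchsorted(ends_sorted, locus.start, side="right")
        )
        return n_start_before_end - n_end_at_or_before_start
    ovl = np.minimum(ends, locus.end) - np.maximum(starts, locus.start)
    return int(np.count_nonzero(ovl >= min_bp))


def count_fragments_bulk(
    loci: Sequence[GenomicInterval], frags: FragmentSet, min_bp: int = 1
) -> np.ndarray:
    """Fragment counts for many loci at once (same semantics as the scalar op)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    counts = np.zeros(len(loci), dtype=np.int64)
    if min_bp != 1:
        for i, lo in enumerate(loci):
            counts[i] = count_overlapping_fragments(lo, frags, min_bp)
        return counts
    index = frags.index()
    by_chrom: dict[str, list[int]] = {}
    for i, lo in enumerate(loci):
        by_chrom.setdefault(lo.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        if chrom not in index:
            continue
        starts, _, ends_sorted = index[chrom]
        ls = np.asarray([loci[i].start for i in idxs], dtype=np.int64)
        le = np.asarray([loci[i].end for i in idxs], dtype=np.int64)
        n_before = np.searchsorted(starts, le, side="left")
        n_done = np.searchsorted(ends_sorted, ls, side="right")
        counts[idxs] = n_before - n_done
    return counts
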