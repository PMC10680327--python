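"""Calling of TSS-distal active enhancers, m3E classification, super-enhancer
stitching and genomic-distribution annotation.

Active enhancers are H3K27ac peaks lying entirely more than a configurable
distance (default 2 kb) from every annotated TSS; enhancers overlapping a
TSS-distal H3K4me3 peak are classified as H3K4me3-enriched enhancers (m3Es).
Super enhancers are called ROSE-style: constituents within 12.5 kb are
stitched, candidates ranked by summed H3K27ac signal, and the cutoff is the
point on the min-max-scaled rank/signal curve where the slope first exceeds 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SampleManifest,
    read_peaks,
)
from .intervals import merge, min_distance_to_tss, overlaps

__all__ = [
    "Enhancer",
    "EnhancerSet",
    "QCReport",
    "qc_filter_samples",
    "distal_peaks",
    "call_active_enhancers",
    "call_m3es",
    "stitch_super_enhancers",
    "annotate_genomic_distribution",
]

TE, M3E, SE = "TE", "m3E", "SE"


@dataclass(frozen=True)
class Enhancer:
    interval: GenomicInterval
    klass: str                      # TE | m3E | SE
    source_peak_ids: tuple[int, ...] = ()


@dataclass
class EnhancerSet:
    sample_id: str
    enhancers: list[Enhancer]

    def __len__(self) -> int:
        return len(self.enhancers)

    def of_class(self, klass: str) -> list[Enhancer]:
        return [e for e in self.enhancers if e.klass == klass]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.enhancers]


# ---------------------------------------------------------------------------
# sample QC


@dataclass
class QCReport:
    """Per-sample peak counts and inclusion decisions; pairing is preserved."""

    rows: pd.DataFrame  # sample_id, patient_id, tissue, counts per mark, included, reason

    @property
    def included_patients(self) -> list[str]:
        ok = self.rows[self.rows["included"]]
        return sorted(ok["patient_id"].unique())

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def qc_filter_samples(
    manifest: SampleManifest,
    min_peaks: int | Mapping[str, int] = 5000,
    peak_counts: Mapping[tuple[str, str, str], int] | None = None,
) -> QCReport:
    """Exclude samples whose peak count for any mark falls below a minimum.

    A failing sample takes its pair partner with it, so downstream stages only
    ever see complete native/tumor pairs.  ``peak_counts`` maps
    (patient_id, tissue, mark) to a count and bypasses file reads when given
    (the cohort may already be in memory); otherwise peak files named in the
    manifest are read and counted.
    """
    def threshold(mark: str) -> int:
        if isinstance(min_peaks, Mapping):
            return int(min_peaks.get(mark, 0))
        return int(min_peaks)

    records: dict[tuple[str, str], dict] = {}
    for row in manifest.rows.itertuples():
        key = (row.patient_id, row.tissue)
        rec = records.setdefault(
            key,
            {"patient_id": row.patient_id, "tissue": row.tissue,
             "sample_id": f"{row.patient_id}_{row.tissue}", "counts": {}},
        )
        if peak_counts is not None:
            n = peak_counts[(row.patient_id, row.tissue, row.mark)]
        else:
            n = len(read_peaks(row.peak_path, "bed", mark=row.mark))
        rec["counts"][row.mark] = n

    fail_reason: dict[tuple[str, str], str] = {}
    for key, rec in records.items():
        low = [
            f"{mark}={n}<{threshold(mark)}"
            for mark, n in sorted(rec["counts"].items())
            if n < threshold(mark)
        ]
        if low:
            fail_reason[key] = "low peak count: " + ", ".join(low)

    out_rows = []
    for pid in manifest.patients:
        keys = [(pid, "native"), (pid, "tumor")]
        present = [k for k in keys if k in records]
        if len(present) < 2:
            warnings.warn(f"patient {pid} has a single tissue; dropped")
            for k in present:
                out_rows.append({**_flat(records[k]), "included": False,
                                 "reason": "unpaired"})
            continue
        direct = {k: fail_reason.get(k) for k in keys}
        any_fail = any(direct.values())
        for k in keys:
            if direct[k]:
                reason = direct[k]
            elif any_fail:
                other = keys[1] if k == keys[0] else keys[0]
                reason = f"pair partner excluded ({records[other]['tissue']})"
            else:
                reason = ""
            out_rows.append({**_flat(records[k]), "included": not any_fail,
                             "reason": reason})
    return QCReport(pd.DataFrame(out_rows))


def _flat(rec: dict) -> dict:
    out = {"sample_id": rec["sample_id"], "patient_id": rec["patient_id"],
           "tissue": rec["tissue"]}
    for mark, n in sorted(rec["counts"].items()):
        out[f"n_peaks_{mark}"] = n
    return out


# ---------------------------------------------------------------------------
# enhancer / m3E calling


def distal_peaks(
    peaks: PeakSet, model: GeneModel, tss_exclusion_bp: int = 2000
) -> list[GenomicInterval]:
    """Peaks whose every base lies more than ``tss_exclusion_bp`` from all TSS."""
    out = []
    for iv in peaks.intervals:
        d, _ = min_distance_to_tss(iv, model)
        if d > tss_exclusion_bp:
            out.append(iv)
    return out


def call_active_enhancers(
    h3k27ac: PeakSet, model: GeneModel, tss_exclusion_bp: int = 2000
) -> EnhancerSet:
    """TSS-distal H3K27ac peaks, all labelled typical enhancers (TE)."""
    enh = [
        Enhancer(iv, TE, (i,))
        for i, iv in enumerate(h3k27ac.intervals)
        if min_distance_to_tss(iv, model)[0] > tss_exclusion_bp
    ]
    return EnhancerSet(h3k27ac.sample_id, enh)


def call_m3es(
    enhancers: EnhancerSet,
    h3k4me3: PeakSet,
    model: GeneModel,
    tss_exclusion_bp: int = 2000,
    min_bp: int = 1,
) -> tuple[EnhancerSet, PeakSet]:
    """Relabel enhancers overlapping a TSS-distal H3K4me3 peak as m3Es.

    The enhancer keeps its own (H3K27ac) coordinates.  Returns the updated
    set and the TSS-distal H3K4me3 peaks used, which downstream fraction
    statistics need.
    """
    distal_me3 = distal_peaks(h3k4me3, model, tss_exclusion_bp)
    me3_starts: dict[str, np.ndarray] = {}
    me3_ends: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in distal_me3:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        me3_starts[chrom] = np.asarray([p.start for p in ivs])
        me3_ends[chrom] = np.asarray([p.end for p in ivs])

    out = []
    for e in enhancers.enhancers:
        iv = e.interval
        hit = False
        if iv.chrom in me3_starts:
            s, t = me3_starts[iv.chrom], me3_ends[iv.chrom]
            ovl = np.minimum(t, iv.end) - np.maximum(s, iv.start)
            hit = bool((ovl >= min_bp).any())
        out.append(Enhancer(iv, M3E if hit else e.klass, e.source_peak_ids))
    return (
        EnhancerSet(enhancers.sample_id, out),
        PeakSet(h3k4me3.sample_id, h3k4me3.mark, distal_me3),
    )


def stitch_super_enhancers(
    enhancers: EnhancerSet,
    signal: Sequence[float],
    stitch_bp: int = 12500,
) -> EnhancerSet:
    """ROSE-style super-enhancer calling.

    Enhancers within ``stitch_bp`` are stitched into candidates; candidate
    signal is the sum of constituent signal; candidates are ranked ascending
    and both axes min-max scaled; the super enhancers are the candidates
    strictly above the first point at which the discrete slope of the scaled
    curve exceeds 1.  Ties in signal are broken by coordinate so the call is
    deterministic.  Fewer than 3 candidates, or a flat signal curve, yields
    no super enhancers.
    """
    if len(signal) != len(enhancers):
        raise ValueError("signal length must match enhancer count")
    ivs = enhancers.intervals
    merged = merge(ivs, gap=stitch_bp, sample_ids=[str(i) for i in range(len(ivs))])
    if len(merged) < 3:
        warnings.warn("fewer than 3 stitched candidates; no super enhancers called")
        return EnhancerSet(enhancers.sample_id, [])
    sig = np.asarray(signal, dtype=float)
    cand_signal = np.asarray(
        [sum(sig[int(sid)] for sid, _ in m.members) for m in merged]
    )
    order = sorted(
        range(len(merged)),
        key=lambda i: (cand_signal[i], merged[i].interval.chrom,
                       merged[i].interval.start),
    )
    y = cand_signal[order]
    if y[-1] == y[0]:
        return EnhancerSet(enhancers.sample_id, [])
    yn = (y - y[0]) / (y[-1] - y[0])
    xn = np.arange(len(y)) / (len(y) - 1)
    slopes = np.diff(yn) / np.diff(xn)
    above = np.nonzero(slopes > 1.0)[0]
    if above.size == 0:
        return EnhancerSet(enhancers.sample_id, [])
    cut = int(above[0])  # candidates with rank index > cut are SEs
    ses = []
    for rank in range(cut + 1, len(order)):
        m = merged[order[rank]]
        ses.append(
            Enhancer(m.interval, SE, tuple(int(sid) for sid, _ in m.members))
        )
    ses.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return EnhancerSet(enhancers.sample_id, ses)


# ---------------------------------------------------------------------------
# genomic distribution


CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def annotate_genomic_distribution(
    loci: Sequence[GenomicInterval],
    model: GeneModel,
    tss_exclusion_bp: int = 2000,
) -> dict[str, int]:
    """Assign each locus one category by priority promoter > exon > intron >
    intergenic (any-overlap); counts always sum to the input size.

    "Promoter" means within ``tss_exclusion_bp`` of some TSS; "intron" means
    inside a gene span without touching an exon.
    """
    exon_idx: dict[str, list[GenomicInterval]] = {}
    span_idx: dict[str, list[tuple[int, int]]] = {}
    for g in model.genes:
        span_idx.setdefault(g.chrom, []).append(g.span)
        exon_idx.setdefault(g.chrom, []).extend(g.exons)

    counts = dict.fromkeys(CATEGORIES, 0)
    for iv in loci:
        d, _ = min_distance_to_tss(iv, model)
        if d <= tss_exclusion_bp:
            counts["promoter"] += 1
            continue
        if any(overlaps(iv, ex) for ex in exon_idx.get(iv.chrom, [])):
            counts["exon"] += 1
            continue
        spans = span_idx.get(iv.chrom, [])
        if any(min(e, iv.end) > max(s, iv.start) for s, e in spans):
            counts["intron"] += 1
            continue
        counts["intergenic"] += 1
    return counts
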