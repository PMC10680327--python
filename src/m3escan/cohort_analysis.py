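"""Cohort-level summaries downstream of enhancer and variant calling.

Covers per-sample m3E fractions, nearest-TSS target-gene assignment,
expression comparison between enhancer-class target-gene sets, PCA of the
variant-m3E signal matrix for sample classification, and TF-occupancy
trends across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enhancers import EnhancerSet, M3E
from .genome_io import GeneModel, GenomicInterval, PeakSet
from .intervals import overlaps
from .quant import SignalMatrix

__all__ = [
    "fraction_report",
    "assign_target_genes",
    "ExpressionTable",
    "compare_target_expression",
    "pca_classification",
    "tf_overlap_trend",
]


def fraction_report(
    enhancer_sets: Mapping[str, EnhancerSet],
    distal_h3k4me3: Mapping[str, PeakSet],
    all_h3k4me3: Mapping[str, PeakSet],
) -> pd.DataFrame:
    """Per-sample m3E fraction of enhancers, and fraction of H3K4me3 peaks
    lying on m3Es.

    ``enhancer_sets`` must carry m3E labels (i.e. be the output of m3E
    calling).  A sample with zero enhancers is flagged and its fractions are
    NaN.
    """
    rows = []
    for sid, enh in enhancer_sets.items():
        n_enh = len(enh)
        m3es = [e.interval for e in enh.of_class(M3E)]
        if n_enh == 0:
            rows.append({"sample_id": sid, "n_enhancers": 0, "n_m3es": 0,
                         "m3e_fraction_of_enhancers": math.nan,
                         "h3k4me3_peak_fraction_on_m3es": math.nan,
                         "flag": "zero enhancers"})
            continue
        all_me3 = all_h3k4me3[sid].intervals
        n_on = sum(
            1 for p in all_me3 if any(overlaps(p, m) for m in m3es)
        )
        rows.append({
            "sample_id": sid,
            "n_enhancers": n_enh,
            "n_m3es": len(m3es),
            "m3e_fraction_of_enhancers": len(m3es) / n_enh,
            "h3k4me3_peak_fraction_on_m3es": (n_on / len(all_me3)) if all_me3
            else math.nan,
            "flag": "",
        })
    return pd.DataFrame(rows)


def assign_target_genes(
    loci: Sequence[GenomicInterval],
    model: GeneModel,
    max_distance_bp: int = 500_000,
    k_nearest: int = 1,
) -> dict[GenomicInterval, list[str]]:
    """Proximal target genes: the k nearest TSS (by distance from the locus
    midpoint) within ``max_distance_bp``.

    Ties broken by (distance, gene_id lexicographic); an empty list when no
    TSS is in range.
    """
    if len(model) == 0:
        raise ValueError("gene model is empty")
    out: dict[GenomicInterval, list[str]] = {}
    for iv in loci:
        idx = model.tss_index(iv.chrom)
        if idx is None:
            out[iv] = []
            continue
        tss, gene_ids = idx
        mid = iv.midpoint
        d = np.abs(tss - mid)
        cand = [
            (float(d[i]), gene_ids[i])
            for i in range(len(tss))
            if d[i] <= max_distance_bp
        ]
        cand.sort()
        out[iv] = [g for _, g in cand[:k_nearest]]
    return out


@dataclass
class ExpressionTable:
    """gene_id -> per-sample expression (FPKM as provided upstream)."""

    values: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def mean_expression(self, genes: Sequence[str]) -> tuple[np.ndarray, int]:
        """Per-gene mean across samples; returns (values, n_missing_dropped)."""
        present = [g for g in genes if g in self.values.index]
        dropped = len(genes) - len(present)
        return self.values.loc[present].mean(axis=1).to_numpy(), dropped


def compare_target_expression(
    groups: Mapping[str, Sequence[str]],
    expr: ExpressionTable,
    exact_max_n: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median expression per enhancer-class gene set plus pairwise two-sided
    Mann-Whitney p-values.

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` members (deterministic small-sample behaviour), the
    normal approximation otherwise.  Genes absent from the table are dropped
    and counted.
    """
    summaries = []
    vals: dict[str, np.ndarray] = {}
    for name, genes in groups.items():
        if len(genes) == 0:
            raise ValueError(f"group {name!r} is empty")
        v, dropped = expr.mean_expression(list(genes))
        vals[name] = v
        summaries.append({"group": name, "n": len(v), "n_missing": dropped,
                          "median": float(np.median(v)) if len(v) else math.nan})
    names = list(groups)
    prows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            method = "exact" if max(len(vals[a]), len(vals[b])) <= exact_max_n \
                else "asymptotic"
            res = stats.mannwhitneyu(vals[a], vals[b], alternative="two-sided",
                                     method=method)
            prows.append({"group_a": a, "group_b": b, "p_value": float(res.pvalue),
                          "method": method})
    return pd.DataFrame(summaries).set_index("group"), pd.DataFrame(prows)


def pca_classification(
    matrix: SignalMatrix, n_components: int = 2
) -> pd.DataFrame:
    """Sample coordinates on the top principal components of log2(RPKM + 1).

    Rows (loci) are mean-centered; no unit-variance scaling.  The sign of
    each component is fixed so that its largest-magnitude locus loading is
    positive, making the output deterministic.  A constant matrix yields
    all-zero coordinates.
    """
    if len(matrix.samples) < 2 or len(matrix.loci) < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    x = np.log2(matrix.values + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    if np.allclose(x, 0):
        import warnings

        warnings.warn("constant signal matrix; PCA coordinates are all zero")
        coords = np.zeros((len(matrix.samples), n_components))
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        k = min(n_components, s.size)
        coords = np.zeros((len(matrix.samples), n_components))
        for c in range(k):
            load = u[:, c]
            sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
            coords[:, c] = sign * s[c] * vt[c]
    df = pd.DataFrame(
        coords, columns=[f"PC{c + 1}" for c in range(n_components)]
    )
    df.insert(0, "sample_id", [sid for sid, _ in matrix.samples])
    df.insert(1, "tissue", [t for _, t in matrix.samples])
    return df


def tf_overlap_trend(
    m3e_sets: Mapping[str, Sequence[GenomicInterval]],
    tf_peaks: PeakSet,
    enhancer_sets: Mapping[str, Sequence[GenomicInterval]],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Fraction of m3Es (and, in parallel, of enhancers) overlapped by TF
    peaks, per condition/timepoint.  Zero-m3E conditions get NaN and a flag.
    """
    tf = tf_peaks.intervals
    rows = []
    for cond in m3e_sets:
        def frac(loci: Sequence[GenomicInterval]) -> float:
            if len(loci) == 0:
                return math.nan
            hit = sum(
                1 for lo in loci if any(overlaps(lo, p, min_bp) for p in tf)
            )
            return hit / len(loci)

        f_m3e = frac(m3e_sets[cond])
        f_enh = frac(enhancer_sets.get(cond, []))
        rows.append({
            "condition": cond,
            "m3e_tf_fraction": f_m3e,
            "enhancer_tf_fraction": f_enh,
            "flag": "no m3Es" if math.isnan(f_m3e) else "",
        })
    return pd.DataFrame(rows)
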