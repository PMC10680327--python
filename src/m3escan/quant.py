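"""RPKM quantification of ChIP signal over loci, and fold-change arithmetic.

RPKM = fragments overlapping the locus / (locus length in kb x library size
in millions).  Fold changes between tissues are pseudocount-stabilized
ratios, (tumor + c) / (native + c), with c = 0.5 by default so zero-signal
loci stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import FragmentSet, GenomicInterval
from .intervals import count_fragments_bulk

__all__ = ["rpkm", "build_signal_matrix", "fold_change", "SignalMatrix",
           "summarize_group_signal"]


def rpkm(locus: GenomicInterval, frags: FragmentSet, min_bp: int = 1) -> float:
    """Reads per kilobase of locus per million mapped fragments."""
    length_kb = (locus.end - locus.start) / 1000.0
    if length_kb <= 0:
        raise ValueError("zero-length locus")
    count = count_fragments_bulk([locus], frags, min_bp=min_bp)[0]
    return float(count) / (length_kb * frags.total_mapped / 1e6)


@dataclass
class SignalMatrix:
    """loci x samples matrix of RPKM values.

    ``samples`` is a list of (sample_id, tissue); ``values[i, j]`` is the
    RPKM of locus i in sample j; ``library_sizes[j]`` is that sample's
    total mapped fragment count.
    """

    loci: list[GenomicInterval]
    samples: list[tuple[str, str]]
    values: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.values.shape != (len(self.loci), len(self.samples)):
            raise ValueError("SignalMatrix dimensions inconsistent")
        if (self.values < 0).any():
            raise ValueError("RPKM values must be non-negative")

    def columns_for_tissue(self, tissue: str) -> np.ndarray:
        return np.asarray([j for j, (_, t) in enumerate(self.samples) if t == tissue])

    def mean_by_tissue(self, tissue: str) -> np.ndarray:
        cols = self.columns_for_tissue(tissue)
        if cols.size == 0:
            raise ValueError(f"no samples of tissue {tissue!r}")
        return self.values[:, cols].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.loci]
        cols = [sid for sid, _ in self.samples]
        return pd.DataFrame(self.values, index=idx, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_signal_matrix(
    loci: Sequence[GenomicInterval],
    fragment_sets: Sequence[FragmentSet],
    tissues: Sequence[str] | None = None,
    min_bp: int = 1,
) -> SignalMatrix:
    """RPKM matrix over ``loci`` for a list of per-sample fragment sets.

    Column order follows ``fragment_sets``; all sets must share one mark.
    """
    marks = {fs.mark for fs in fragment_sets}
    if len(marks) > 1:
        raise ValueError(f"fragment sets mix marks: {sorted(marks)}")
    if tissues is None:
        tissues = [""] * len(fragment_sets)
    lengths_kb = np.asarray([(iv.end - iv.start) / 1000.0 for iv in loci])
    values = np.zeros((len(loci), len(fragment_sets)))
    for j, fs in enumerate(fragment_sets):
        counts = count_fragments_bulk(loci, fs, min_bp=min_bp)
        values[:, j] = counts / (lengths_kb * fs.total_mapped / 1e6)
    return SignalMatrix(
        loci=list(loci),
        samples=[(fs.sample_id, t) for fs, t in zip(fragment_sets, tissues)],
        values=values,
        library_sizes=np.asarray([fs.total_mapped for fs in fragment_sets]),
    )


def fold_change(tumor: float, native: float, pseudocount: float = 0.5) -> float:
    """(tumor + c) / (native + c); +inf sentinel when the denominator is 0."""
    if tumor < 0 or native < 0:
        raise ValueError("signal values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = native + pseudocount
    if denom == 0:
        return math.inf
    return (tumor + pseudocount) / denom


def summarize_group_signal(
    matrix: SignalMatrix,
    locus_groups: Mapping[str, Sequence[GenomicInterval]],
    tissue: str | None = None,
) -> pd.DataFrame:
    """Median and quartiles of per-locus mean RPKM for each locus group.

    Per-locus means are taken across samples of ``tissue`` (all samples when
    None).  Loci in a group must be rows of the matrix.
    """
    pos = {iv.key(): i for i, iv in enumerate(matrix.loci)}
    if tissue is None:
        means = matrix.values.mean(axis=1)
    else:
        means = matrix.mean_by_tissue(tissue)
    rows = []
    for group, loci in locus_groups.items():
        if len(loci) == 0:
            raise ValueError(f"group {group!r} is empty")
        try:
            idx = [pos[iv.key()] for iv in loci]
        except KeyError as exc:
            raise ValueError(f"group {group!r} contains a locus not in the matrix") from exc
        vals = means[idx]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": group, "n": len(idx), "q1": q1, "median": med,
                     "q3": q3, "mean": float(vals.mean())})
    return pd.DataFrame(rows).set_index("group")
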