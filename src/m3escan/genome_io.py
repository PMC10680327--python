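"""Readers, writers and core record types for the genomic formats the pipeline touches.

Every coordinate held in memory is 0-based half-open (the BED convention).
GTF input, which is 1-based inclusive, is converted on read and back on
write, so the two conversions are mutual inverses.  Chromosome names are
taken verbatim; an optional ``chr_prefix`` mode harmonizes mixed-source
inputs ("add" / "strip" / "keep").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "Gene",
    "GeneModel",
    "FragmentSet",
    "SampleManifest",
    "Sample",
    "PatientPair",
    "Cohort",
    "read_peaks",
    "read_fragments",
    "read_gene_model",
    "write_gene_model",
    "write_intervals",
    "write_loci",
    "read_manifest",
    "write_manifest",
    "load_cohort",
]

MARKS = ("H3K27ac", "H3K4me3", "TF")
TISSUES = ("native", "tumor")


class ParseError(ValueError):
    """Malformed row in a genomic text format; the message names the line."""


def normalize_chrom(name: str, mode: str = "keep") -> str:
    if mode == "keep":
        return name
    if mode == "add":
        return name if name.startswith("chr") else "chr" + name
    if mode == "strip":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chr_prefix mode {mode!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def intervals_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays, sorted by start."""
    out: dict[str, list[list[int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    result = {}
    for chrom, (starts, ends) in out.items():
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        order = np.argsort(s, kind="stable")
        result[chrom] = (s[order], e[order])
    return result


@dataclass
class PeakSet:
    """Called peaks of one histone mark (or TF) in one sample."""

    sample_id: str
    mark: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        self.intervals = sort_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return intervals_by_chrom(self.intervals)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]        # 0-based half-open transcript span
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        s, e = self.span
        expected = s if self.strand == "+" else e - 1
        if self.tss != expected:
            raise ValueError(f"TSS of {self.gene_id} inconsistent with span/strand")
        for ex in self.exons:
            if ex.start < s or ex.end > e:
                raise ValueError(f"exon outside span for {self.gene_id}")


class GeneModel:
    """Gene annotation with a strand-aware TSS index for distance queries."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.span[0]))
        self._tss_index: dict[str, tuple[np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._tss_index[chrom] = (
                np.asarray([p[0] for p in pairs], dtype=np.int64),
                [p[1] for p in pairs],
            )

    def __len__(self) -> int:
        return len(self.genes)

    def tss_index(self, chrom: str) -> tuple[np.ndarray, list[str]] | None:
        return self._tss_index.get(chrom)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._tss_index)


class FragmentSet:
    """Aligned fragment intervals of one mark in one sample.

    ``total_mapped`` is the library size (all mapped fragments genome-wide);
    it may exceed the number of fragments carried here, which is why it is a
    separate field and the RPKM denominator.  Fragments are stored as
    per-chromosome coordinate arrays; :attr:`fragments` materializes interval
    objects on demand.
    """

    def __init__(
        self,
        sample_id: str,
        mark: str,
        fragments: Iterable[GenomicInterval] | None = None,
        total_mapped: int = 0,
        _arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    ):
        self.sample_id = sample_id
        self.mark = mark
        if _arrays is None:
            _arrays = intervals_by_chrom(list(fragments or []))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        n = 0
        for chrom, (starts, ends) in _arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            if starts.size and (starts.min() < 0 or (starts >= ends).any()):
                raise ValueError(f"invalid fragment coordinates on {chrom}")
            self._by_chrom[chrom] = (starts, ends, np.sort(ends))
            n += starts.size
        self.n_fragments = n
        self.total_mapped = int(total_mapped)
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0")
        if self.total_mapped < n:
            raise ValueError("total_mapped smaller than the number of fragments")

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        mark: str,
        arrays: dict[str, tuple[np.ndarray, np.ndarray]],
        total_mapped: int,
    ) -> "FragmentSet":
        return cls(sample_id, mark, total_mapped=total_mapped, _arrays=arrays)

    def __len__(self) -> int:
        return self.n_fragments

    @property
    def fragments(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._by_chrom):
            starts, ends, _ = self._by_chrom[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(starts, ends)
            )
        return out

    def index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chrom (starts_sorted, ends_by_start, ends_sorted) for counting."""
        return self._by_chrom


# ---------------------------------------------------------------------------
# peak / fragment readers


_FORMAT_COLUMNS = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}


def _parse_interval_line(
    line: str, lineno: int, fmt: str, chr_prefix: str
) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: fewer than 3 tab-separated columns")
    chrom = normalize_chrom(fields[0], chr_prefix)
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise ParseError(f"line {lineno}: invalid coordinates {start}-{end}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    if fmt in ("narrowPeak", "broadPeak") and len(fields) > 6:
        # column 7 is signalValue in the ENCODE peak formats
        score = float(fields[6])
    elif len(fields) > 4 and fields[4] != ".":
        score = float(fields[4])
    return GenomicInterval(chrom, start, end, name=name, score=score)


def _read_interval_file(
    path: str | Path, fmt: str, chr_prefix: str
) -> list[GenomicInterval]:
    if fmt not in _FORMAT_COLUMNS:
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_interval_line(line, lineno, fmt, chr_prefix))
    return intervals


def read_peaks(
    path: str | Path,
    format: str = "bed",
    sample_id: str = "",
    mark: str = "H3K27ac",
    chr_prefix: str = "keep",
) -> PeakSet:
    """Read a BED / narrowPeak / broadPeak file into a sorted :class:`PeakSet`.

    Comment, ``track`` and ``browser`` lines are skipped; a malformed row
    raises :class:`ParseError` naming the line number.
    """
    return PeakSet(sample_id, mark, _read_interval_file(path, format, chr_prefix))


def read_fragments(
    path: str | Path,
    total_mapped: int,
    sample_id: str = "",
    mark: str = "H3K27ac",
    chr_prefix: str = "keep",
) -> FragmentSet:
    """Read fragment intervals (BED) with an externally supplied library size."""
    return FragmentSet(
        sample_id, mark, _read_interval_file(path, "bed", chr_prefix), total_mapped
    )


# ---------------------------------------------------------------------------
# GTF


_GTF_COLS = [
    "chrom", "source", "feature", "start", "end",
    "score", "strand", "frame", "attributes",
]


def _gtf_attr(attrs: str, key: str) -> str | None:
    # attributes look like: gene_id "G1"; transcript_id "G1.T1";
    marker = key + ' "'
    i = attrs.find(marker)
    if i < 0:
        return None
    j = attrs.find('"', i + len(marker))
    return attrs[i + len(marker): j]


def read_gene_model(
    path: str | Path,
    chr_prefix: str = "keep",
    tss_anchor: str = "transcript",
) -> GeneModel:
    """Read a GTF into a :class:`GeneModel` (coordinates converted to 0-based).

    One TSS per gene: the 5' end of its longest transcript (``tss_anchor=
    "transcript"``, default) or of the annotated gene span when a ``gene``
    feature is present (``tss_anchor="gene"``).  Genes with no exon rows are
    skipped with a warning.
    """
    if tss_anchor not in ("transcript", "gene"):
        raise ValueError("tss_anchor must be 'transcript' or 'gene'")
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GTF_COLS, header=None,
        dtype={"chrom": str}, keep_default_na=False,
    )
    if df.empty:
        return GeneModel([])
    df = df[df["feature"].isin(["gene", "transcript", "exon"])].copy()
    df["gene_id"] = [_gtf_attr(a, "gene_id") for a in df["attributes"]]
    df["transcript_id"] = [_gtf_attr(a, "transcript_id") for a in df["attributes"]]
    # GTF is 1-based inclusive -> 0-based half-open
    df["start0"] = df["start"].astype(np.int64) - 1
    df["end0"] = df["end"].astype(np.int64)

    genes: list[Gene] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        exons = gdf[gdf["feature"] == "exon"]
        if exons.empty:
            warnings.warn(f"gene {gene_id} has no exons; skipped", stacklevel=2)
            continue
        chrom = normalize_chrom(str(gdf["chrom"].iloc[0]), chr_prefix)
        strand = str(gdf["strand"].iloc[0])

        tdf = gdf[gdf["feature"] == "transcript"]
        if tss_anchor == "gene" and (gdf["feature"] == "gene").any():
            grow = gdf[gdf["feature"] == "gene"].iloc[0]
            span = (int(grow["start0"]), int(grow["end0"]))
            chosen_exons = exons
        elif not tdf.empty:
            lengths = tdf["end0"] - tdf["start0"]
            trow = tdf.iloc[int(np.argmax(lengths.to_numpy()))]
            span = (int(trow["start0"]), int(trow["end0"]))
            tid = trow["transcript_id"]
            chosen_exons = exons[exons["transcript_id"] == tid]
            if chosen_exons.empty:
                chosen_exons = exons
        else:
            # no transcript rows: infer span from the exon envelope
            span = (int(exons["start0"].min()), int(exons["end0"].max()))
            chosen_exons = exons
        tss = span[0] if strand == "+" else span[1] - 1
        exon_ivs = tuple(
            GenomicInterval(chrom, int(r.start0), int(r.end0))
            for r in chosen_exons.itertuples()
        )
        genes.append(Gene(str(gene_id), chrom, strand, tss, span, exon_ivs))
    return GeneModel(genes)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write a GeneModel back to GTF (transcript + exon rows, 1-based)."""
    with open(path, "w") as fh:
        for g in model.genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            s, e = g.span
            fh.write(
                f"{g.chrom}\tm3escan\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tm3escan\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# writers


def write_intervals(
    intervals: Sequence[GenomicInterval], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write intervals as BED (name and score columns when present)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for iv in sort_intervals(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                row.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                row.append(repr(iv.score))
            fh.write("\t".join(row) + "\n")


_LOCI_TSV_COLUMNS = [
    "chrom", "start", "end", "direction", "recurrence",
    "p", "q", "fold_change", "class",
]


def write_loci(loci: Sequence, path: str | Path, format: str = "tsv",
               header_comment: str | None = None) -> None:
    """Write variant loci (or plain intervals) as BED or TSV.

    BED output round-trips through :func:`read_peaks`; TSV carries the full
    locus record (direction, recurrence, p, q, fold change, class).
    """
    if loci is None:
        raise ValueError("loci must not be None")
    if format == "bed":
        ivs = []
        for lo in loci:
            iv = lo if isinstance(lo, GenomicInterval) else lo.interval
            name = getattr(lo, "class_label", iv.name)
            ivs.append(replace(iv, name=name))
        write_intervals(ivs, path)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for lo in loci:
        if isinstance(lo, GenomicInterval):
            rows.append([lo.chrom, lo.start, lo.end, ".", ".", ".", ".", ".", "."])
        else:
            iv = lo.interval
            rows.append([
                iv.chrom, iv.start, iv.end, lo.direction, lo.recurrence,
                f"{lo.p_value:.6g}" if lo.p_value is not None else ".",
                f"{lo.q_value:.6g}" if lo.q_value is not None else ".",
                f"{lo.cohort_fc:.6g}" if lo.cohort_fc is not None else ".",
                lo.class_label or ".",
            ])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_LOCI_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# sample manifest and cohort loading


_MANIFEST_COLUMNS = [
    "patient_id", "tissue", "mark", "peak_path", "fragment_path", "total_mapped",
]


@dataclass
class SampleManifest:
    """Rows pairing native/tumor samples per patient, one row per (sample, mark)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.rows["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue values: {sorted(bad)}")
        k27 = self.rows[self.rows["mark"] == "H3K27ac"]
        for pid, sub in k27.groupby("patient_id"):
            if set(sub["tissue"]) != set(TISSUES):
                raise ValueError(
                    f"patient {pid} lacks both tissues for H3K27ac in manifest"
                )

    @property
    def patients(self) -> list[str]:
        return sorted(self.rows["patient_id"].unique())

    def validate_paths(self) -> None:
        for col in ("peak_path", "fragment_path"):
            for p in self.rows[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, sep="\t", index=False, columns=_MANIFEST_COLUMNS)


@dataclass
class Sample:
    """All data for one (patient, tissue): peaks and fragments per mark."""

    sample_id: str
    patient_id: str
    tissue: str
    peaks: dict[str, PeakSet]
    fragments: dict[str, FragmentSet]


@dataclass
class PatientPair:
    patient_id: str
    native: Sample
    tumor: Sample


@dataclass
class Cohort:
    """A paired native/tumor cohort held in memory."""

    pairs: list[PatientPair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def samples(self) -> list[Sample]:
        out = []
        for p in self.pairs:
            out.append(p.native)
            out.append(p.tumor)
        return out

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        keep = set(patient_ids)
        return Cohort([p for p in self.pairs if p.patient_id in keep])


def load_cohort(manifest: SampleManifest, chr_prefix: str = "keep") -> Cohort:
    """Materialize a :class:`Cohort` from manifest rows (reads every file)."""
    manifest.validate_paths()
    pairs = []
    for pid in manifest.patients:
        samples: dict[str, Sample] = {}
        for tissue in TISSUES:
            sub = manifest.rows[
                (manifest.rows["patient_id"] == pid)
                & (manifest.rows["tissue"] == tissue)
            ]
            if sub.empty:
                continue
            sid = f"{pid}_{tissue}"
            peaks, frags = {}, {}
            for row in sub.itertuples():
                peaks[row.mark] = read_peaks(
                    row.peak_path, "bed", sample_id=sid, mark=row.mark,
                    chr_prefix=chr_prefix,
                )
                frags[row.mark] = read_fragments(
                    row.fragment_path, int(row.total_mapped), sample_id=sid,
                    mark=row.mark, chr_prefix=chr_prefix,
                )
            samples[tissue] = Sample(sid, pid, tissue, peaks, frags)
        if set(samples) == set(TISSUES):
            pairs.append(PatientPair(pid, samples["native"], samples["tumor"]))
        else:
            warnings.warn(f"patient {pid} incomplete in manifest; dropped")
    return Cohort(pairs)
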