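"""Synthetic paired native/tumor ChIP-seq cohorts with planted ground truth.

The generator lays out a small genome (non-overlapping genes and enhancer
loci on a block grid, so every enhancer is TSS-distal by construction),
designates a configurable fraction of enhancers as m3Es (each receives an
overlapping TSS-distal H3K4me3 peak), plants gain/lost variant m3Es of
configurable fold change that recur across a configurable fraction of
pairs, and draws per-locus fragment counts from a negative-binomial noise
model.

Noise model: each (locus, patient, mark) carries a latent gamma activity
factor shared between the patient's native and tumor samples (patient-
specific enhancer activity); conditional counts are Poisson.  Marginally a
count is negative-binomial with mean ``base_rpkm_mean`` (scaled by locus
length and library size) and dispersion ``nb_dispersion`` (var = mu +
disp*mu^2); within a pair the biological factor cancels, so paired fold
changes are dominated by the planted effects rather than by the
overdispersion.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    Cohort,
    FragmentSet,
    Gene,
    GeneModel,
    GenomicInterval,
    PatientPair,
    PeakSet,
    Sample,
    SampleManifest,
    write_gene_model,
    write_intervals,
    write_manifest,
)
from .intervals import overlaps

__all__ = [
    "SimConfig",
    "PlantedLocus",
    "SyntheticTruth",
    "SimResult",
    "generate_genome",
    "generate_cohort",
    "score_recovery",
    "RecoveryScore",
    "write_bundle",
    "generate_expression",
    "plant_tf_peaks",
]

GAIN, LOST, NONE = "gain", "lost", "none"
_BLOCK_BP = 20_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the statistical structure of a paired tumor/normal
    cohort at desk scale: 20 patient pairs, 500 shared enhancer loci per
    sample of which 20% are m3Es, 50 gain and 20 lost variant m3Es planted
    at a true fold change of 4 (gain) or 1/4 (lost) recurring in 80% of
    pairs, 2% sporadic background perturbations, and negative-binomial
    counts at dispersion 0.3 around 30 RPKM.  The 3M-fragment library depth
    keeps per-enhancer counts in the regime where a true 2-fold change is
    reliably detectable (~100 fragments per kb-scale locus), as in a
    moderately sequenced ChIP library at this genome size.
    """

    seed: int = 0
    n_pairs: int = 20
    n_chroms: int = 4
    chrom_length_bp: int = 10_000_000
    n_genes: int = 400
    n_enhancers_per_sample: int = 500
    m3e_fraction: float = 0.2
    n_gain_vm3e: int = 50
    n_lost_vm3e: int = 20
    n_se_clusters: int = 4
    n_gain_vsel: int = 0
    effect_fc: float = 4.0
    recurrence_rate: float = 0.8
    background_variant_rate: float = 0.02
    nb_dispersion: float = 0.3
    base_rpkm_mean: float = 30.0
    library_size: int = 3_000_000
    jitter_frac: float = 0.10
    fragment_length_bp: int = 200
    h3k4me3_m3e_ratio: float = 2.0
    se_signal_boost: float = 8.0
    promoter_h3k4me3_fraction: float = 0.8
    promoter_h3k27ac_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_chroms < 1:
            raise ValueError("n_pairs and n_chroms must be positive")
        if not (0.0 < self.m3e_fraction <= 1.0):
            raise ValueError("m3e_fraction must lie in (0, 1]")
        if not (0.0 < self.recurrence_rate <= 1.0):
            raise ValueError("recurrence_rate must lie in (0, 1]")
        if self.effect_fc < 1.0:
            raise ValueError("effect_fc must be >= 1")
        if self.nb_dispersion < 0 or self.background_variant_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_variant_m3es > self.n_m3es:
            raise ValueError(
                f"{self.n_gain_vm3e}+{self.n_lost_vm3e} planted variant m3Es "
                f"exceed the {self.n_m3es} m3E loci implied by m3e_fraction"
            )
        if self.n_gain_vsel > self.n_se_clusters:
            raise ValueError("n_gain_vsel exceeds n_se_clusters")
        blocks_needed = (
            self.n_genes + self.n_enhancers_per_sample + self.n_se_clusters
        )
        if blocks_needed > self.total_blocks:
            raise ValueError(
                f"genome too small: need {blocks_needed} blocks of "
                f"{_BLOCK_BP} bp, have {self.total_blocks}"
            )

    @property
    def n_m3es(self) -> int:
        return round(self.m3e_fraction * self.n_enhancers_per_sample)

    @property
    def n_variant_m3es(self) -> int:
        return self.n_gain_vm3e + self.n_lost_vm3e

    @property
    def total_blocks(self) -> int:
        return self.n_chroms * (self.chrom_length_bp // _BLOCK_BP)


@dataclass(frozen=True)
class PlantedLocus:
    interval: GenomicInterval
    klass: str                      # TE | m3E | SE
    direction: str                  # gain | lost | none
    true_fc: float
    recurring_pairs: tuple[str, ...]


@dataclass
class SyntheticTruth:
    loci: list[PlantedLocus]

    def of(self, klass: str | None = None, variant_only: bool = False
           ) -> list[PlantedLocus]:
        out = self.loci
        if klass is not None:
            out = [p for p in out if p.klass == klass]
        if variant_only:
            out = [p for p in out if p.direction != NONE]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "class": p.klass,
                    "direction": p.direction,
                    "true_fc": p.true_fc,
                    "recurring_pairs": ",".join(p.recurring_pairs),
                }
                for p in self.loci
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    config: SimConfig
    genome: GeneModel
    cohort: Cohort
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome layout


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GeneModel, np.ndarray]:
    """Place non-overlapping genes on the block grid; returns the model and
    the shuffled block order (consumed further by :func:`generate_cohort`).

    Features live in the interior of 20-kb blocks with 4-kb margins, so any
    two features in different blocks are at least 8 kb apart and every
    enhancer block is TSS-distal even after boundary jitter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blocks_per_chrom = config.chrom_length_bp // _BLOCK_BP
    order = rng.permutation(config.total_blocks)
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        b = int(order[gi])
        chrom = _chrom_name(b // blocks_per_chrom)
        bstart = (b % blocks_per_chrom) * _BLOCK_BP
        lo, hi = bstart + 4000, bstart + _BLOCK_BP - 4000
        glen = int(rng.integers(2000, 8001))
        gstart = int(rng.integers(lo, hi - glen + 1))
        gend = gstart + glen
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        bounds = np.sort(rng.choice(np.arange(1, glen), 2 * n_exons, replace=False))
        exons = []
        for k in range(n_exons):
            s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
            if e > s:
                exons.append(GenomicInterval(chrom, gstart + s, gstart + e))
        exons.insert(0, GenomicInterval(chrom, gstart, gstart + 200))
        exons.append(GenomicInterval(chrom, gend - 200, gend))
        tss = gstart if strand == "+" else gend - 1
        genes.append(Gene(f"G{gi:04d}", chrom, strand, tss, (gstart, gend),
                          tuple(exons)))
    return GeneModel(genes), order


# ---------------------------------------------------------------------------
# cohort generation


def _place_locus_in_block(
    b: int, blocks_per_chrom: int, length: int, rng: np.random.Generator
) -> GenomicInterval:
    chrom = _chrom_name(b // blocks_per_chrom)
    bstart = (b % blocks_per_chrom) * _BLOCK_BP
    lo, hi = bstart + 4000, bstart + _BLOCK_BP - 4000
    s = int(rng.integers(lo, hi - length + 1))
    return GenomicInterval(chrom, s, s + length)


def generate_cohort(config: SimConfig) -> SimResult:
    """Generate the full paired cohort with planted ground truth.

    Deterministic given ``config.seed``: the same config yields identical
    peaks, fragments and truth on every call.
    """
    rng = np.random.default_rng(config.seed)
    genome, block_order = generate_genome(config, rng)
    blocks_per_chrom = config.chrom_length_bp // _BLOCK_BP

    # --- locus universe ---------------------------------------------------
    enh_blocks = block_order[config.n_genes:
                             config.n_genes + config.n_enhancers_per_sample]
    se_blocks = block_order[
        config.n_genes + config.n_enhancers_per_sample:
        config.n_genes + config.n_enhancers_per_sample + config.n_se_clusters
    ]
    enh_loci = [
        _place_locus_in_block(int(b), blocks_per_chrom,
                              int(rng.integers(600, 1401)), rng)
        for b in enh_blocks
    ]
    # SE clusters: three constituents 2 kb apart within one block
    se_constituents: list[list[GenomicInterval]] = []
    for b in se_blocks:
        chrom = _chrom_name(int(b) // blocks_per_chrom)
        bstart = (int(b) % blocks_per_chrom) * _BLOCK_BP
        cluster = [
            GenomicInterval(chrom, bstart + 4000 + 3000 * k,
                            bstart + 4000 + 3000 * k + 1000)
            for k in range(3)
        ]
        se_constituents.append(cluster)

    n_enh = len(enh_loci)
    m3e_idx = rng.choice(n_enh, size=config.n_m3es, replace=False)
    m3e_idx.sort()
    is_m3e = np.zeros(n_enh, dtype=bool)
    is_m3e[m3e_idx] = True

    variant_pick = rng.choice(m3e_idx, size=config.n_variant_m3es, replace=False)
    gain_idx = set(int(i) for i in variant_pick[: config.n_gain_vm3e])
    lost_idx = set(int(i) for i in variant_pick[config.n_gain_vm3e:])
    vsel_pick = rng.choice(config.n_se_clusters, size=config.n_gain_vsel,
                           replace=False) if config.n_se_clusters else np.array([])
    vsel_gain = set(int(i) for i in vsel_pick)

    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_pairs)]

    def draw_recurring() -> tuple[str, ...]:
        mask = rng.random(config.n_pairs) < config.recurrence_rate
        return tuple(pid for pid, m in zip(patient_ids, mask) if m)

    truth_loci: list[PlantedLocus] = []
    enh_direction = [NONE] * n_enh
    enh_fc = [1.0] * n_enh
    enh_recurring: list[tuple[str, ...]] = [()] * n_enh
    for i in range(n_enh):
        if i in gain_idx:
            enh_direction[i], enh_fc[i] = GAIN, config.effect_fc
            enh_recurring[i] = draw_recurring()
        elif i in lost_idx:
            enh_direction[i], enh_fc[i] = LOST, 1.0 / config.effect_fc
            enh_recurring[i] = draw_recurring()
        truth_loci.append(
            PlantedLocus(enh_loci[i], "m3E" if is_m3e[i] else "TE",
                         enh_direction[i], enh_fc[i], enh_recurring[i])
        )
    se_direction, se_recurring = [], []
    for c, cluster in enumerate(se_constituents):
        d = GAIN if c in vsel_gain else NONE
        rec = draw_recurring() if d == GAIN else ()
        se_direction.append(d)
        se_recurring.append(rec)
        envelope = GenomicInterval(cluster[0].chrom, cluster[0].start,
                                   cluster[-1].end)
        truth_loci.append(
            PlantedLocus(envelope, "SE", d,
                         config.effect_fc if d == GAIN else 1.0, rec)
        )

    # --- signal loci: (interval, mark -> base RPKM mean) ------------------
    # per-mark lists of (interval, base_mean, variant_kind, recurring_set)
    base = config.base_rpkm_mean
    me3_te_level = base / config.h3k4me3_m3e_ratio

    k27_loci: list[GenomicInterval] = []
    k27_mean: list[float] = []
    k27_dir: list[str] = []
    k27_rec: list[set[str]] = []
    me3_loci: list[GenomicInterval] = []
    me3_mean: list[float] = []
    me3_dir: list[str] = []
    me3_rec: list[set[str]] = []

    for i, iv in enumerate(enh_loci):
        k27_loci.append(iv)
        k27_mean.append(base)
        k27_dir.append(enh_direction[i])
        k27_rec.append(set(enh_recurring[i]))
        # H3K4me3 fragments over every enhancer; only m3Es get called peaks
        me3_loci.append(iv)
        me3_mean.append(base if is_m3e[i] else me3_te_level)
        me3_dir.append(enh_direction[i])
        me3_rec.append(set(enh_recurring[i]))
    for c, cluster in enumerate(se_constituents):
        for iv in cluster:
            k27_loci.append(iv)
            k27_mean.append(base * config.se_signal_boost)
            k27_dir.append(se_direction[c])
            k27_rec.append(set(se_recurring[c]))
    # promoter peaks / fragments
    prom_me3, prom_k27 = [], []
    for g in genome.genes:
        s = max(0, g.tss - 500)
        iv = GenomicInterval(g.chrom, s, s + 1000)
        if rng.random() < config.promoter_h3k4me3_fraction:
            prom_me3.append(iv)
            me3_loci.append(iv)
            me3_mean.append(base * 2)
            me3_dir.append(NONE)
            me3_rec.append(set())
        if rng.random() < config.promoter_h3k27ac_fraction:
            prom_k27.append(iv)
            k27_loci.append(iv)
            k27_mean.append(base)
            k27_dir.append(NONE)
            k27_rec.append(set())

    # --- per-sample counts and fragments ----------------------------------
    disp = config.nb_dispersion
    frag_len = config.fragment_length_bp

    def simulate_mark(
        loci: Sequence[GenomicInterval],
        means: Sequence[float],
        dirs: Sequence[str],
        recs: Sequence[set[str]],
        mark: str,
    ) -> dict[str, dict[str, FragmentSet]]:
        """sample_id -> FragmentSet for one mark, all pairs."""
        out: dict[str, dict[str, FragmentSet]] = {}
        n_loci = len(loci)
        lengths_kb = np.asarray([(iv.end - iv.start) / 1000.0 for iv in loci])
        mu_rpkm = np.asarray(means, dtype=float)
        chroms = np.asarray([iv.chrom for iv in loci])
        starts_arr = np.asarray([iv.start for iv in loci], dtype=np.int64)
        ends_arr = np.asarray([iv.end for iv in loci], dtype=np.int64)
        flens = np.minimum(frag_len, ends_arr - starts_arr)
        is_gain = np.asarray([d == GAIN for d in dirs])
        is_lost = np.asarray([d == LOST for d in dirs])
        rec_mat = np.zeros((n_loci, len(patient_ids)), dtype=bool)
        for i, r in enumerate(recs):
            for j, pid in enumerate(patient_ids):
                if pid in r:
                    rec_mat[i, j] = True
        for j, pid in enumerate(patient_ids):
            # latent biological activity shared by the patient's two tissues
            if disp > 0:
                latent = rng.gamma(1.0 / disp, disp, size=n_loci)
            else:
                latent = np.ones(n_loci)
            lib = {
                "native": int(config.library_size * rng.uniform(0.8, 1.2)),
                "tumor": int(config.library_size * rng.uniform(0.8, 1.2)),
            }
            effect = {"native": np.ones(n_loci), "tumor": np.ones(n_loci)}
            planted = rec_mat[:, j]
            effect["tumor"][is_gain & planted] = config.effect_fc
            effect["tumor"][is_lost & planted] = 1.0 / config.effect_fc
            # sporadic background perturbations (tumor or native, either way)
            bg = rng.random(n_loci) < config.background_variant_rate
            bg &= ~((is_gain | is_lost) & planted)
            bg_tissue = rng.random(n_loci) < 0.5
            bg_fc = np.where(rng.random(n_loci) < 0.5, config.effect_fc,
                             1.0 / config.effect_fc)
            effect["tumor"][bg & bg_tissue] = bg_fc[bg & bg_tissue]
            effect["native"][bg & ~bg_tissue] = bg_fc[bg & ~bg_tissue]
            for tissue in ("native", "tumor"):
                mu = (mu_rpkm * effect[tissue] * latent
                      * lengths_kb * lib[tissue] / 1e6)
                counts = rng.poisson(mu)
                lo = np.repeat(starts_arr, counts)
                hi = np.repeat(ends_arr - flens, counts) + 1
                fl = np.repeat(flens, counts)
                fstarts = rng.integers(lo, hi)
                fchroms = np.repeat(chroms, counts)
                packed = {}
                for chrom in np.unique(chroms):
                    m = fchroms == chrom
                    packed[str(chrom)] = (fstarts[m], fstarts[m] + fl[m])
                sid = f"{pid}_{tissue}"
                out.setdefault(pid, {})[tissue] = FragmentSet.from_arrays(
                    sid, mark, packed, lib[tissue]
                )
        return out

    k27_frags = simulate_mark(k27_loci, k27_mean, k27_dir, k27_rec, "H3K27ac")
    me3_frags = simulate_mark(me3_loci, me3_mean, me3_dir, me3_rec, "H3K4me3")

    # --- per-sample peak files (boundary-jittered) -------------------------
    def jitter(iv: GenomicInterval) -> GenomicInterval:
        if config.jitter_frac == 0:
            return iv
        w = iv.end - iv.start
        lim = max(1, int(config.jitter_frac * w))
        ds = int(rng.integers(-lim, lim + 1))
        de = int(rng.integers(-lim, lim + 1))
        s, e = iv.start + ds, iv.end + de
        if e <= s:
            e = s + 1
        return GenomicInterval(iv.chrom, max(0, s), e)

    k27_peak_universe = enh_loci + [iv for cl in se_constituents for iv in cl] \
        + prom_k27
    me3_peak_universe = [enh_loci[int(i)] for i in m3e_idx] + prom_me3

    pairs: list[PatientPair] = []
    for pid in patient_ids:
        samples = {}
        for tissue in ("native", "tumor"):
            sid = f"{pid}_{tissue}"
            peaks = {
                "H3K27ac": PeakSet(sid, "H3K27ac",
                                   [jitter(iv) for iv in k27_peak_universe]),
                "H3K4me3": PeakSet(sid, "H3K4me3",
                                   [jitter(iv) for iv in me3_peak_universe]),
            }
            frags = {
                "H3K27ac": k27_frags[pid][tissue],
                "H3K4me3": me3_frags[pid][tissue],
            }
            samples[tissue] = Sample(sid, pid, tissue, peaks, frags)
        pairs.append(PatientPair(pid, samples["native"], samples["tumor"]))

    return SimResult(config, genome, Cohort(pairs), SyntheticTruth(truth_loci))


# ---------------------------------------------------------------------------
# recovery scoring


_CLASS_MATCH = {"Vm3E": {"m3E"}, "VSEL": {"SE"}, "VEL": {"TE", "m3E", "SE"}}


@dataclass
class RecoveryScore:
    sensitivity: float
    precision: float
    n_planted: int
    n_called: int
    n_recovered: int
    n_matched_calls: int
    confusion: dict
    zero_calls: bool = False


def score_recovery(
    called: Sequence, truth: SyntheticTruth, min_bp: int = 1
) -> RecoveryScore:
    """Score called variant loci against the planted truth.

    A planted variant locus is recovered iff at least one call of matching
    class and direction overlaps it by >= min_bp; sensitivity is
    recovered/planted and precision matched/called.  With zero calls,
    precision is reported as 1.0 and flagged.
    """
    classes = {getattr(c, "class_label", None) for c in called}
    classes.discard(None)
    if len(classes) > 1:
        raise ValueError(f"called loci mix classes: {sorted(classes)}")
    if called and not classes:
        raise ValueError("called loci carry no class label")
    truth_classes = _CLASS_MATCH.get(next(iter(classes)), None) if classes else None

    planted = [
        p for p in truth.loci
        if p.direction != NONE
        and (truth_classes is None or p.klass in truth_classes)
    ]
    n_rec = 0
    matched_calls: set[int] = set()
    confusion: dict[str, int] = {"recovered": 0, "missed": 0}
    for p in planted:
        hit = False
        for j, c in enumerate(called):
            if c.direction == p.direction and overlaps(c.interval, p.interval,
                                                       min_bp):
                hit = True
                matched_calls.add(j)
        if hit:
            n_rec += 1
            confusion["recovered"] += 1
        else:
            confusion["missed"] += 1
    # calls overlapping any planted variant (either direction) count as
    # matched for precision only when the direction agrees
    n_matched = len(matched_calls)
    sens = n_rec / len(planted) if planted else 1.0
    if called:
        prec = n_matched / len(called)
        zero = False
    else:
        prec, zero = 1.0, True
    confusion["false_calls"] = len(called) - n_matched
    return RecoveryScore(sens, prec, len(planted), len(called), n_rec,
                         n_matched, confusion, zero)


# ---------------------------------------------------------------------------
# bundle writing and auxiliary generators


def write_bundle(result: SimResult, outdir: str | Path) -> SampleManifest:
    """Write GTF, per-sample peak/fragment BEDs, manifest and truth table.

    The returned manifest points at the written files, so the bundle can be
    re-loaded with :func:`m3escan.genome_io.load_cohort`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_model(result.genome, outdir / "genes.gtf")
    result.truth.to_tsv(outdir / "truth.tsv")
    rows = []
    for pair in result.cohort.pairs:
        for sample in (pair.native, pair.tumor):
            for mark in ("H3K27ac", "H3K4me3"):
                peak_path = outdir / f"{sample.sample_id}_{mark}_peaks.bed"
                frag_path = outdir / f"{sample.sample_id}_{mark}_fragments.bed"
                write_intervals(sample.peaks[mark].intervals, peak_path)
                write_intervals(sample.fragments[mark].fragments, frag_path)
                rows.append({
                    "patient_id": pair.patient_id,
                    "tissue": sample.tissue,
                    "mark": mark,
                    "peak_path": str(peak_path),
                    "fragment_path": str(frag_path),
                    "total_mapped": sample.fragments[mark].total_mapped,
                })
    manifest = SampleManifest(pd.DataFrame(rows))
    write_manifest(manifest, outdir / "manifest.tsv")
    return manifest


def generate_expression(
    genome: GeneModel,
    truth: SyntheticTruth,
    n_samples: int = 6,
    medians: dict[str, float] | None = None,
    sigma: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic FPKM table whose target genes of SE > m3E > TE loci differ in
    median expression (defaults 20 / 10 / 5 FPKM, log-normal spread).

    Target gene of a planted locus = nearest TSS.  Genes targeted by no
    locus get the TE median.
    """
    if medians is None:
        medians = {"TE": 5.0, "m3E": 10.0, "SE": 20.0}
    rng = np.random.default_rng(seed)
    gene_class: dict[str, str] = {}
    priority = {"TE": 0, "m3E": 1, "SE": 2}
    for p in truth.loci:
        idx = genome.tss_index(p.interval.chrom)
        if idx is None:
            continue
        tss, gene_ids = idx
        g = gene_ids[int(np.argmin(np.abs(tss - p.interval.midpoint)))]
        if g not in gene_class or priority[p.klass] > priority[gene_class[g]]:
            gene_class[g] = p.klass
    rows, index = [], []
    for g in genome.genes:
        med = medians[gene_class.get(g.gene_id, "TE")]
        vals = med * rng.lognormal(0.0, sigma, size=n_samples)
        rows.append(vals)
        index.append(g.gene_id)
    return pd.DataFrame(
        rows, index=index,
        columns=[f"S{i + 1}" for i in range(n_samples)],
    )


def plant_tf_peaks(
    loci: Sequence[GenomicInterval],
    fraction: float,
    seed: int = 0,
    width: int = 400,
    sample_id: str = "tf",
) -> PeakSet:
    """TF peaks covering a given fraction of ``loci`` (centered, fixed width)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = round(fraction * len(loci))
    chosen = rng.choice(len(loci), size=k, replace=False)
    peaks = []
    for i in chosen:
        iv = loci[int(i)]
        mid = (iv.start + iv.end) // 2
        s = max(0, mid - width // 2)
        peaks.append(GenomicInterval(iv.chrom, s, s + width))
    return PeakSet(sample_id, "TF", peaks)
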