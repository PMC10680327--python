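import numpy as np
import pytest

from m3escan.genome_io import (
    Cohort,
    FragmentSet,
    Gene,
    GeneModel,
    GenomicInterval,
    PatientPair,
    PeakSet,
    Sample,
)
from m3escan.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_result():
    """The default synthetic study cohort (20 pairs), shared across tests."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast desk-scale configuration for file-based / end-to-end tests."""
    return SimConfig(
        seed=3, n_pairs=6, n_chroms=2, chrom_length_bp=3_000_000,
        n_genes=100, n_enhancers_per_sample=120, m3e_fraction=0.25,
        n_gain_vm3e=12, n_lost_vm3e=5, n_se_clusters=3,
    )


@pytest.fixture(scope="session")
def small_result(small_sim_config):
    return generate_cohort(small_sim_config)


@pytest.fixture
def simple_genome():
    """Two genes on chr1 (TSS at 10000 '+' and 50000 '-'), one on chr2."""
    def mk(gene_id, chrom, strand, start, end):
        tss = start if strand == "+" else end - 1
        exons = (
            GenomicInterval(chrom, start, start + 300),
            GenomicInterval(chrom, end - 300, end),
        )
        return Gene(gene_id, chrom, strand, tss, (start, end), exons)

    return GeneModel([
        mk("GA", "chr1", "+", 10000, 14000),
        mk("GB", "chr1", "-", 46000, 50001),
        mk("GC", "chr2", "+", 30000, 35000),
    ])


def build_counts_cohort(locus, native_counts, tumor_counts, library_size=1_000_000):
    """A minimal in-memory cohort with one H3K27ac locus and exact per-pair
    fragment counts, so RPKM equals the count (1 kb locus, 1e6 library)."""
    assert len(native_counts) == len(tumor_counts)
    pairs = []
    flen = 200
    mid = (locus.start + locus.end) // 2
    for i, (nc, tc) in enumerate(zip(native_counts, tumor_counts)):
        pid = f"P{i + 1:02d}"
        samples = {}
        for tissue, c in (("native", nc), ("tumor", tc)):
            sid = f"{pid}_{tissue}"
            starts = np.full(c, mid - flen // 2, dtype=np.int64)
            frags = FragmentSet.from_arrays(
                sid, "H3K27ac",
                {locus.chrom: (starts, starts + flen)} if c else {},
                library_size,
            )
            peaks = {"H3K27ac": PeakSet(sid, "H3K27ac", [locus]),
                     "H3K4me3": PeakSet(sid, "H3K4me3", [locus])}
            samples[tissue] = Sample(sid, pid, tissue, peaks,
                                     {"H3K27ac": frags, "H3K4me3": frags})
        pairs.append(PatientPair(pid, samples["native"], samples["tumor"]))
    return Cohort(pairs)


@pytest.fixture
def counts_cohort_builder():
    return build_counts_cohort
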