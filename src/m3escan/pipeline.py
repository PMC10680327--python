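"""End-to-end orchestration: QC -> enhancers -> m3Es -> SEs -> quantification
-> VEL/Vm3E/VSEL -> summaries, with reproducible, hash-stamped outputs.

Default thresholds are the published analysis parameters: 2 kb TSS
exclusion, per-pair fold change >= 2, cohort fold change 1.5 for Vm3Es,
significant-percentage cutoff 0.90 with q < 0.05 for VEL recurrence
selection, fixed recurrence 5 for VSELs, ROSE-style 12.5 kb stitching, and
a minimum of 5000 peaks per mark for sample QC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort_analysis as ca
from . import enhancers as enh_mod
from . import variants as var_mod
from .genome_io import (
    read_gene_model,
    read_manifest,
    load_cohort,
    write_loci,
    write_intervals,
)
from .quant import build_signal_matrix
from .simulate import SimConfig, generate_cohort, write_bundle

__all__ = ["PipelineConfig", "run_full", "simulate"]

log = logging.getLogger("m3escan")


@dataclass
class PipelineConfig:
    manifest_path: str = ""
    gtf_path: str = ""
    output_dir: str = "m3escan_out"
    seed: int = 0
    tss_exclusion_bp: int = 2000
    pair_fc: float = 2.0
    cohort_fc: float = 1.5
    vel_fc: float = 2.0
    significant_fraction_cutoff: float = 0.90
    q_cutoff: float = 0.05
    vsel_recurrence: int = 5
    stitch_bp: int = 12500
    pseudocount: float = 0.5
    min_peaks: int = 5000
    chr_prefix: str = "keep"

    def config_hash(self) -> str:
        """Hash of the analysis parameters and inputs (not the output path)."""
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a JSON config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_full(config: PipelineConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Result files (all stamped with the config hash):
    qc_report.tsv, fractions.tsv, genomic_distribution.tsv,
    m3e_merged.bed, {vel,vm3e,vsel}_{gain,lost}.tsv and the run log.
    Re-running with identical inputs and config is bit-identical apart from
    run.log timings.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"config_hash={chash}"
    log_lines = [f"config_hash\t{chash}"]

    def stage(name: str, start: float) -> None:
        log_lines.append(f"{name}\t{time.time() - start:.2f}s")
        log.info("stage %s done in %.2fs", name, time.time() - start)

    try:
        t = time.time()
        manifest = read_manifest(config.manifest_path)
        manifest.validate_paths()
        model = read_gene_model(config.gtf_path, chr_prefix=config.chr_prefix)
        stage("load", t)

        t = time.time()
        qc = enh_mod.qc_filter_samples(manifest, config.min_peaks)
        with open(outdir / "qc_report.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            qc.rows.to_csv(fh, sep="\t", index=False)
        cohort = load_cohort(manifest, config.chr_prefix).subset(
            qc.included_patients
        )
        if cohort.n_pairs == 0:
            raise RuntimeError("stage qc: no patient pairs pass QC")
        stage("qc", t)

        t = time.time()
        m3e_sets, distal_me3, all_me3 = {}, {}, {}
        for s in cohort.samples:
            try:
                enh = enh_mod.call_active_enhancers(
                    s.peaks["H3K27ac"], model, config.tss_exclusion_bp
                )
                enh, dme3 = enh_mod.call_m3es(
                    enh, s.peaks["H3K4me3"], model, config.tss_exclusion_bp
                )
            except Exception as exc:  # noqa: BLE001 - annotate failing sample
                raise RuntimeError(
                    f"stage enhancers failed for sample {s.sample_id}"
                ) from exc
            m3e_sets[s.sample_id] = enh
            distal_me3[s.sample_id] = dme3
            all_me3[s.sample_id] = s.peaks["H3K4me3"]
        stage("enhancers", t)

        t = time.time()
        fr = ca.fraction_report(m3e_sets, distal_me3, all_me3)
        with open(outdir / "fractions.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            fr.to_csv(fh, sep="\t", index=False)

        from .intervals import merge

        all_m3e_ivs = [
            e.interval for es in m3e_sets.values()
            for e in es.of_class(enh_mod.M3E)
        ]
        merged_m3es = [m.interval for m in merge(all_m3e_ivs)]
        write_intervals(merged_m3es, outdir / "m3e_merged.bed",
                        header_comment=stamp)
        dist = enh_mod.annotate_genomic_distribution(
            merged_m3es, model, config.tss_exclusion_bp
        )
        with open(outdir / "genomic_distribution.tsv", "w") as fh:
            fh.write(f"# {stamp}\ncategory\tcount\n")
            for cat in enh_mod.CATEGORIES:
                fh.write(f"{cat}\t{dist[cat]}\n")
        stage("summaries", t)

        t = time.time()
        vels = var_mod.call_vels(
            cohort, model, config.vel_fc, config.significant_fraction_cutoff,
            config.q_cutoff, config.tss_exclusion_bp, config.pseudocount,
        )
        vm3es = var_mod.call_vm3es(
            cohort, model, config.pair_fc, config.cohort_fc,
            config.tss_exclusion_bp, config.pseudocount, m3e_sets=m3e_sets,
        )
        vsels = var_mod.call_vsels(
            cohort, model, config.vsel_recurrence, config.vel_fc,
            config.tss_exclusion_bp, config.stitch_bp, config.pseudocount,
        )
        for name, calls in (("vel", vels), ("vm3e", vm3es), ("vsel", vsels)):
            for direction in (var_mod.GAIN, var_mod.LOST):
                sub = [v for v in calls if v.direction == direction]
                write_loci(sub, outdir / f"{name}_{direction}.tsv", "tsv",
                           header_comment=stamp)
        stage("variants", t)

        t = time.time()
        if len(vm3es) >= 2 and cohort.n_pairs >= 1:
            frag_sets, tissues = [], []
            for p in cohort.pairs:
                for s in (p.native, p.tumor):
                    frag_sets.append(s.fragments["H3K27ac"])
                    tissues.append(s.tissue)
            mat = build_signal_matrix(
                [v.interval for v in vm3es], frag_sets, tissues
            )
            pca = ca.pca_classification(mat)
            with open(outdir / "pca_coordinates.tsv", "w") as fh:
                fh.write(f"# {stamp}\n")
                pca.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        stage("pca", t)
    finally:
        log_lines.append(f"total\t{time.time() - t0:.2f}s")
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return outdir


def simulate(config: SimConfig, outdir: str | Path) -> Path:
    """Generate a synthetic input bundle on disk (delegates to the cohort
    generator); returns the bundle directory containing manifest.tsv."""
    result = generate_cohort(config)
    write_bundle(result, outdir)
    return Path(outdir)
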