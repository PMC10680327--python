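# m3escan

Discovery of **H3K4me3-enriched enhancers (m3Es)** and recurrent **variant
enhancer loci** from paired native/tumor ChIP-seq cohorts.

Classically enhancers carry H3K4me1/2 while H3K4me3 marks promoters, but a
subset of active enhancers is H3K4me3-enriched, and these behave
differently from typical enhancers in tumors. Given per-sample H3K27ac and
H3K4me3 peak calls plus aligned fragments for a cohort of paired
native/tumor tissue samples, `m3escan`:

1. **QC-filters samples** by peak count (failing samples take their pair
   partner with them, so the cohort stays paired);
2. calls **active enhancers** — H3K27ac peaks whose every base lies > 2 kb
   from all annotated TSS;
3. classifies **m3Es** — enhancers overlapping a TSS-distal H3K4me3 peak;
4. stitches **super enhancers** (SEs) ROSE-style (12.5 kb stitching, rank
   vs. summed-signal curve, slope-1 tangent cutoff);
5. quantifies per-locus signal as **RPKM** = fragments / (kb x million
   mapped);
6. calls recurrent variant loci across the cohort:
   - **VELs**: per-pair H3K27ac fold change FC >= 2 (gain or lost), merged
     cohort-wide per direction; each merged locus gets a recurrence k (the
     number of distinct patients calling it), an exact binomial tail
     p-value P(X >= k), X ~ Bin(n, p0) against the cohort-estimated null
     call rate p0, and a Benjamini-Hochberg q-value; the recurrence
     threshold is the smallest r at which >= 90% of loci with k >= r have
     q < 0.05;
   - **Vm3Es**: m3Es with at least one per-pair FC >= 2 supporter *and*
     cohort mean-RPKM fold change >= 1.5 (gain) or <= 1/1.5 (lost);
   - **VSELs**: the VEL procedure on SE loci with a fixed recurrence
     threshold of 5;
7. summarizes: m3E fractions, genomic distribution, nearest-TSS target
   genes, expression comparison (Mann-Whitney), PCA sample classification
   on log2(RPKM+1) over Vm3E loci, and TF-occupancy trends.

A **synthetic-cohort generator** (`m3escan.simulate`) produces complete
paired cohorts — genome GTF, per-sample peak and fragment BEDs, manifest —
with planted m3Es, variant loci of known fold change and recurrence, and
negative-binomial count noise, so every stage is testable without any
external data.

## Worked example

```python
from m3escan import SimConfig, generate_cohort, call_vm3es, score_recovery

res = generate_cohort(SimConfig(seed=7))        # 20 pairs, 50 gain + 20 lost planted
calls = call_vm3es(res.cohort, res.genome)
score = score_recovery(calls, res.truth)
gains = sum(1 for v in calls if v.direction == "gain")
print(f"called {len(calls)} Vm3Es ({gains} gain, {len(calls) - gains} lost)")
print(f"sensitivity {score.sensitivity:.3f}, precision {score.precision:.3f}")
```

prints

```
called 69 Vm3Es (50 gain, 19 lost)
sensitivity 0.986, precision 1.000
```

i.e. of the 70 planted variant m3Es, 69 are recovered with no false calls;
the one miss is a planted lost locus whose cohort mean fold change (0.88)
stays above the 1/1.5 lost threshold — a few high-activity patients in
which the locus does not recur dominate the cohort mean. Each returned
`VariantLocus` carries its coordinates, direction, recurrence k/n, p- and
q-value, and cohort fold change.

The same analysis runs from the shell on a file bundle:

```bash
m3escan simulate --seed 7 --out bundle/
m3escan run-all --manifest bundle/manifest.tsv --gtf bundle/genes.gtf \
    --min-peaks 50 --out results/
```

which writes `qc_report.tsv`, `fractions.tsv`, `genomic_distribution.tsv`,
`m3e_merged.bed`, `{vel,vm3e,vsel}_{gain,lost}.tsv` and
`pca_coordinates.tsv`, every file stamped with the configuration hash;
re-running with the same inputs is bit-identical.

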