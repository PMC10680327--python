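# Methods

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED convention); GTF
input (1-based inclusive) is converted on read and back on write, so the
two conversions are mutual inverses. Two intervals that merely abut do not
overlap. The TSS of a gene is the 5' end of its longest transcript (a
`tss_anchor="gene"` option uses the annotated gene span instead, for
annotations whose gene feature is authoritative). Distance from a TSS to
an interval is the strand-ignorant coordinate difference between the TSS
point and the nearest contained base, and 0 when the point lies inside.

## Enhancer and m3E calling

An **active enhancer** is an H3K27ac peak whose *every base* lies more
than `tss_exclusion_bp` (default 2000) from all TSS. We use the whole-peak
rule rather than a summit rule because it maximally excludes promoter
H3K4me3 bleed, which is the point of the exclusion; the choice matters
only for peaks straddling the 2 kb boundary.

An **m3E** is an enhancer overlapping (>= 1 bp, configurable) at least one
H3K4me3 peak that is itself TSS-distal under the same rule. The m3E keeps
the enhancer's own (H3K27ac) coordinates; the H3K4me3 peak only licenses
the label. Everywhere the analysis says "overlap" without quantification
we use the weakest reading, >= 1 bp.

**Super enhancers** are called ROSE-style because no more specific recipe
is standard: constituents within `stitch_bp` (default 12 500) are
stitched; candidates are ranked by summed constituent H3K27ac RPKM; with
both the rank axis and the signal axis min-max scaled, the super enhancers
are the candidates strictly above the first point where the discrete slope
of the curve exceeds 1. Ties are broken by coordinate, so the call is
deterministic. A flat curve or fewer than three candidates yields no SEs.

**Genomic distribution** assigns each locus exactly one of promoter >
exon > intron > intergenic by any-overlap priority ("promoter" = within
the TSS-exclusion distance of a TSS). The priority order is a convention;
counts always partition the input.

**Sample QC** excludes a sample whose peak count for any mark falls below
`min_peaks` (default 5000 per mark, the order of magnitude separating
usable from failed libraries in tissue ChIP-seq; there is no canonical
value). A failing sample removes its pair partner too, and an unpaired
patient is dropped with a warning, so downstream stages only see complete
pairs.

## Signal quantification

Per-locus signal is RPKM: fragments overlapping the locus by >= 1 bp,
divided by locus length in kb and library size in millions. Fold changes
are pseudocount-stabilized ratios (tumor + c)/(native + c) with c = 0.5
RPKM, so zero-signal loci stay finite and a locus equal in both tissues
has FC 1 for any c; c = 0 is allowed and yields an infinity sentinel that
callers exclude.

## Variant-locus statistics

Per pair, a tested locus is called **gain** when FC(tumor/native) >= 2 and
**lost** when FC(native/tumor) >= 2 (threshold inclusive; a threshold > 1
makes the directions exclusive). Same-direction calls are merged
cohort-wide into union envelopes; the **recurrence** k of a merged locus
counts distinct patients, never calls.

The significance of recurrence k out of n pairs is the exact binomial
upper tail P(X >= k), X ~ Bin(n, p0), with the null rate p0 estimated as
(total per-pair variant calls)/(total per-pair tested loci), clamped away
from {0, 1} by one count. This is the simplest defensible null for "how
often would k of n pairs agree by chance"; the `NullModel` is a value
object, and `permutation_null` (tissue labels shuffled within patients)
provides an independent estimate for cross-checking. p-values are
Benjamini-Hochberg adjusted per direction.

For **VELs** the recurrence threshold per direction is the smallest r such
that among loci with recurrence >= r (inclusive; an exclusive switch
exists because ">" vs ">=" is a genuine convention choice) at least 90%
have q < 0.05. If no r qualifies the direction returns empty with a
warning. Cohorts of fewer than 3 pairs are refused.

For **Vm3Es** the two published conditions are composed conjunctively,
since nothing specifies their combination: a merged cohort m3E locus is a
gain Vm3E when its cohort mean-RPKM fold change (mean over tumor samples
vs. mean over native samples) is >= 1.5 *and* at least one per-pair
FC >= 2 gain call overlaps it; lost is symmetric with mean-FC <= 1/1.5.
Recurrence, p and q are recorded on the output for reporting; an optional
`min_recurrence` filter exists but is off by default. Note that the
recorded q-values are computed against a null rate estimated from the m3E
universe itself, which in a heavily-planted synthetic cohort is dominated
by true variants; they are reported, not used for calling.

**VSELs** run the VEL machinery on per-sample super-enhancer loci with a
fixed recurrence threshold (default 5) instead of data-driven selection.

## Downstream summaries

Target genes are the k nearest TSS (by distance from the locus midpoint)
within 500 kb, ties broken by distance then gene id; k up to 3 is
supported since an enhancer can plausibly regulate several proximal
genes. Expression comparison between target-gene sets uses the two-sided
Mann-Whitney test, exact for groups of <= 8 (deterministic small-sample
behaviour), normal approximation above. PCA operates on log2(RPKM+1) with
per-locus centering and no variance scaling — the transform switches are
exposed because no canonical choice exists; each component's sign is fixed
by making its largest-magnitude loading positive, so coordinates are
deterministic and invariant (bar sign) under sample reordering.

## Synthetic cohort generator

The generator emulates the statistical structure a paired tumor/normal
enhancer cohort presents to the caller, at desk scale.

**Layout.** The genome is a grid of 20-kb blocks; genes, enhancer loci and
SE clusters occupy the 12-kb interiors of distinct blocks, so every
enhancer is TSS-distal by construction (>= 8 kb from any feature in a
neighbouring block) and distinct truth loci never fuse during merging,
even after boundary jitter. Each sample receives a peak at every universe
locus with boundaries jittered by +-10% of width, emulating peak-caller
variability. A configurable fraction of genes also gets promoter H3K4me3
(80%) and H3K27ac (50%) peaks so the distal filter is genuinely exercised.

**Classes and effects.** `m3e_fraction` of enhancers are m3Es (each gets
an overlapping distal H3K4me3 peak); planted gain/lost variant m3Es are
drawn from the m3E pool (validated to fit), and each recurs independently
per pair with probability `recurrence_rate` (0.8). In a recurring pair the
tumor signal is multiplied by `effect_fc` (gain, default 4) or divided by
it (lost). SE clusters are three constituents 3 kb apart with an 8x signal
boost. Sporadic background perturbations hit each non-recurring
(locus, pair) at `background_variant_rate` (0.02), in a random tissue and
direction, at the same effect size.

**Noise.** Each (locus, patient, mark) carries a latent gamma activity
factor (shape 1/`nb_dispersion`, mean 1) shared between the patient's
native and tumor samples; fragment counts are conditionally Poisson with
mean = RPKM-level x locus kb x library size / 1e6. Marginally every count
is exactly negative-binomial with the configured mean and dispersion
(var = mu + 0.3 mu^2); the within-pair sharing models the fact that
enhancer activity is a property of the patient's tissue, so paired fold
changes reflect planted effects plus Poisson noise rather than the full
biological overdispersion. A consequence worth knowing: the cohort mean FC
weights patients by activity, so a planted locus can occasionally be
missed when high-activity patients happen to be the non-recurring ones.

**Depth.** The default library (3 M fragments over a 40 Mb genome) puts
~100 fragments on a kb-scale locus, the regime in which a true 2-fold
change is reliably detectable and noise-only FC >= 2 calls are rare
(~0.3%), comparable per-locus to a moderately sequenced real ChIP library.
Fragments are 200 bp and placed uniformly inside their locus.

Everything is deterministic given the seed; the same config yields
byte-identical bundles.

**What the generator does not model:** correlated patient structure
(recurrence is independent Bernoulli), copy-number events under fold
changes, mappability/GC bias, read-level artifacts, and peak
presence/absence variation between samples (every sample has a peak at
every universe locus). Passing recovery tests therefore demonstrates the
correctness of the calling logic and statistics under the stated noise
model, not robustness to all failure modes of real tissue ChIP-seq.

## Problem sizes

The default study conditions are 20 pairs, 500 enhancer loci per sample
(20% m3Es, of which 50 gain + 20 lost planted variants), 4 chromosomes of
10 Mb, 400 genes. The test suite and acceptance script run cohorts at
these sizes (and smaller ones for file-based round trips), chosen so each
cohort generates and analyses in a few seconds on one core.

## Known limitations

- The binomial recurrence null treats loci as exchangeable and pairs as
  independent; clustered patients or locus-specific call rates would
  inflate significance.
- Fragment counting is overlap-based (>= 1 bp), not midpoint-based;
  at realistic fragment/locus size ratios the difference is negligible.
- Cohort fold change is a ratio of means, which weights high-signal
  samples more than a mean of ratios would; this matches the published
  description ("mean signal ... fold change") but is a choice.
- "Relative signal" figures are reproduced as per-locus mean RPKM without
  further scaling; any per-figure normalization applied upstream elsewhere
  is not modelled.
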