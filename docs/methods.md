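# Methods

## Scope and design

`archatac` analyses bulk accessibility (ATAC-style tagmentation), bulk
ssDNA/transcription (KAS-style enrichment) and single-molecule methylation
footprinting (NOMe-seq/dSMF-style) on genomes composed of several replicons
at unequal per-cell copy number. Every statistic is computed on 0-based
half-open coordinates; strand-aware operations orient offsets so that
negative values are upstream of the TSS (the TSS of a `-` strand gene is
`end - 1`).

The package also contains a synthetic data generator. Its defaults define
the study conditions under which the estimators are validated; they are not
fit to data but chosen to reproduce the qualitative structure the analyses
assume (below).

## Synthetic genome and assay models

**Genome.** Five replicons of 400 / 150 / 120 / 30 / 6 kb at copy numbers
1 / 1 / 1 / 1.4 / 26 — a ~10x scale-down of a haloarchaeal genome
(main chromosome plus four plasmids, the smallest highly polyploid) chosen
for desk-scale runtimes. The fractional 1.4 ploidy enters only as the mean
per-cell copy number, which is all coverage depends on. ~200
non-overlapping genes are packed proportionally to replicon length;
adjacent co-oriented runs form operons (sizes 1–6, geometric-ish). One
CRISPR-like locus (20 x 30 bp tandem repeat + 35 bp spacers, with an
adjacent cas-like gene) is placed on the second replicon; the window
between array and cas gene is the dormant-condition ssDNA peak.

**Sequence/GC.** Base composition is genic GC 0.62, intergenic 0.58, with
eight 4-kb high-GC (0.75) patches on the main chromosome and AT-rich
(GC 0.42) promoter elements at TSS ± 100 bp, reflecting the AT-rich
TATA/BRE boxes of archaeal promoters. This composition makes the
accessibility-vs-GC anti-correlation partly biological (accessible
promoters are AT-rich) and partly technical (see GC bias), mirroring the
ambiguity of the real measurement.

**ATAC.** Tn5 insertion weight at base b is
`copy(replicon) x [background + enrichment x accessibility(gene) if b in
TSS ± 100 bp] x exp(slope x (GC_local - GC_genome))` with background 1,
enrichment 8, slope −3 over a 200 bp GC window. Per-gene accessibility is
lognormal(0, 0.5) and shared across growth conditions — by construction,
conditions change transcription but not accessibility, which is the
decoupling structure the differential layer must recover. Fragment lengths
are a discretized lognormal parameterized by its mode (95 bp, the midpoint
of the expected 90–100 bp band) truncated to [30, 500]; the log-sd (0.18)
is chosen so the distribution has a well-resolved peak at its mode rather
than a plateau. Sampled positions are fragment midpoints.

**Naked DNA.** Per-replicon weight ∝ length x copy number, uniform within
a replicon, same length model. This is the copy-number estimator's input.

**KAS.** Read placement weight: per-gene body rate + 5x promoter-proximal
pause over the first 50 bp of each *transcription unit* (singletons and
operon-first genes — operon-internal genes share the unit promoter), all
times copy number over a 0.05/bp background. Rates are drawn per
transcription unit (lognormal(0, 1)); a flagged ~25% of multi-gene operons
carries an internal initiation site: the downstream members switch to an
independently boosted (5x) rate and gain their own pause peak. Between
exponential and stationary conditions, whole units covering ~30% of genes
shift their rate by 2^(±2). The dormant condition sets all gene rates to
~0 over a 0.002/bp background and adds a 10/bp peak in the CRISPR-locus
window, so most reads fall in that single peak.

**Methylation molecules.** Each molecule spans a contiguous window
(default 200 bp); half anchor at jittered TSSs, the rest land uniformly
with copy-number weight. Every GpC cytosine (plus CpG in dSMF mode; GCG
sites are excluded as context-ambiguous) is methylated with the
per-condition accessibility probability — 0.15 exponential, 0.11
stationary, i.e. true protection 85% / 89%. All promoters carry a
footprint at offsets [−60, −10) occupied in 5% of molecules; inside an
occupied footprint the methylation probability drops to a 0.02 leak. The
footprint width and occupancy are stand-ins (the phenomenon is reported
only qualitatively) and are recorded in `SimTruth`.

What the generator does *not* emulate: sequencing error, PCR duplicates,
mappability structure, bisulfite-conversion chemistry, rRNA multimapping
and real promoter sequence motifs. Passing tests therefore demonstrate
estimator correctness under the modelled structure, not robustness to
those artefacts.

## Estimators and numerical choices

**Coverage.** Per-base occupancy counts fragments overlapping each base
(cut-site mode counts the two Tn5 insertion points instead); binned values
are within-bin means, so coverage conservation (sum of per-base coverage =
sum of fragment lengths) holds exactly. RPM multiplies by 1e6 / total
fragments pooled over all replicons; with a 26x plasmid in the genome the
pooled-vs-per-replicon choice is material, so a per-replicon flag exists.

**TSS ratio score.** Pooled-sum form: one ratio of pooled means rather
than a mean of per-TSS ratios, which is robust to individual promoters
with empty background windows. "± 100 bp" is the 201-bp window
[TSS−100, TSS+101); background windows are [±2000−50, ±2000+50). A TSS
missing either background window is skipped and counted. The score is
scale-invariant (identical under raw and RPM).

**Peak calling.** Fragment *midpoints* are counted per window so the
Poisson window model is exact (overlap counting correlates adjacent
windows). λ is the maximum of the copy-weighted genome-wide rate, 1 kb and
10 kb local rates, the depth-scaled control rate when a naked-DNA control
is given, and a 0.1 floor — a deliberate simplification of the MACS2
λ_local scheme with auditable math; MACS2 parity is a non-goal. Windows at
p ≤ 1e−4 are merged across gaps ≤ 100 bp; peaks shorter than 75 bp are
dropped and filtered at BH q ≤ 0.05 (recorded in output headers). Summits
are the leftmost coverage maximum.

**Protection.** The headline estimate pools calls ("fraction of sites
protected"); a per-molecule average is reported alongside since the two
readings are both defensible. Molecules need ≥ 3 informative sites;
metaprofile offsets with < 20 calls are masked. The footprint detector
takes the maximal run of offsets above baseline + 2 binomial SE of the
(call-weighted) flank baseline and permutes offset labels (seeded) for an
empirical p; at the default 5% occupancy the per-offset elevation is
~0.0065, detectable in pooled window comparisons at ~1e4 molecules but
below the run-detector's resolution at that depth — which matches the
expectation that the footprint is visible in a few percent of single
molecules, not as a bulk feature.

**Metagene.** Gene bodies are rescaled to 50 bins by averaging per-base
signal in equal subintervals; flanks (500 bp) are unscaled, strand
oriented, with off-replicon offsets excluded rather than zero-filled.
Genes shorter than 300 bp are excluded (and counted) because shorter genes
alias the bin structure.

**Operon coordination.** Per-gene density = fragment count / gene length,
depth- (per million) and copy-weight-normalized; uniformity is the sample
CV (ddof = 1) and max/min ratio. A peak flags internal initiation when its
summit lies ≥ 100 bp inside the operon span and within 150 bp of a
non-first gene start (transcription order); the 150 bp rule is a stand-in
recorded in output metadata, since no quantitative criterion for
"internal promoter" exists.

**Differential test.** Size factors are median-of-ratios over features
nonzero in all libraries, rescaled to geometric mean 1. Dispersion is
per-feature method of moments on normalized counts, pooled across the two
groups (weights n−1), floored at 1e−8; no empirical-Bayes shrinkage is
applied — the decoupling conclusion depends on which features change, not
on shrinkage-grade effect sizes. The Wald statistic uses a delta-method SE
on log2((mean_B + 1)/(mean_A + 1)) with NB model variance; p-values come
from the normal reference and q-values from an in-package BH step-up
(cross-checked against statsmodels in tests). A single-library group falls
back to Poisson dispersion with a warning. Correlations are computed on
log2(x + 1) normalized values, or directly on paired log2 fold changes in
"changes" mode.

## Degenerate inputs and tie-breaks

Zero-gene annotations fail TSS operations with a clear error; a zero
background window sum is an error, not infinity; an undefined
promoter/body ratio returns NaN rather than dividing by zero; histogram
modes tie-break to the smaller length; summit ties break leftmost;
duplicate-fragment collapsing is off by default (inputs are assumed
deduplicated upstream) behind a flag.

## Problem sizes

Validation runs use 2e5 fragments per bulk library, 1e4 molecules per
footprinting condition, and 50-seed loops at reduced depth on a miniature
(84 kb, 40-gene) genome for calibration checks. These sizes put binomial
sampling error well inside the tolerances being asserted while keeping the
full suite fast.

## Known limitations

The NB Wald test is anticonservative for very low counts with few
replicates (the usual caveat for unshrunk method-of-moments dispersion);
the peak caller has no broad-peak mode and does not model fragment-size
shifting; the footprint detector assumes a single dominant footprint in
the search window; operon statistics assume annotation-supplied operon
membership and do not infer transcription units de novo; multimapping
normalization for repeated loci (e.g. duplicated rRNA operons) is out of
scope — simulated genomes contain no duplicated operons.
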