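# archatac

Chromatin accessibility, single-molecule footprinting and ssDNA
transcription analysis for multi-replicon prokaryotic genomes — the kind of
genome a halophilic archaeon carries: one main chromosome plus several
plasmids at wildly unequal per-cell copy numbers (the smallest at ~26
copies per chromosome).

The package is aimed at researchers analysing ATAC-seq, NOMe-seq/dSMF and
KAS-seq data from archaea or bacteria, where standard eukaryote-centric
tooling breaks down: replicon ploidy distorts depth normalization, operons
complicate per-gene quantification, and absolute protection must be read
from single-molecule methylation calls rather than bulk coverage. It ships
with a synthetic multi-replicon assay generator so every stage is testable
end to end without sequencing data.

## What it computes

- **TSS ratio score** (library QC): pooled mean ATAC signal in TSS ± 100 bp
  divided by pooled mean signal in the two 100-bp windows centered ± 2 kb
  from each TSS. Unenriched libraries score ~1.
- **Replicon copy number**: per replicate,
  ratio(X) = (fragments on X / length X) / (fragments on main / length main),
  averaged over naked-DNA tagmentation replicates.
- **Local-Poisson peak calling**: sliding windows (w = 150, s = 50) of
  fragment-midpoint counts against λ = max(genome-wide rate weighted by
  replicon copy number, 1 kb / 10 kb local rates, control-derived rate,
  0.1), Poisson upper-tail p, BH q across windows, merged peaks with
  summits, plus signed summit-to-nearest-TSS distances.
- **Absolute protection** from methylation footprinting: the fraction of
  informative GpC (optionally CpG) sites left unmethylated, with Wilson CI;
  single-molecule protection matrices; strand-aware protection
  metaprofiles; a permutation-tested detector for the small protection
  footprint immediately upstream of TSSs.
- **KAS-type ssDNA analysis**: scaled gene-body metagenes,
  promoter-proximal pausing ratios, and per-operon transcription
  uniformity (CV, max/min density ratio) with internal-initiation flags.
- **Differential counts and decoupling**: median-of-ratios size factors, a
  self-contained negative-binomial Wald test, BH FDR, and
  Pearson/Spearman correlation of accessibility vs transcription levels
  or changes.

## Worked example

```python
from archatac import *
from archatac.footprints import absolute_protection

sim = Simulation(SimConfig())          # default multi-replicon genome

# replicon ploidy from 4 naked-DNA replicates
reps = [sim.naked(200_000, seed) for seed in (1, 2, 3, 4)]
print(replicon_copy_number(reps, sim.genome, "chr").mean_ratio.round(2))

atac = sim.atac("exponential", 200_000, seed=1)
print(fragment_length_histogram(atac).mode)

track = coverage_track(atac, sim.genome)
print(tss_ratio_score(track, sim.genome).score)

peaks = call_peaks(atac, sim.genome, copy_weights=sim.truth.copy_numbers)
print(peak_tss_distances(peaks, sim.genome)[1])

calls = sim.methyl_molecules("exponential", 10_000, window=200, seed=7)
print(absolute_protection(calls).fraction)
```

Output:

```
chr      1.00
pHV4     0.99
pHV3     1.00
pHV1     1.41
pHV2    25.98
95
4.63
1.0
0.8514
```

Reading: the estimator recovers the configured ploidies (26x for the
pHV2-like plasmid, 1.4x for the pHV1-like one, 1:1 for the rest); ATAC
fragments are unimodal with a 95 bp mode; the library is strongly
TSS-enriched (score 4.6); every called peak sits within 200 bp of a TSS;
and 85% of methyltransferase-accessible sites are protected — the
exponential-phase occupancy level.

A command-line layer mirrors the library:

```sh
archatac simulate --n 200000 --seed 1 --out data/
archatac tss-score --fragments data/atac_exponential.bed \
    --fasta data/genome.fa --annotation data/annotation.tsv
archatac peaks --fragments data/atac_exponential.bed \
    --fasta data/genome.fa --annotation data/annotation.tsv --out peaks.bed
```

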