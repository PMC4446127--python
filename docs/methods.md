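# Methods

This note documents the models, conventions and design choices behind
`promdir`, in the spirit of a methods supplement: what each stage assumes,
which constants matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Coordinates and geometry

All coordinates are 0-based, half-open (BED convention). A read's 5′ end
is `start` for + reads and `end − 1` for − reads. ChIP-seq reads are
*replaced* by a 147 bp fragment anchored at the 5′ end (the approximate
nucleosome footprint), regardless of the sequenced read length; fragments
are clipped at chromosome bounds rather than discarded, preserving mass
near the ends. RNA-seq is handled differently: gapped (12-column)
alignments are split into their ungapped blocks and piled up at their
actual extents with no extension, because transcript coverage — not
nucleosome occupancy — is the quantity of interest there. Duplicate reads
are kept (no deduplication).

Footprint windows are ±1 kb around the TSS, 2001 columns in the gene's
5′→3′ frame; column 0 is always 1 kb upstream. The TSS base itself is
assigned to the *downstream* half (positions 0..+1000). This is a
convention choice — the window has an odd number of bases and the middle
base has to live somewhere — and all segment arithmetic is derived from
it.

## Directionality rules

* **Active**: a same-strand CAGE cluster within 10 bp of the TSS
  (point-to-interval distance, inclusive bound).
* **Bidirectional (gene-model rule)**: another gene's TSS on the opposite
  strand within 1 kb (point-to-point, inclusive).
* **Bidirectional (CAGE rule)**: an opposite-strand cluster within 1 kb
  (point-to-interval, inclusive).
* Per rule, unidirectional = active and not bidirectional; the combined
  class requires agreement, otherwise the gene is excluded.
* **Alternative-TSS filter**: a unidirectional gene is flagged when a
  same-strand cluster's nearest base lies 11..1000 bp upstream. Starting
  at 11 bp means the gene's own activity-defining cluster can never
  disqualify it; the choice is ours, since nothing forces the two windows
  to be disjoint.

Cluster thresholding retains all clusters above the smallest score cutoff
that keeps at most 29,857 of them (the promoter count expected from a
deeply-sequenced CAGE sample). This is threshold semantics, not top-N
selection: a tie group straddling the cap is dropped whole, so the
retained count may undershoot the cap.

## Footprints and the bootstrap

Group footprints are column means of the per-gene window matrix. The 95%
CI is a percentile bootstrap over genes (100 resamples, the customary
resampling depth for this analysis). With only 100 resamples, linearly
interpolated percentiles bias the interval inward and cost real coverage,
so the bounds are outward-rounded order statistics (`method="lower"` /
`"higher"`); measured coverage under a normal model with 200 genes is
~94–95% versus ~92% for interpolated percentiles. Bounds are additionally
clamped around the exact mean so `lo ≤ mean ≤ hi` holds degenerately. No
per-gene or library-size normalization is applied: profiles are average
read counts, comparable across groups of the same sample.

## Segment peak test

The 2001-column window is cut into 13 contiguous segments whose lengths
differ by at most 1 (twelve of 154 bp, one of 153 bp), longer segments
placed first from the upstream end. The segment width was chosen to be
close to — but not larger than — one nucleosome plus linker, so one
segment cannot span two phased nucleosomes. A gene's statistic per
segment is the maximum per-base depth; the background λ is the
genome-wide mean depth of the same extended-read track (total mass over
total genome length, genome-wide rather than per-chromosome; a
per-chromosome variant would only matter with heterogeneous chromosomes).
Each of the 78 (segment, fold) cells gets a two-sided Fisher's exact test
on the 2×2 peak/no-peak × class table; we use the two-sided test because
the analysis should also be able to detect peaks enriched in the
*bidirectional* class. Bonferroni correction multiplies by 78 and caps at
1. The "top segment" at a fold is the one with the largest prevalence
difference, ties broken upstream-first; ties do occur on synthetic data
because a 147 bp point-source pileup necessarily saturates two adjacent
153–154 bp segments when it straddles their boundary.

## Motif analysis

Scanning uses log-odds scores of the position count matrix with
pseudocount 1 against a 0-order background estimated from the scanned
sequence itself. Scores are discretized to 1/1000 log-units; the null
score distribution is computed exactly by convolving the per-position
score PMFs on that integer grid, so p = P(S ≥ s) carries no sampling
error and the discretization error is bounded by L/2000 log-units.
Windows containing N are skipped. One scan covers all active genes of a
sample jointly, with overlapping promoter windows merged first so no
genomic window enters the multiple-testing budget twice;
Benjamini–Hochberg q-values are computed over every scanned window of the
run and hits are reported at q ≤ 0.05.

Motif coverage counts (gene, hit) pairs per covered base in the gene
frame (per-base span coverage; counting only hit starts is available as a
flag). The coverage is smoothed by a ±20 bp truncated moving average and
the motif site is the smoothed argmax, ties resolved toward the TSS and
then upstream — the tie rule matters for degenerate inputs such as a
single 1 bp hit, whose 41 bp smoothed plateau resolves to the plateau edge
nearest the TSS.

The 'CTCF' group contains unidirectional genes with a hit whose 5′-most
base (gene frame) lies within 100 bp of the motif site *and* at least 100
CTCF reads in the ±1 kb window. Read counts are estimated as window depth
sum divided by the 147 bp extension, which is exact for fragments fully
inside the window and slightly conservative at the edges. Correlations
between total window CTCF signal and each mark's upstream/downstream sums
are Pearson (Spearman behind a flag); zero-variance inputs yield a
missing coefficient.

## Co-occurrence clustering

Features are the per-track ±1 kb windows averaged in consecutive 25 bp
bins (a trailing 1 bp bin is averaged over its own width) and
concatenated. k-means with k = 2 uses k-means++ seeding, 10 restarts and a
fixed seed (scikit-learn's Lloyd implementation); features are raw read
densities, unscaled — a z-scaling flag exists but is off by default, so
the clustering follows absolute signal strength. Cluster 1 is canonically
the cluster with higher mean CTCF signal. The association with
directionality is a two-sided Fisher test on the cluster × class table,
with excluded/inactive genes dropped.

## The synthetic landscape

The generator tiles one chromosome (default 10 Mb) with well-separated
promoter units: single unidirectional genes and divergent gene pairs
(default 400 genes, 25% bidirectional, unit spacing ≥ 5 kb). Realizing
bidirectional promoters as literal divergent pairs makes both
directionality rules true by construction and lets each member's
antisense tags and upstream RNA-seq signal emerge from its partner rather
than from an ad-hoc overlay.

Key defaults, chosen once as plausible study conditions:

| parameter | default | role |
|---|---|---|
| sense tags/gene | lognormal(μ=3.0, σ=1.2), floor 1 | spans expression quartiles (median ≈ 20 tags) |
| antisense ratio (pairs) | 0.6 | partner expression scaled off the first member |
| zero-antisense fraction (uni) | 0.7 | the large 'None' antisense group |
| CTCF/RAD21 peak | offset −80 bp, jitter ±15, in 60% of uni genes | the planted upstream pileup |
| peak reads | Poisson(strength·150) CTCF, Poisson(strength·120) RAD21, strength ~ lognormal(0, 0.2) | shared strength couples CTCF and RAD21 per gene |
| promoter mark | nucleosomes at +100/+300/+500 bp, sd 50, amplitudes 25/18/12, saturating in expression | phased downstream array |
| background | 2·10⁻⁴ reads/bp/track | uniform noise floor |

The ±15 bp peak jitter matters for the motif-site estimator: with a
perfectly fixed offset the smoothed coverage has an exactly flat top
(smoothing window wider than the hit support) and the tie-break, not the
signal, decides the site. Peak read amplitudes sit comfortably above the
100-read CTCF-group rule, so the planted genes are recoverable; the
shared lognormal strength factor gives the within-group CTCF–RAD21
correlation observed in real cohesin data. Upstream promoter-mark signal
is supplied by the partner gene in pairs and by an explicit upstream arm
(amplitude saturating in the antisense tag count, x/(x+20)) in uni genes
with stray antisense tags, so upstream signal grows monotonically with
antisense level by construction.

The motif is a **synthetic** 19 bp CTCF-like position count matrix
(consensus `CCGCGAGGTGGCAGTACCT`, 85:5 counts) written into the uniform
A/C/G/T background sequence at the peak center, on a random strand by
default. It shares the length and file format of the JASPAR CTCF matrix
but not its counts.

**What the generator does not emulate:** realistic genome composition,
GC/mappability bias, replicate structure, multi-TSS genes, enhancers, or
inter-chromosomal effects. Passing tests therefore demonstrate that the
*computations* are correct and well-calibrated and that the pipeline
recovers known structure under fair noise — not that the biological
effect sizes match any particular cell line.

## Problem sizes

Defaults were sized for interactive use: 400 genes / 10 Mb for the main
landscape, 60–80 genes for structural tests, 1000 replicates for bootstrap
coverage, 200 simulations for the family-wise-error and null-p checks.
All are parameters, not limits.

## Known limitations

* The activity rule keys on clusters' nearest-base distance; very long
  clusters can activate a gene from afar if they reach within 10 bp.
* Read-count estimation from depth slightly undercounts fragments
  clipped at window edges.
* `cross_sample_consistency` treats any excluded call in an active sample
  as 'mixed', a conservative choice.
* The exact-p DP assumes a 0-order background; higher-order backgrounds
  would require a different recursion.
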