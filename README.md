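# promdir

Promoters of protein-coding genes differ in whether transcription initiates
in one direction or divergently in both. `promdir` classifies genes as
**bi- or unidirectionally transcribed** from CAGE (cap analysis of gene
expression) evidence and contrasts histone-modification and
transcription-factor ChIP-seq signal around the TSS between the two
classes — including the segment-based CTCF peak-prevalence test, CTCF
motif-site localization, signal correlation analysis for genes with a
well-positioned upstream CTCF peak, and CTCF/RAD21 co-occurrence
clustering. It is aimed at regulatory genomicists who want a tested,
reusable, fully scriptable version of this analysis. A synthetic-data
generator with known ground truth stands in for genome-scale CAGE/ChIP-seq
tracks, so every stage is verifiable at desk scale.

## The analysis

**Directionality.** A gene is *active* when a CAGE cluster lies on its
strand within 10 bp of the TSS. An active gene is *bidirectional* by the
gene-model rule when another gene's TSS lies on the opposite strand within
1 kb, and by the CAGE rule when an opposite-strand CAGE cluster lies within
1 kb; each rule calls the remaining active genes unidirectional, and only
genes on which both rules agree keep a combined class.

**Footprints.** Reads are extended to the 147 bp nucleosome length and
piled into per-base coverage. For a gene set *G* the footprint is the mean
depth at every position *x* ∈ [−1000, +1000] in each gene's 5′→3′ frame,
with a 95% percentile-bootstrap CI from resampling genes 100 times.

**Segment peak test.** The ±1 kb window is split into 13 segments of
153–154 bp. Gene *g* has a peak in segment *s* at fold *f* when
max depth in *s* ≥ *f* · λ, with λ the genome-wide mean per-base depth.
For each of the 13 × 6 (segment, fold) cells with
*f* ∈ {5, 10, 20, 50, 100, 200}, peak prevalence in the two classes is
compared by two-sided Fisher's exact test, Bonferroni-corrected over the
78 tests.

**Motifs.** Promoter sequences are scanned on both strands with a
position-weight matrix; log-odds p-values are exact (dynamic programming
over the discretized score distribution) and hits are thresholded at
Benjamini–Hochberg q ≤ 0.05. Per-base motif coverage around the TSS,
smoothed by a ±20 bp average, localizes the *motif site*; unidirectional
genes with a motif within 100 bp of that site and ≥ 100 CTCF reads in the
window form the 'CTCF' group for the correlation analysis.

**Co-occurrence.** Active genes are clustered (k-means, k = 2) on their
25 bp-binned CTCF + RAD21 window signal, and cluster membership is tested
against directionality with Fisher's exact test.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic landscape (400 genes — 300 unidirectional, 100 bidirectional as
divergent pairs — on a 10 Mb chromosome):

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_annotate.py --seed 0
python analysis/05_peaks.py    --seed 0
```

which prints (abridged):

```
simulated 400 genes on one 10 Mb chromosome
planted CTCF/RAD21 peaks: 171 (motif written for 158)

active genes: 400 / 400
rule agreement: 100.0% of active genes
ground-truth recovery: 100.0%

78 Fisher tests (13 segments x 6 fold thresholds)
fold  100: top segment  -230..  -77  uni  57.0%  bi   0.0%  p_bonf 2.72e-28  *
```

Every generated gene is active (each gets a TSS cluster by construction),
both directionality rules agree, and the combined annotation recovers the
planted classes exactly. The segment test finds the planted upstream
CTCF pileup: at 100-fold enrichment over background, the segment spanning
77–230 bp upstream of the TSS holds a peak in 57% of unidirectional genes
and 0% of bidirectional ones. The remaining drivers localize the CTCF
motif site 80 bp upstream of the TSS (`06`), show antisense RNA-seq signal
upstream only in bidirectional genes (`03`), upstream H3K4me3 rising
monotonically with the antisense level (`04`), and a CTCF+RAD21
co-occurrence cluster of 171 genes that is exclusively unidirectional,
p = 3.5·10⁻³⁰ (`07`).

The same pipeline is available as a CLI (`promdir all --seed 0 --outdir
out/`) and as plain library calls (`promdir.pipeline.run`).

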