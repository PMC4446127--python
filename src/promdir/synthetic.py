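"""Synthetic promoter landscape with known directionality ground truth.

The generator emulates the data a promoter-directionality study consumes:
a gene table, raw CAGE tags and CAGE clusters, ChIP-seq read sets for CTCF,
RAD21 and a promoter histone mark, strand-specific (optionally gapped)
RNA-seq reads, and a chromosome sequence with CTCF-like motif instances
planted upstream of unidirectional genes.

Design of the landscape
-----------------------
* The chromosome is tiled with well-separated "promoter units": either a
  single unidirectional gene or a divergent gene pair. A divergent pair
  realizes a bidirectional promoter literally — each member is a real gene
  on the opposite strand within 1 kb of the other — so both the
  gene-model-based and the CAGE-based bidirectionality rules hold by
  construction, and the antisense tag/RNA-seq structure of each member
  emerges from its partner.
* Every gene gets a same-strand CAGE cluster within 10 bp of its TSS whose
  score equals its tag count, so all generated genes are "active".
* A configurable fraction of unidirectional genes carries a planted
  CTCF+RAD21 read pileup centered ~80 bp upstream of the TSS (jittered),
  usually with a motif instance written into the sequence at the pileup
  center.
* Promoter-mark reads are drawn from Gaussian mixtures at phased nucleosome
  positions downstream of the TSS, with amplitude saturating in the gene's
  expression; upstream mark signal arises from the partner gene (divergent
  pairs) or an explicit upstream arm scaled by the gene's antisense tag
  count, so upstream signal grows with antisense transcription.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``SimulationConfig.seed``; identical configs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_gene_table,
)

BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space

#: consensus of the synthetic CTCF-like motif (19 bp, invented stand-in for
#: the JASPAR CTCF matrix; same length and file format, not the real counts)
SYNTHETIC_CTCF_CONSENSUS = "CCGCGAGGTGGCAGTACCT"


def synthetic_ctcf_pcm(consensus: str = SYNTHETIC_CTCF_CONSENSUS,
                       major: int = 85, minor: int = 5) -> np.ndarray:
    """A synthetic position count matrix (4 x L, rows A/C/G/T).

    ``major`` counts go to the consensus base at each position and ``minor``
    to each other base, mimicking a strong JASPAR-style motif.
    """
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    pcm = np.full((4, len(consensus)), minor, dtype=int)
    for j, base in enumerate(consensus):
        pcm[code[base], j] = major
    return pcm


@dataclass
class SimulationConfig:
    """Parameters of the synthetic promoter landscape (defaults = study conditions)."""

    seed: int = 0
    n_genes: int = 400
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    min_gene_spacing: int = 5000
    fraction_bidirectional: float = 0.25
    # per-gene CAGE tag counts: lognormal(mu, sigma), rounded, floor 1
    sense_tag_mu: float = 3.0
    sense_tag_sigma: float = 1.2
    antisense_zero_fraction: float = 0.7
    antisense_ratio: float = 0.6
    alt_tss_fraction: float = 0.1
    # planted CTCF/RAD21 pileups (gene 5'->3' frame; negative = upstream)
    ctcf_peak_offset: int = -80
    ctcf_peak_jitter: int = 15
    ctcf_peak_fraction: float = 0.6
    ctcf_peak_reads: int = 150
    rad21_peak_reads: int = 120
    ctcf_peak_strength_sd: float = 0.2
    read_spread_sd: float = 10.0
    motif_probability: float = 0.9
    motif_strand: str = "random"  # '+', '-', or 'random' relative to genome
    # promoter-mark nucleosome mixture: (center offset bp, amplitude, sd bp)
    hm_profile: dict = field(default_factory=lambda: {
        "H3K4me3": [(100, 25.0, 50.0), (300, 18.0, 50.0), (500, 12.0, 50.0)],
    })
    hm_saturation_tags: float = 20.0
    background_read_rate: float = 2e-4
    chip_read_length: int = 36
    # RNA-seq
    rnaseq_reads_per_tag: float = 2.0
    rnaseq_span: int = 1000
    rnaseq_read_length: int = 50
    rnaseq_gap_fraction: float = 0.3

    # internal geometry
    _pair_sep_min: int = 150
    _pair_sep_max: int = 800
    _margin: int = 3000

    def __post_init__(self) -> None:
        for name in ("fraction_bidirectional", "antisense_zero_fraction",
                     "alt_tss_fraction", "ctcf_peak_fraction",
                     "motif_probability", "rnaseq_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.ctcf_peak_offset) > 1000:
            raise ValueError("ctcf_peak_offset must lie within ±1000")
        if self.motif_strand not in ("+", "-", "random"):
            raise ValueError("motif_strand must be '+', '-' or 'random'")
        if self.n_genes < 4:
            raise ValueError("need at least 4 genes")
        # normalize nucleosome mixtures to tuples (YAML round-trips lists)
        self.hm_profile = {
            mark: [tuple(entry) for entry in mixture]
            for mark, mixture in self.hm_profile.items()
        }


@dataclass
class SimulatedData:
    """Everything the pipeline consumes, plus the ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    cage_tags: list[GenomicInterval]
    cage_clusters: list[GenomicInterval]
    chip_reads: dict[str, list[GenomicInterval]]
    rnaseq_reads: list[GenomicInterval]
    sequences: dict[str, np.ndarray]  # uint8 codes, 0..3 = A/C/G/T
    pcm: np.ndarray
    truth: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence_str(self, chrom: str) -> str:
        return "".join(BASES[self.sequences[chrom]])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the standard file formats the pipeline reads."""
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        from .motifs import write_jaspar

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "cage_tags": outdir / "cage_tags.bed",
            "cage_clusters": outdir / "cage_clusters.bed",
            "rnaseq": outdir / "rnaseq.bed",
            "genome": outdir / "genome.fa",
            "pcm": outdir / "ctcf_motif.pcm",
            "truth": outdir / "ground_truth.tsv",
            "chrom_sizes": outdir / "chrom.sizes",
        }
        write_gene_table(paths["genes"], self.genes)
        write_bed(paths["cage_tags"], self.cage_tags)
        write_bed(paths["cage_clusters"], self.cage_clusters)
        write_bed(paths["rnaseq"], self.rnaseq_reads)
        for mark, reads in self.chip_reads.items():
            p = outdir / f"chip_{mark}.bed"
            paths[f"chip_{mark}"] = p
            write_bed(p, reads)
        records = [SeqRecord(Seq(self.sequence_str(c)), id=c, description="")
                   for c in self.sequences]
        SeqIO.write(records, paths["genome"], "fasta")
        write_jaspar(paths["pcm"], self.pcm, name="CTCF_synthetic")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["chrom_sizes"], "w") as fh:
            for c, n in self.chrom_lengths.items():
                fh.write(f"{c}\t{n}\n")
        return paths


def _frame_to_genomic(tss: int, strand: str, x: int) -> int:
    """Map a gene-frame coordinate (0 = TSS, + = downstream) to genomic bp."""
    return tss + x if strand == "+" else tss - x


def _tag_interval(chrom: str, p5: int, strand: str, length: int = 20,
                  name: str = ".", score: float = 0.0) -> GenomicInterval:
    """A read-like interval whose 5' end sits at ``p5``."""
    if strand == "-":
        return GenomicInterval(chrom, p5 - length + 1, p5 + 1, name, score, strand)
    return GenomicInterval(chrom, p5, p5 + length, name, score, strand)


def generate(config: SimulationConfig) -> SimulatedData:
    """Generate the full synthetic dataset for one sample."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_bi = int(round(cfg.n_genes * cfg.fraction_bidirectional))
    if n_bi % 2:
        n_bi -= 1
    n_uni = cfg.n_genes - n_bi
    n_units = n_uni + n_bi // 2

    unit_pitch = cfg.min_gene_spacing + cfg._pair_sep_max
    required = 2 * cfg._margin + max(n_units - 1, 0) * unit_pitch
    if required > cfg.chrom_length:
        raise ValueError(
            f"chromosome of {cfg.chrom_length} bp too short for {cfg.n_genes} "
            f"genes at spacing {cfg.min_gene_spacing} (need >= {required} bp)"
        )

    # unit anchors: sorted, pairwise distance >= unit_pitch
    slack = cfg.chrom_length - required
    offsets = np.sort(rng.uniform(0, slack, size=n_units))
    anchors = (cfg._margin + offsets + np.arange(n_units) * unit_pitch).astype(int)
    unit_is_pair = np.zeros(n_units, dtype=bool)
    unit_is_pair[: n_bi // 2] = True
    rng.shuffle(unit_is_pair)

    genes: list[GeneModel] = []
    partner: dict[str, str | None] = {}
    for anchor, is_pair in zip(anchors, unit_is_pair):
        if is_pair:
            sep = int(rng.integers(cfg._pair_sep_min, cfg._pair_sep_max + 1))
            ga = GeneModel(f"g{len(genes):04d}", cfg.chrom, "-", int(anchor - sep))
            gb = GeneModel(f"g{len(genes) + 1:04d}", cfg.chrom, "+", int(anchor))
            genes += [ga, gb]
            partner[ga.gene_id] = gb.gene_id
            partner[gb.gene_id] = ga.gene_id
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(f"g{len(genes):04d}", cfg.chrom, strand, int(anchor))
            genes.append(g)
            partner[g.gene_id] = None

    by_id = {g.gene_id: g for g in genes}

    # --- CAGE tag counts -------------------------------------------------
    sense: dict[str, int] = {}
    for g in genes:
        p = partner[g.gene_id]
        if p is not None and p in sense:
            # second member of a pair: scaled off the first member
            sense[g.gene_id] = max(
                1, int(rng.poisson(cfg.antisense_ratio * sense[p])))
        else:
            sense[g.gene_id] = max(
                1, int(round(rng.lognormal(cfg.sense_tag_mu, cfg.sense_tag_sigma))))

    antisense: dict[str, int] = {}
    alt_tss: dict[str, bool] = {}
    for g in genes:
        p = partner[g.gene_id]
        if p is not None:
            antisense[g.gene_id] = sense[p]
            alt_tss[g.gene_id] = False
        else:
            if rng.random() < cfg.antisense_zero_fraction:
                antisense[g.gene_id] = 0
            else:
                antisense[g.gene_id] = 1 + int(rng.poisson(2.0))
            alt_tss[g.gene_id] = rng.random() < cfg.alt_tss_fraction

    # --- tags and clusters ----------------------------------------------
    cage_tags: list[GenomicInterval] = []
    cage_clusters: list[GenomicInterval] = []
    for g in genes:
        n = sense[g.gene_id]
        deltas = rng.integers(-5, 6, size=n)
        for d in deltas:
            cage_tags.append(_tag_interval(g.chrom, g.tss + int(d), g.strand))
        cage_clusters.append(GenomicInterval(
            g.chrom, g.tss - 5, g.tss + 6, g.gene_id, float(n), g.strand))
        if partner[g.gene_id] is None and antisense[g.gene_id] > 0:
            # stray antisense initiation: raw tags upstream, no cluster
            opp = "-" if g.strand == "+" else "+"
            for _ in range(antisense[g.gene_id]):
                u = int(rng.integers(50, 1000))
                p5 = _frame_to_genomic(g.tss, g.strand, -u)
                cage_tags.append(_tag_interval(g.chrom, p5, opp))
        if alt_tss[g.gene_id]:
            u = int(rng.integers(200, 901))
            pos = _frame_to_genomic(g.tss, g.strand, -u)
            s, e = (pos - 5, pos + 6)
            cage_clusters.append(GenomicInterval(
                g.chrom, s, e, f"{g.gene_id}_alt", 5.0, g.strand))

    # --- ChIP-seq reads ---------------------------------------------------
    half = NUC_HALF = 73  # extended-fragment half-width (147 bp // 2)
    rl = cfg.chip_read_length

    def peak_reads(center: int, n: int) -> list[GenomicInterval]:
        out = []
        shifts = np.rint(rng.normal(0.0, cfg.read_spread_sd, size=n)).astype(int)
        strands = rng.random(n) < 0.5
        for shift, plus in zip(shifts, strands):
            c = center + int(shift)
            if plus:
                start = c - half
                out.append(GenomicInterval(cfg.chrom, start, start + rl,
                                           ".", 0.0, "+"))
            else:
                end = c + half + 1
                out.append(GenomicInterval(cfg.chrom, end - rl, end,
                                           ".", 0.0, "-"))
        return out

    sat = cfg.hm_saturation_tags

    chip_reads: dict[str, list[GenomicInterval]] = {
        "CTCF": [], "RAD21": [], **{m: [] for m in cfg.hm_profile}}

    ctcf_flag: dict[str, bool] = {}
    motif_flag: dict[str, bool] = {}
    peak_center: dict[str, int | None] = {}
    for g in genes:
        is_uni = partner[g.gene_id] is None
        planted = is_uni and rng.random() < cfg.ctcf_peak_fraction
        ctcf_flag[g.gene_id] = planted
        if planted:
            off = cfg.ctcf_peak_offset + int(
                rng.integers(-cfg.ctcf_peak_jitter, cfg.ctcf_peak_jitter + 1))
            center = _frame_to_genomic(g.tss, g.strand, off)
            peak_center[g.gene_id] = center
            # shared per-gene binding strength couples CTCF and RAD21 counts
            strength = rng.lognormal(0.0, cfg.ctcf_peak_strength_sd)
            chip_reads["CTCF"] += peak_reads(
                center, int(rng.poisson(strength * cfg.ctcf_peak_reads)))
            chip_reads["RAD21"] += peak_reads(
                center, int(rng.poisson(strength * cfg.rad21_peak_reads)))
            motif_flag[g.gene_id] = rng.random() < cfg.motif_probability
        else:
            peak_center[g.gene_id] = None
            motif_flag[g.gene_id] = False

        for mark, mixture in cfg.hm_profile.items():
            arms = [(+1, sense[g.gene_id])]
            if is_uni and antisense[g.gene_id] > 0:
                # no partner gene to supply upstream signal: explicit arm
                arms.append((-1, antisense[g.gene_id]))
            for sign, tags in arms:
                f = tags / (tags + sat)
                for off0, amp, sd in mixture:
                    n = int(rng.poisson(amp * f))
                    centers = sign * off0 + np.rint(
                        rng.normal(0.0, sd, size=n)).astype(int)
                    for c_frame in centers:
                        c = _frame_to_genomic(g.tss, g.strand, int(c_frame))
                        chip_reads[mark] += peak_reads(c, 1)

    # uniform background for every mark
    for mark in chip_reads:
        n_bg = int(rng.poisson(cfg.background_read_rate * cfg.chrom_length))
        starts = rng.integers(0, cfg.chrom_length - rl, size=n_bg)
        strands = rng.random(n_bg) < 0.5
        for s, plus in zip(starts, strands):
            chip_reads[mark].append(GenomicInterval(
                cfg.chrom, int(s), int(s) + rl, ".", 0.0, "+" if plus else "-"))

    # --- RNA-seq (sense-strand, downstream of each gene's TSS) -----------
    rnaseq: list[GenomicInterval] = []
    for g in genes:
        n = int(rng.poisson(cfg.rnaseq_reads_per_tag * sense[g.gene_id]))
        span = cfg.rnaseq_read_length
        for _ in range(n):
            u = int(rng.integers(0, cfg.rnaseq_span - span))
            gapped = rng.random() < cfg.rnaseq_gap_fraction
            total = span + 60 if gapped else span
            if g.strand == "+":
                s = g.tss + u
            else:
                s = g.tss - u - total + 1
            e = s + total
            if gapped:
                b = span // 2
                sizes, starts = (b, span - b), (0, total - (span - b))
            else:
                sizes, starts = (span,), (0,)
            rnaseq.append(GenomicInterval(g.chrom, s, e, ".", 0.0, g.strand,
                                          block_sizes=sizes, block_starts=starts))

    # --- sequence with planted motifs -------------------------------------
    seq = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
    pcm = synthetic_ctcf_pcm()
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    consensus = np.array([code[b] for b in SYNTHETIC_CTCF_CONSENSUS], dtype=np.uint8)
    L = len(consensus)
    for g in genes:
        if not motif_flag[g.gene_id]:
            continue
        center = peak_center[g.gene_id]
        start = center - L // 2
        if cfg.motif_strand == "random":
            minus = rng.random() < 0.5
        else:
            minus = cfg.motif_strand == "-"
        inst = _COMPLEMENT[consensus][::-1] if minus else consensus
        seq[start:start + L] = inst

    # --- ground truth ------------------------------------------------------
    order = np.lexsort((np.arange(len(genes)),
                        np.array([sense[g.gene_id] for g in genes])))
    quart = np.empty(len(genes), dtype=object)
    labels = ["Lowest", "Mid-low", "Mid-high", "Highest"]
    for i, block in enumerate(np.array_split(order, 4)):
        quart[block] = labels[i]
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "true_class": ["bi" if partner[g.gene_id] else "uni" for g in genes],
        "sense_tags": [sense[g.gene_id] for g in genes],
        "antisense_tags": [antisense[g.gene_id] for g in genes],
        "ctcf_peak": [ctcf_flag[g.gene_id] for g in genes],
        "motif": [motif_flag[g.gene_id] for g in genes],
        "alt_tss": [alt_tss[g.gene_id] for g in genes],
        "expression_quartile": quart,
    })

    return SimulatedData(
        config=cfg,
        genes=genes,
        cage_tags=cage_tags,
        cage_clusters=cage_clusters,
        chip_reads=chip_reads,
        rnaseq_reads=rnaseq,
        sequences={cfg.chrom: seq},
        pcm=pcm,
        truth=truth,
    )


def subsample_activity(
    sim: SimulatedData, keep_fraction: float, seed: int
) -> tuple[list[GenomicInterval], pd.Series]:
    """Emulate a second sample: drop the TSS clusters of some genes.

    Returns the reduced cluster list and a boolean Series (by gene_id) of
    which genes keep their activity-defining cluster.
    """
    rng = np.random.default_rng(seed)
    keep = pd.Series(
        rng.random(len(sim.genes)) < keep_fraction,
        index=[g.gene_id for g in sim.genes],
    )
    dropped = {gid for gid, k in keep.items() if not k}
    clusters = [c for c in sim.cage_clusters
                if c.name.removesuffix("_alt") not in dropped]
    return clusters, keep
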