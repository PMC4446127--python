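"""End-to-end orchestration: simulate → prep → annotate → footprint → bins
→ peaks → motif → cluster.

Each stage is a function over a working directory: it reads the files the
previous stages wrote (standard text formats only), writes its tables under
``<outdir>/tables``, and is individually re-runnable. ``run`` drives any
single stage or the whole chain and writes a manifest with row counts and
content checksums for every produced table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, cage, cooccurrence, directionality, footprints, motifs, peaks
from .config import PipelineConfig
from .genome_io import (
    CoverageTrack,
    build_coverage,
    read_bed,
    read_gene_table,
    split_gapped,
    write_bed,
)
from .synthetic import generate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "annotate", "footprint", "bins", "peaks",
          "motif", "cluster")


class MissingInputError(FileNotFoundError):
    pass


def _need(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"missing input {path.name!r}; run stage {produced_by!r} first")
    return path


def _data(outdir: Path) -> Path:
    return outdir / "data"


def _tables(outdir: Path) -> Path:
    p = outdir / "tables"
    p.mkdir(parents=True, exist_ok=True)
    return p


def _chrom_lengths(outdir: Path) -> dict[str, int]:
    lengths = {}
    for line in _need(_data(outdir) / "chrom.sizes", "simulate").read_text().splitlines():
        chrom, n = line.split("\t")
        lengths[chrom] = int(n)
    return lengths


def _genes(outdir: Path):
    return read_gene_table(_need(_data(outdir) / "genes.tsv", "simulate"))


def _clusters(outdir: Path):
    return read_bed(_need(_tables(outdir) / "clusters_retained.bed", "prep"), 6)


def _annotation(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(
        _need(_tables(outdir) / "annotation.tsv", "annotate"),
        sep="\t", index_col="gene_id")


def _chip_track(outdir: Path, mark: str, cfg: PipelineConfig) -> CoverageTrack:
    reads = read_bed(_need(_data(outdir) / f"chip_{mark}.bed", "simulate"), 6)
    return build_coverage(reads, _chrom_lengths(outdir),
                          extension_bp=cfg.read_extension)


def _chip_marks(outdir: Path) -> list[str]:
    return sorted(p.stem.removeprefix("chip_")
                  for p in _data(outdir).glob("chip_*.bed"))


def _class_genes(outdir: Path, cls: str):
    ann = _annotation(outdir)
    ids = set(ann.index[ann["class_combined"] == cls])
    return [g for g in _genes(outdir) if g.gene_id in ids]


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = generate(cfg.simulation)
    sim.write(_data(outdir))


def stage_prep(cfg: PipelineConfig, outdir: Path) -> None:
    clusters = read_bed(_need(_data(outdir) / "cage_clusters.bed", "simulate"), 6)
    retained = cage.threshold_clusters(clusters, cfg.cluster_cap)
    write_bed(_tables(outdir) / "clusters_retained.bed", retained)
    report = pd.DataFrame([{
        "clusters_in": len(clusters),
        "clusters_retained": len(retained),
        "cap": cfg.cluster_cap,
        "threshold": min((c.score for c in retained), default=np.nan),
    }])
    report.to_csv(_tables(outdir) / "cluster_report.tsv", sep="\t", index=False)


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    genes = _genes(outdir)
    clusters = _clusters(outdir)
    tags = read_bed(_need(_data(outdir) / "cage_tags.bed", "simulate"), 6)
    sense = cage.count_tags_table(genes, tags, cfg.activity_distance,
                                  "same_strand_near_tss")
    anti = cage.count_tags_table(genes, tags, cfg.bidirectional_distance,
                                 "opposite_strand_flank")
    ann = directionality.annotate(
        genes, clusters, sense, anti,
        cfg.activity_distance, cfg.bidirectional_distance)
    ann.to_csv(_tables(outdir) / "annotation.tsv", sep="\t")


def stage_footprint(cfg: PipelineConfig, outdir: Path) -> None:
    genes = _genes(outdir)
    ann = _annotation(outdir)
    seed = cfg.stage_seed("footprint")
    frames = []
    for mark in _chip_marks(outdir):
        track = _chip_track(outdir, mark, cfg)
        for cls in ("uni", "bi"):
            ids = set(ann.index[ann["class_combined"] == cls])
            grp = [g for g in genes if g.gene_id in ids]
            if not grp:
                continue
            mat = footprints.window_matrix(track, grp, cfg.flank)
            prof = footprints.mean_footprint(mat, cfg.n_bootstrap, seed)
            frames.append(prof.to_frame(label=f"{mark}:{cls}"))
    # strand-specific RNA-seq
    rna = read_bed(_need(_data(outdir) / "rnaseq.bed", "simulate"), 12)
    blocks = [b for r in rna for b in split_gapped(r)]
    rtrack = build_coverage(blocks, _chrom_lengths(outdir),
                            extension_bp=None, stranded=True)
    for cls in ("uni", "bi"):
        ids = set(ann.index[ann["class_combined"] == cls])
        grp = [g for g in genes if g.gene_id in ids]
        if not grp:
            continue
        sense_p, anti_p = footprints.strand_specific_footprint(
            rtrack, grp, cfg.flank, cfg.n_bootstrap, seed)
        frames.append(sense_p.to_frame(label=f"RNAseq_sense:{cls}"))
        frames.append(anti_p.to_frame(label=f"RNAseq_antisense:{cls}"))
    pd.concat(frames).to_csv(_tables(outdir) / "footprints.tsv",
                             sep="\t", index=False)


def stage_bins(cfg: PipelineConfig, outdir: Path) -> None:
    ann = _annotation(outdir)
    active = ann[ann["active"]]
    expr = binning.expression_bins(active["sense_tags"].to_dict())
    anti = binning.antisense_bins(active["antisense_tags"].to_dict())
    table = binning.bins_table(
        {"expression": expr, "antisense": anti},
        {"expression": active["sense_tags"].to_dict(),
         "antisense": active["antisense_tags"].to_dict()})
    table.to_csv(_tables(outdir) / "bins.tsv", sep="\t", index=False)

    genes = _genes(outdir)
    seed = cfg.stage_seed("bins")
    rows = []
    for mark in _chip_marks(outdir):
        track = _chip_track(outdir, mark, cfg)
        mat = footprints.window_matrix(track, genes, cfg.flank)
        for variable, bins in (("expression", expr), ("antisense", anti)):
            profs = binning.per_bin_footprints(
                bins, ann, {mark: mat}, n_boot=cfg.n_bootstrap, seed=seed)
            for (mk, cls, lab), prof in profs.items():
                df = prof.to_frame()
                df["mark"], df["class"] = mk, cls
                df["bin_variable"], df["bin_label"] = variable, lab
                rows.append(df)
    pd.concat(rows).to_csv(_tables(outdir) / "per_bin_footprints.tsv",
                           sep="\t", index=False)


def stage_peaks(cfg: PipelineConfig, outdir: Path) -> None:
    track = _chip_track(outdir, "CTCF", cfg)
    uni = _class_genes(outdir, "uni")
    bi = _class_genes(outdir, "bi")
    uni_mat = footprints.window_matrix(track, uni, cfg.flank)
    bi_mat = footprints.window_matrix(track, bi, cfg.flank)
    segments = peaks.partition_segments(cfg.flank, cfg.n_segments)
    background = peaks.genomic_background(track)
    table = peaks.peak_prevalence_test(
        uni_mat, bi_mat, segments, background, cfg.fold_thresholds, cfg.alpha)
    table.to_csv(_tables(outdir) / "segments.tsv", sep="\t", index=False)


def stage_motif(cfg: PipelineConfig, outdir: Path) -> None:
    from Bio import SeqIO

    genes = _genes(outdir)
    ann = _annotation(outdir)
    fasta = _need(_data(outdir) / "genome.fa", "simulate")
    sequences = {rec.id: motifs.encode(str(rec.seq))
                 for rec in SeqIO.parse(str(fasta), "fasta")}
    _, pcm = motifs.read_jaspar(_need(_data(outdir) / "ctcf_motif.pcm",
                                      "simulate"))
    active_ids = set(ann.index[ann["active"]])
    active = [g for g in genes if g.gene_id in active_ids]
    regions = motifs.regions_from_genes(sequences, active, cfg.flank)
    hits = motifs.scan(motifs.PWM(pcm), regions, cfg.q_threshold)
    hits.to_csv(_tables(outdir) / "hits.tsv", sep="\t", index=False)

    uni = _class_genes(outdir, "uni")
    bi = _class_genes(outdir, "bi")
    cov_rows = []
    site_uni = None
    for cls, grp in (("uni", uni), ("bi", bi)):
        raw, smoothed, site = motifs.motif_coverage(
            hits, grp, cfg.flank, cfg.smooth_halfwidth)
        if cls == "uni":
            site_uni = site
        cov_rows.append(pd.DataFrame({
            "position": np.arange(-cfg.flank, cfg.flank + 1),
            "coverage": raw,
            "smoothed": smoothed,
            "group": cls,
            "motif_site": site if site is not None else np.nan,
        }))
    pd.concat(cov_rows).to_csv(_tables(outdir) / "motif_coverage.tsv",
                               sep="\t", index=False)

    if site_uni is None:
        logger.warning("no motif site in unidirectional genes; "
                       "skipping CTCF grouping")
        return
    ctcf_track = _chip_track(outdir, "CTCF", cfg)
    uni_mat = footprints.window_matrix(ctcf_track, uni, cfg.flank)
    groups = motifs.ctcf_group(uni, hits, site_uni, uni_mat,
                               cfg.min_ctcf_reads, cfg.motif_site_distance,
                               cfg.read_extension)
    groups.rename("group").to_csv(_tables(outdir) / "ctcf_groups.tsv", sep="\t",
                                  index_label="gene_id")
    ctcf_total = footprints.flank_signal(uni_mat)["total"]
    sums = {}
    for mark in _chip_marks(outdir):
        if mark == "CTCF":
            continue
        track = _chip_track(outdir, mark, cfg)
        sums[mark] = footprints.flank_signal(
            footprints.window_matrix(track, uni, cfg.flank))
    if min((groups == g).sum() for g in ("CTCF", "Non-CTCF")) >= 3 and sums:
        corr = motifs.correlation_matrix(ctcf_total, sums, groups)
        corr.to_csv(_tables(outdir) / "correlations.tsv", sep="\t", index=False)


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    genes = _genes(outdir)
    ann = _annotation(outdir)
    active_ids = set(ann.index[ann["active"]])
    active = [g for g in genes if g.gene_id in active_ids]
    mats = []
    ctcf_slice = None
    for i, mark in enumerate(("CTCF", "RAD21")):
        track = _chip_track(outdir, mark, cfg)
        mats.append(footprints.window_matrix(track, active, cfg.flank))
    features, slices = cooccurrence.feature_matrix(mats, cfg.cluster_bin_bp)
    result = cooccurrence.kmeans2(features, cfg.stage_seed("cluster"),
                                  cfg.n_restarts, ctcf_columns=slices[0])
    out = pd.DataFrame({
        "cluster": result.labels,
        "class_combined": ann.loc[result.labels.index, "class_combined"],
    })
    out.to_csv(_tables(outdir) / "clusters.tsv", sep="\t",
               index_label="gene_id")
    assoc = cooccurrence.association_test(result.labels, ann)
    t = assoc["table"]
    pd.DataFrame([{
        "cluster1_uni": t[0, 0], "cluster1_bi": t[0, 1],
        "cluster2_uni": t[1, 0], "cluster2_bi": t[1, 1],
        "cluster1_uni_pct": assoc["cluster1_uni_pct"],
        "cluster1_bi_pct": assoc["cluster1_bi_pct"],
        "p": assoc["p"],
    }]).to_csv(_tables(outdir) / "association.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "annotate": stage_annotate,
    "footprint": stage_footprint,
    "bins": stage_bins,
    "peaks": stage_peaks,
    "motif": stage_motif,
    "cluster": stage_cluster,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(stage: str, config: PipelineConfig, outdir: str | Path) -> dict:
    """Run one stage or 'all'; returns (and writes) the output manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r} (choose from {STAGES})")
    config.to_yaml(outdir / "config_resolved.yaml")
    timings = {}
    for name in stages:
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        _STAGE_FUNCS[name](config, outdir)
        timings[name] = round(time.perf_counter() - t0, 3)
    manifest = {"stages": list(stages), "seed": config.seed,
                "timings_s": timings, "tables": {}}
    tables_dir = outdir / "tables"
    if tables_dir.exists():
        for p in sorted(tables_dir.iterdir()):
            n_rows = sum(1 for _ in open(p)) - 1 if p.suffix == ".tsv" else None
            manifest["tables"][p.name] = {
                "rows": n_rows, "sha256": _checksum(p)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
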