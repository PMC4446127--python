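"""CAGE cluster thresholding and raw-tag counting around TSSs."""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval


def threshold_clusters(
    clusters: Sequence[GenomicInterval], max_n: int = 29857
) -> list[GenomicInterval]:
    """Keep clusters above the smallest score cutoff retaining <= ``max_n``.

    This is threshold semantics, not top-N sampling: all clusters tied at
    the chosen cutoff are kept or dropped as a whole, so the retained count
    can be below ``max_n`` when a tie group straddles the cap. Fewer
    clusters than ``max_n`` passes everything through unchanged.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if len(clusters) <= max_n:
        return list(clusters)
    scores = np.array([c.score for c in clusters])
    uniq = np.unique(scores)[::-1]  # descending candidate cutoffs
    counts = np.array([(scores >= t).sum() for t in uniq])
    ok = np.flatnonzero(counts <= max_n)
    if len(ok) == 0:
        return []
    t = uniq[ok[-1]]  # smallest cutoff still within the cap
    return [c for c in clusters if c.score >= t]


def tag_distance(tag: GenomicInterval, tss: int) -> int:
    """Absolute distance from a tag's 5' end to the TSS."""
    return abs(tag.five_prime - tss)


def count_tags(
    gene: GeneModel,
    tags: Sequence[GenomicInterval],
    window_bp: int,
    side: Literal["same_strand_near_tss", "opposite_strand_flank"],
) -> int:
    """Count raw tags whose 5' end lies within ``window_bp`` of the TSS.

    ``same_strand_near_tss`` counts tags on the gene's strand (expression
    proxy); ``opposite_strand_flank`` counts opposite-strand tags
    (antisense-transcription proxy). Distance bounds are inclusive.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    same = side == "same_strand_near_tss"
    if side not in ("same_strand_near_tss", "opposite_strand_flank"):
        raise ValueError(f"unknown side {side!r}")
    n = 0
    for t in tags:
        if t.chrom != gene.chrom:
            continue
        strand_ok = (t.strand == gene.strand) if same else (t.strand != gene.strand)
        if strand_ok and tag_distance(t, gene.tss) <= window_bp:
            n += 1
    return n


def count_tags_table(
    genes: Sequence[GeneModel],
    tags: Sequence[GenomicInterval],
    window_bp: int,
    side: Literal["same_strand_near_tss", "opposite_strand_flank"],
) -> dict[str, int]:
    """Vectorized :func:`count_tags` over a gene set (same semantics)."""
    same = side == "same_strand_near_tss"
    # sorted 5' positions per (chrom, strand)
    index: dict[tuple[str, str], np.ndarray] = {}
    for t in tags:
        index.setdefault((t.chrom, t.strand), []).append(t.five_prime)  # type: ignore
    index = {k: np.sort(np.asarray(v)) for k, v in index.items()}
    out: dict[str, int] = {}
    for g in genes:
        if same:
            strands = [g.strand]
        else:
            strands = [s for s in ("+", "-", ".") if s != g.strand]
        total = 0
        for s in strands:
            pos = index.get((g.chrom, s))
            if pos is None:
                continue
            lo = np.searchsorted(pos, g.tss - window_bp, side="left")
            hi = np.searchsorted(pos, g.tss + window_bp, side="right")
            total += int(hi - lo)
        out[g.gene_id] = total
    return out
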