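"""Interval I/O and per-base coverage tracks.

All coordinates are 0-based half-open (BED convention). Reads are turned
into nucleosome-length occupancy by replacing each read with a 147-bp
interval anchored at its 5' end; coverage is the per-base count of
occupying fragments, clipped at chromosome bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: nucleosome-length fragment used to extend ChIP-seq reads
NUCLEOSOME_BP = 147


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, scored genomic interval (BED6 semantics).

    ``block_sizes``/``block_starts`` carry BED12 block structure for gapped
    alignments; they are ``None`` for plain BED6 records.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    block_sizes: tuple[int, ...] | None = None
    block_starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most base (strand-aware; '.' treated as '+')."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its canonical TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


def read_bed(path: str | Path, columns: int = 6) -> list[GenomicInterval]:
    """Read a BED6 or BED12 file into intervals (file order preserved)."""
    if columns not in (6, 12):
        raise ValueError("columns must be 6 or 12")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < columns:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {columns} columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            blocks = None, None
            if columns == 12:
                n_blocks = int(fields[9])
                sizes = tuple(int(x) for x in fields[10].rstrip(",").split(","))
                starts = tuple(int(x) for x in fields[11].rstrip(",").split(","))
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ValueError(f"{path}:{lineno}: inconsistent block count")
                blocks = sizes, starts
            try:
                out.append(
                    GenomicInterval(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        name=fields[3],
                        score=float(fields[4]),
                        strand=fields[5],
                        block_sizes=blocks[0],
                        block_starts=blocks[1],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as BED6, or BED12 when block structure is present."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name, str(score), iv.strand]
            if iv.block_sizes is not None:
                row += [
                    str(iv.start),
                    str(iv.end),
                    "0",
                    str(len(iv.block_sizes)),
                    ",".join(map(str, iv.block_sizes)),
                    ",".join(map(str, iv.block_starts)),
                ]
            fh.write("\t".join(row) + "\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV with header gene_id/chrom/strand/tss."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "chrom", "strand", "tss"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                genes.append(
                    GeneModel(
                        gene_id=f[idx["gene_id"]],
                        chrom=f[idx["chrom"]],
                        strand=f[idx["strand"]],
                        tss=int(f[idx["tss"]]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene_id")
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def split_gapped(record: GenomicInterval) -> list[GenomicInterval]:
    """Expand a gapped (BED12) alignment into one ungapped interval per block."""
    if record.block_sizes is None:
        return [GenomicInterval(record.chrom, record.start, record.end,
                                record.name, record.score, record.strand)]
    out = []
    for size, offset in zip(record.block_sizes, record.block_starts):
        s = record.start + offset
        e = s + size
        if e > record.end:
            raise ValueError(
                f"block [{s},{e}) extends past record end {record.end}"
            )
        out.append(GenomicInterval(record.chrom, s, e, record.name,
                                   record.score, record.strand))
    return out


class CoverageTrack:
    """Dense per-base read depth per chromosome, optionally per strand.

    ``data`` maps ``chrom`` (unstranded) or ``(chrom, strand)`` (stranded)
    to an int64 depth vector of the chromosome length.
    """

    def __init__(self, chrom_lengths: Mapping[str, int], stranded: bool = False):
        self.chrom_lengths = dict(chrom_lengths)
        self.stranded = stranded
        self.data: dict = {}
        if stranded:
            for chrom, n in self.chrom_lengths.items():
                for strand in ("+", "-"):
                    self.data[(chrom, strand)] = np.zeros(n, dtype=np.int64)
        else:
            for chrom, n in self.chrom_lengths.items():
                self.data[chrom] = np.zeros(n, dtype=np.int64)

    @property
    def total_mass(self) -> int:
        return int(sum(int(v.sum()) for v in self.data.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def mean_depth(self) -> float:
        """Genome-wide average per-base depth (both strands pooled)."""
        if self.genome_length == 0:
            raise ValueError("zero-length genome")
        return self.total_mass / self.genome_length

    def _vector(self, chrom: str, strand: str | None) -> np.ndarray:
        if self.stranded:
            if strand is None:
                raise ValueError("stranded track requires a strand")
            return self.data[(chrom, strand)]
        return self.data[chrom]

    def window(self, chrom: str, start: int, end: int,
               strand: str | None = None) -> np.ndarray:
        """Depth over [start, end); out-of-bounds positions read as zero."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.chrom_lengths[chrom]
        vec = self._vector(chrom, strand)
        out = np.zeros(end - start, dtype=np.int64)
        lo, hi = max(start, 0), min(end, n)
        if lo < hi:
            out[lo - start:hi - start] = vec[lo:hi]
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        """Export non-zero runs as bedGraph (strand appended to chrom name)."""
        with open(path, "w") as fh:
            for key, vec in sorted(self.data.items(), key=str):
                name = key if isinstance(key, str) else f"{key[0]}{key[1]}"
                breaks = np.flatnonzero(np.diff(vec)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(vec)]))
                for s, e in zip(starts, ends):
                    v = int(vec[s])
                    if v:
                        fh.write(f"{name}\t{s}\t{e}\t{v}\n")


def build_coverage(
    reads: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    extension_bp: int | None = NUCLEOSOME_BP,
    stranded: bool = False,
) -> CoverageTrack:
    """Pile reads into a :class:`CoverageTrack`.

    Each read is replaced by an ``extension_bp`` fragment anchored at its 5'
    end (``[start, start+ext)`` for + reads, ``[end-ext, end)`` for − reads),
    clipped to the chromosome; ``extension_bp=None`` keeps the read's own
    extent (used for RNA-seq blocks).
    """
    if extension_bp is not None and extension_bp < 1:
        raise ValueError("extension_bp must be >= 1")
    track = CoverageTrack(chrom_lengths, stranded=stranded)
    # difference arrays, cumulative-summed once per chromosome at the end
    diffs = {k: np.zeros(len(v) + 1, dtype=np.int64)
             for k, v in track.data.items()}
    for r in reads:
        if r.chrom not in chrom_lengths:
            raise KeyError(f"read on unknown chromosome {r.chrom!r}")
        n = chrom_lengths[r.chrom]
        if extension_bp is None:
            s, e = r.start, r.end
        elif r.strand == "-":
            s, e = r.end - extension_bp, r.end
        else:
            s, e = r.start, r.start + extension_bp
        s, e = max(s, 0), min(e, n)
        if s >= e:
            continue
        key = (r.chrom, r.strand) if stranded else r.chrom
        if stranded and r.strand not in ("+", "-"):
            raise ValueError("stranded coverage requires stranded reads")
        diffs[key][s] += 1
        diffs[key][e] -= 1
    for key, d in diffs.items():
        track.data[key] = np.cumsum(d[:-1])
    return track
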