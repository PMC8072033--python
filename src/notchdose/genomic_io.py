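"""Genomic interval arithmetic and plain-text format I/O.

Coordinates are 0-based half-open throughout (BED convention); the midpoint of
``[start, end)`` is ``floor((start + end) / 2)``.  Browser-style 1-based
listings must be converted by the caller (subtract 1 from the start).

Formats handled: BED3/BED6, bedGraph (binned cut counts), FASTA (promoter
sequences), and TSV TSS tables.  All readers tolerate comment lines starting
with ``#`` or ``track``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import ParseError

PROMOTER_HALF_WIDTH = 1000  # bp each side of the TSS; promoter window = 2 kb


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class PromoterRecord:
    """A gene promoter: the 2-kb window centred on the 5'-most TSS.

    The window is strand-independent, ``[TSS - 1000, TSS + 1000)``; the
    sequence is optional until attached from a FASTA.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str = "."
    sequence: str | None = None
    window: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if self.tss < PROMOTER_HALF_WIDTH:
            raise ValueError(
                f"TSS {self.tss} of {self.gene_id} closer than "
                f"{PROMOTER_HALF_WIDTH} bp to the contig start"
            )
        self.window = GenomicInterval(
            self.chrom,
            self.tss - PROMOTER_HALF_WIDTH,
            self.tss + PROMOTER_HALF_WIDTH,
            id=self.gene_id,
            strand=self.strand,
        )
        if self.sequence is not None and len(self.sequence) != len(self.window):
            raise ValueError(
                f"promoter sequence of {self.gene_id} has length "
                f"{len(self.sequence)}, expected {len(self.window)}"
            )

    def with_sequence(self, sequence: str) -> "PromoterRecord":
        return PromoterRecord(self.gene_id, self.chrom, self.tss, self.strand, sequence)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving file order."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0 or start >= end:
            raise ParseError(
                f"{path}:{lineno}: invalid coordinates {chrom}:{start}-{end}"
            )
        name = fields[3] if len(fields) > 3 else f"region_{len(intervals)}"
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        intervals.append(GenomicInterval(chrom, start, end, id=name, strand=strand))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


def read_bedgraph_matrix(
    paths: Mapping[str, str | Path],
    regions: Sequence[GenomicInterval],
    bin_size: int,
) -> dict[str, np.ndarray]:
    """Read per-sample bedGraphs into (n_regions, n_bins) count matrices.

    bedGraph intervals must align to the bin grid anchored at each region
    start (they may span several bins with a constant value).  Missing bins
    are 0.  Overlapping lines within a region are rejected: summing would
    silently mask a data bug.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    lengths = {len(r) for r in regions}
    if len(lengths) > 1:
        raise ValueError("regions must share a common length")
    n_bins = (lengths.pop() // bin_size) if regions else 0

    out: dict[str, np.ndarray] = {}
    for sample, path in paths.items():
        path = Path(path)
        by_chrom: dict[str, list[tuple[int, int, float, int]]] = {}
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            by_chrom.setdefault(fields[0], []).append((start, end, value, lineno))

        mat = np.zeros((len(regions), n_bins), dtype=float)
        for ri, region in enumerate(regions):
            covered = np.zeros(n_bins, dtype=bool)
            for start, end, value, lineno in by_chrom.get(region.chrom, ()):
                if end <= region.start or start >= region.end:
                    continue
                if (start - region.start) % bin_size or (end - region.start) % bin_size:
                    raise ParseError(
                        f"{path}:{lineno}: interval {region.chrom}:{start}-{end} "
                        f"does not align to the {bin_size}-bp grid of region {region.id}"
                    )
                b0 = max(0, (start - region.start) // bin_size)
                b1 = min(n_bins, (end - region.start) // bin_size)
                if covered[b0:b1].any():
                    raise ParseError(
                        f"{path}:{lineno}: interval {region.chrom}:{start}-{end} "
                        f"overlaps an earlier line within region {region.id}"
                    )
                covered[b0:b1] = True
                mat[ri, b0:b1] = value
        out[sample] = mat
    return out


def write_bedgraph(
    matrix: np.ndarray,
    regions: Sequence[GenomicInterval],
    bin_size: int,
    path: str | Path,
) -> None:
    """Write one sample's binned counts as bedGraph; zero bins are omitted."""
    with open(path, "w") as fh:
        for region, row in zip(regions, matrix):
            nz = np.nonzero(row)[0]
            for b in nz:
                s = region.start + int(b) * bin_size
                v = row[b]
                text = f"{v:g}" if v != int(v) else str(int(v))
                fh.write(f"{region.chrom}\t{s}\t{s + bin_size}\t{text}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence map; uppercased, U normalised to T."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper().replace("U", "T")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tss_table(path: str | Path) -> list[PromoterRecord]:
    """Read a TSV TSS table (gene_id, chrom, tss, strand) into promoter records.

    One row per gene: multi-TSS genes are expected to have been collapsed
    upstream to the 5'-most TSS of their protein-coding transcripts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: TSS table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    return [
        PromoterRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(promoters: Sequence[PromoterRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in promoters],
            "chrom": [p.chrom for p in promoters],
            "tss": [p.tss for p in promoters],
            "strand": [p.strand for p in promoters],
        }
    ).to_csv(path, sep="\t", index=False)


def assign_dhs_to_promoters(
    dhs: Sequence[GenomicInterval],
    promoters: Sequence[PromoterRecord],
) -> list[tuple[str, str]]:
    """Assign DHS regions to promoters by midpoint containment.

    A (dhs_id, gene_id) pair is emitted iff the DHS midpoint lies within the
    promoter window ``[TSS - 1000, TSS + 1000)``.  A DHS may hit several genes
    and vice versa.  Output is sorted by DHS input order, then gene_id.
    """
    trees: dict[str, IntervalTree] = {}
    for prom in promoters:
        trees.setdefault(prom.chrom, IntervalTree()).addi(
            prom.window.start, prom.window.end, prom.gene_id
        )
    pairs: list[tuple[str, str]] = []
    for region in dhs:
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        hits = sorted(hit.data for hit in tree.at(region.midpoint))
        pairs.extend((region.id, gene_id) for gene_id in hits)
    return pairs
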