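"""Alignment and track I/O for small-RNA, degradome and mRNA libraries.

All internal coordinates are 0-based half-open (BED convention). Printed
1-based coordinates from locus annotations are converted at the boundary.
The biological 5' end of an aligned read is its ``start`` on the plus
strand and ``end - 1`` on the minus strand.

Supported formats: BED6 (primary), a minimal unspliced SAM subset (via
pysam), and bedGraph for per-coordinate tracks. Read multiplicities are
carried in the BED score column (and an ``XC`` integer tag in SAM) so a
read group occupies a single record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "AlignedRead",
    "GenomicInterval",
    "LibraryStats",
    "five_prime_coordinate",
    "read_alignments",
    "read_bed",
    "read_sam",
    "write_bed",
    "write_sam",
    "write_track",
    "read_track",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, coord: int) -> bool:
        return chrom == self.chrom and self.start <= coord < self.end


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read group: placement, strand, and multiplicity.

    ``count`` is the number of identical reads collapsed into this record;
    sRNA and degradome alignments are unspliced, so the read length equals
    the genomic footprint ``end - start``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1
    library: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"read end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count < 0:
            raise ValueError("read count must be >= 0")

    @property
    def read_length(self) -> int:
        return self.end - self.start


def five_prime_coordinate(read: AlignedRead) -> int:
    """Genomic coordinate of the read's biological 5' end."""
    return read.start if read.strand == "+" else read.end - 1


@dataclass
class LibraryStats:
    """Per-library totals used as RPM/FPKM denominators."""

    total_mapped: int = 0
    per_length_totals: dict[int, int] = field(default_factory=dict)

    def add(self, read: AlignedRead) -> None:
        self.total_mapped += read.count
        length = read.read_length
        self.per_length_totals[length] = (
            self.per_length_totals.get(length, 0) + read.count
        )

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "LibraryStats":
        stats = cls()
        for read in reads:
            stats.add(read)
        return stats


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, library: str = "") -> tuple[list[AlignedRead], LibraryStats]:
    """Parse a BED6 file of read groups (count in the score column)."""
    reads: list[AlignedRead] = []
    stats = LibraryStats()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end, count = int(start_s), int(end_s), int(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate or count") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                read = AlignedRead(chrom, start, end, strand, count, library, name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            reads.append(read)
            stats.add(read)
    return reads, stats


def write_bed(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(
                f"{read.chrom}\t{read.start}\t{read.end}\t{read.name}"
                f"\t{read.count}\t{read.strand}\n"
            )


# ---------------------------------------------------------------------------
# Minimal SAM subset (unspliced, match-only CIGAR)
# ---------------------------------------------------------------------------

def write_sam(
    reads: Sequence[AlignedRead],
    path: str | Path,
    references: Mapping[str, int],
) -> None:
    """Write read groups as unspliced SAM records (count in tag ``XC``)."""
    header = pysam.AlignmentHeader.from_references(
        list(references.keys()), list(references.values())
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name if read.name != "." else f"rg{i}"
            seg.reference_name = read.chrom
            seg.reference_start = read.start
            seg.cigarstring = f"{read.read_length}M"
            seg.flag = 16 if read.strand == "-" else 0
            seg.mapping_quality = 255
            seg.query_sequence = "N" * read.read_length
            seg.set_tag("XC", int(read.count))
            out.write(seg)


def read_sam(path: str | Path, library: str = "") -> tuple[list[AlignedRead], LibraryStats]:
    """Parse the minimal SAM subset; spliced or clipped alignments are rejected."""
    reads: list[AlignedRead] = []
    stats = LibraryStats()
    with pysam.AlignmentFile(str(path), "r") as handle:
        for seg in handle:
            if seg.is_unmapped:
                continue
            if seg.cigartuples is None or any(op != 0 for op, _ in seg.cigartuples):
                raise ValueError(
                    f"{path}: read {seg.query_name!r} has non-match CIGAR "
                    f"{seg.cigarstring!r}; only unspliced alignments are supported"
                )
            count = int(seg.get_tag("XC")) if seg.has_tag("XC") else 1
            read = AlignedRead(
                chrom=seg.reference_name,
                start=seg.reference_start,
                end=seg.reference_end,
                strand="-" if seg.is_reverse else "+",
                count=count,
                library=library,
                name=seg.query_name,
            )
            reads.append(read)
            stats.add(read)
    return reads, stats


def read_alignments(
    path: str | Path, format: str = "bed", library: str = ""
) -> tuple[list[AlignedRead], LibraryStats]:
    """Read an alignment file in the named dialect (``bed`` or ``sam_subset``)."""
    if format == "bed":
        return read_bed(path, library)
    if format in ("sam", "sam_subset"):
        return read_sam(path, library)
    raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_track(
    values: Mapping[int, float],
    path: str | Path,
    chrom: str = "chr1",
    precision: int = 6,
) -> None:
    """Write a per-coordinate track as bedGraph, merging runs of equal value.

    Coordinates absent from ``values`` are not written (treated as gaps, not
    zeros), so a write/read round trip reproduces the input mapping exactly
    at the stated precision.
    """
    with open(path, "w") as handle:
        handle.write(f'track type=bedGraph name="{chrom}"\n')
        if not values:
            return
        coords = sorted(values)
        for coord in coords:
            value = values[coord]
            if not math.isfinite(value):
                raise ValueError(f"non-finite track value at {coord}: {value!r}")
        run_start = prev = coords[0]
        run_value = round(values[run_start], precision)
        for coord in coords[1:]:
            value = round(values[coord], precision)
            if coord == prev + 1 and value == run_value:
                prev = coord
                continue
            handle.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value:.{precision}g}\n")
            run_start = prev = coord
            run_value = value
        handle.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value:.{precision}g}\n")


def read_track(path: str | Path) -> dict[int, float]:
    """Read a bedGraph file back into a coordinate -> value mapping."""
    values: dict[int, float] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            _, start_s, end_s, value_s = fields
            start, end, value = int(start_s), int(end_s), float(value_s)
            for coord in range(start, end):
                if coord in values:
                    warnings.warn(f"{path}:{lineno}: duplicate coordinate {coord}")
                values[coord] = value
    return values
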