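"""Library-level summaries and locus-level small-RNA abundance.

Abundances are reads per million mapped reads (RPM), with the denominator
being the library's total genome-mapped reads of all lengths. Reads are
attributed to positions by their biological 5' end. Includes a simplified
neighbor-coverage allocator for multimapping reads: each multiread's count
is split across its candidate placements in proportion to unique-read
coverage in a window around each placement (a one-pass rendition of the
coverage-guided principle used by full sRNA aligners, not their iterative
machinery).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align_io import AlignedRead, GenomicInterval, LibraryStats, five_prime_coordinate

__all__ = [
    "length_distribution",
    "bin_quantify",
    "allocate_multimappers",
    "locus_abundance",
]


def _rpm(stats: LibraryStats) -> float:
    if stats.total_mapped <= 0:
        raise ValueError("library has no mapped reads; RPM undefined")
    return 1e6 / stats.total_mapped


def length_distribution(
    reads: Iterable[AlignedRead],
    stats: LibraryStats,
    lengths: Sequence[int] = range(18, 27),
) -> dict[int, float]:
    """RPM of reads of each length in ``lengths`` (default 18-26 nt)."""
    factor = _rpm(stats)
    totals = {length: 0.0 for length in lengths}
    for read in reads:
        if read.read_length in totals:
            totals[read.read_length] += read.count
    return {length: count * factor for length, count in totals.items()}


def bin_quantify(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    bin_size: int = 100,
    stats: LibraryStats | None = None,
) -> pd.Series:
    """RPM of 5' ends per fixed-size bin tiling the region.

    Each read contributes its count to exactly the bin containing its 5'
    end; bins are indexed by their start coordinate and tile the region
    without overlap (the last bin may be short).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    factor = _rpm(stats) if stats is not None else 1.0
    starts = range(region.start, region.end, bin_size)
    totals = pd.Series(0.0, index=list(starts), name="rpm")
    for read in reads:
        coord = five_prime_coordinate(read)
        if not region.contains(read.chrom, coord):
            continue
        bin_start = region.start + (coord - region.start) // bin_size * bin_size
        totals[bin_start] += read.count * factor
    return totals


def allocate_multimappers(
    multireads: Mapping[str, Sequence[tuple[str, int]]],
    unique_coverage: Mapping[tuple[str, int], float],
    window: int = 250,
    counts: Mapping[str, float] | None = None,
) -> dict[str, list[float]]:
    """Split each multiread's count across placements by local unique coverage.

    ``multireads`` maps a read id to its candidate placements as
    (chrom, 5'-end coordinate) pairs; ``unique_coverage`` maps positions to
    uniquely-mapped read counts. Each placement is weighted by the summed
    unique coverage within +/-``window`` nt; if every neighborhood is empty
    the count is split uniformly. The returned fractional counts for a read
    always sum exactly to its total (default 1.0 per read, or
    ``counts[read_id]``).
    """
    allocations: dict[str, list[float]] = {}
    for read_id, placements in multireads.items():
        if not placements:
            raise ValueError(f"multiread {read_id!r} has no candidate placements")
        total = 1.0 if counts is None else float(counts[read_id])
        weights = []
        for chrom, coord in placements:
            weights.append(
                sum(
                    unique_coverage.get((chrom, pos), 0.0)
                    for pos in range(coord - window, coord + window + 1)
                )
            )
        weight_sum = sum(weights)
        if weight_sum > 0:
            fractions = [total * w / weight_sum for w in weights]
        else:
            fractions = [total / len(placements)] * len(placements)
        # exact conservation: absorb float residue into the largest share
        residue = total - sum(fractions)
        if fractions and residue != 0.0:
            i = max(range(len(fractions)), key=fractions.__getitem__)
            fractions[i] += residue
        allocations[read_id] = fractions
    return allocations


def locus_abundance(
    reads: Iterable[AlignedRead],
    locus: GenomicInterval,
    stats: LibraryStats,
    read_length: int | None = None,
) -> float:
    """RPM of reads whose 5' end lies in the locus, optionally one length.

    The phasing analysis conventionally restricts to 21-nt reads
    (``read_length=21``); pass ``None`` for all lengths.
    """
    factor = _rpm(stats)
    total = 0.0
    for read in reads:
        if read_length is not None and read.read_length != read_length:
            continue
        if locus.contains(read.chrom, five_prime_coordinate(read)):
            total += read.count
    return total * factor
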