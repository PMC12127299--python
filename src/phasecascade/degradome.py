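"""Degradome 5'-end quantification and the cleavage-efficiency statistic.

Degradome (PARE) reads mark uncapped transcript 5' ends; a spike of read
5' ends exactly at a predicted scissile coordinate evidences miRISC
cleavage there. The central statistic is

    cleavage efficiency = degradome RPM at the scissile site
                          / full-length transcript FPKM,

the per-library ratio of cleaved-fragment production to the standing pool
of intact transcripts. Efficiencies are arbitrary-scaled (RPM/FPKM); only
ratios and within-study comparisons are meaningful. Condition differences
are tested with Fisher's exact test on pooled site counts and a one-sided
Welch t-test on replicate efficiency vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .align_io import AlignedRead, GenomicInterval, LibraryStats, five_prime_coordinate
from .phasing import CYCLE, PhasingConfig, RegisterProfile

__all__ = [
    "CleavageSiteQuant",
    "five_prime_profile",
    "site_cleavage_rpm",
    "transcript_fpkm",
    "cleavage_efficiency",
    "replicate_efficiencies",
    "fisher_cleavage_test",
    "efficiency_difference_test",
    "degradome_radial",
]


def five_prime_profile(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    stats: LibraryStats,
) -> dict[int, float]:
    """RPM of degradome 5' ends per coordinate in the region.

    Zero-count coordinates are omitted; the summed profile therefore equals
    1e6 * (in-region reads) / (library total).
    """
    if stats.total_mapped <= 0:
        raise ValueError("library has no mapped reads; RPM undefined")
    factor = 1e6 / stats.total_mapped
    profile: dict[int, float] = {}
    for read in reads:
        coord = five_prime_coordinate(read)
        if region.contains(read.chrom, coord):
            profile[coord] = profile.get(coord, 0.0) + read.count * factor
    return profile


def site_cleavage_rpm(
    profile: Mapping[int, float], site: int, slop: int = 0
) -> float:
    """Degradome RPM of 5' ends aligning with the site.

    Exact-coordinate matching by default; ``slop`` widens the match to
    +/-slop nt (a permissive option, off in the reference usage).
    """
    return sum(profile.get(site + d, 0.0) for d in range(-slop, slop + 1))


def transcript_fpkm(
    mrna_fragments: Iterable[AlignedRead],
    transcript: GenomicInterval,
    stats: LibraryStats,
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    A fragment counts toward the transcript if its alignment overlaps the
    transcript interval.
    """
    if transcript.length <= 0:
        raise ValueError("transcript length must be positive")
    if stats.total_mapped <= 0:
        raise ValueError("library has no mapped fragments; FPKM undefined")
    on_transcript = sum(
        read.count
        for read in mrna_fragments
        if read.chrom == transcript.chrom
        and read.start < transcript.end
        and read.end > transcript.start
    )
    return on_transcript * 1e9 / (stats.total_mapped * transcript.length)


def cleavage_efficiency(site_rpm: float, fpkm: float) -> float | None:
    """Site RPM / transcript FPKM; ``None`` (missing) when FPKM is zero.

    A zero denominator leaves the ratio undefined — it is reported as
    missing (never 0 or infinity) and propagates as missing through group
    tests.
    """
    if fpkm < 0 or site_rpm < 0:
        raise ValueError("RPM and FPKM must be >= 0")
    if fpkm == 0:
        warnings.warn("transcript FPKM is 0; cleavage efficiency undefined")
        return None
    return site_rpm / fpkm


def replicate_efficiencies(
    site_rpms: Sequence[float], fpkms: Sequence[float]
) -> list[float | None]:
    """Replicate-wise efficiencies with missing values propagated."""
    if len(site_rpms) != len(fpkms):
        raise ValueError("replicate vectors differ in length")
    return [cleavage_efficiency(r, f) for r, f in zip(site_rpms, fpkms)]


@dataclass
class CleavageSiteQuant:
    """Everything measured at one scissile site, replicate-wise."""

    site: int
    site_counts: list[int]
    library_totals: list[int]
    degradome_rpm: list[float]
    transcript_fpkm: list[float]

    @property
    def efficiency(self) -> list[float | None]:
        return replicate_efficiencies(self.degradome_rpm, self.transcript_fpkm)


def fisher_cleavage_test(
    counts_a: int, total_a: int, counts_b: int, total_b: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of site counts between two libraries.

    The 2x2 table is [site reads, remaining library reads] per condition;
    replicates are pooled before testing (an exact test needs counts, and a
    single table is the only construction giving one p per comparison).
    Returns (odds ratio, two-sided p). Degenerate margins give p = 1.
    """
    for count, total in ((counts_a, total_a), (counts_b, total_b)):
        if not 0 <= count <= total:
            raise ValueError("need totals >= counts >= 0")
    table = np.array(
        [[counts_a, total_a - counts_a], [counts_b, total_b - counts_b]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin; Fisher p fixed at 1")
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def efficiency_difference_test(
    effs_a: Sequence[float | None],
    effs_b: Sequence[float | None],
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Welch t-test on replicate cleavage efficiencies.

    ``alternative="greater"`` tests whether group A exceeds group B.
    Missing efficiencies (undefined ratios) are dropped, not imputed; at
    least two defined replicates per group are required.
    """
    a = [e for e in effs_a if e is not None]
    b = [e for e in effs_b if e is not None]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 defined replicate efficiencies per group")
    result = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(result.statistic), float(result.pvalue)


def degradome_radial(
    profile: Mapping[int, float], anchor: int, cycle: int = CYCLE
) -> RegisterProfile:
    """Degradome RPM summed per register of the anchor.

    Same anchoring convention as the sRNA radial profiles: with the anchor
    one nucleotide 5' of the cleavable scissile coordinate, trigger-guided
    cleavage appears on spoke 2.
    """
    abundance = np.zeros(cycle)
    for coord, rpm in profile.items():
        abundance[(coord - anchor) % cycle] += rpm
    return RegisterProfile(abundance, anchor=anchor, strand_policy="sense", cycle=cycle)
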