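"""Sliding-window phasing scores and register ("radial") profiles.

Phased siRNA 5' ends recur every 21 nt, so each coordinate is assigned a
cyclic register 1..21 relative to an anchor. A sliding 189-nt window (nine
complete 21-nt cycles) walks the region in 1-nt steps; for each window the
score rewards concentration of 5'-end abundance in the window-start
register across many cycle positions:

    score = ln[(1 + 10 * P / (1 + U)) ** (k - 2)]   for k >= 3, else 0

with P the in-register abundance (RPM), U the out-of-register abundance,
and k the number of occupied in-register cycle positions. Coordinates whose
score exceeds a threshold (150 in the reference usage) are called phased.

Duplex partners on the antisense strand carry a 2-nt 3' overhang; under the
``merged`` strand policy antisense alignment starts are shifted +2 before
register assignment, which places both strands of a duplex in the same
register and doubles the occupancy ceiling (k_max 18).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .align_io import AlignedRead, GenomicInterval, LibraryStats

__all__ = [
    "CYCLE",
    "PhasingConfig",
    "RegisterProfile",
    "PhasingTrack",
    "assign_register",
    "register_offset",
    "phasing_score",
    "window_phasing_score",
    "phasing_track",
    "register_radial",
    "dominant_registers",
    "matched_coordinate_test",
]

CYCLE = 21


@dataclass(frozen=True)
class PhasingConfig:
    """Tunable conventions of the phasing analysis.

    ``strand_policy``: ``"merged"`` folds antisense reads onto the sense
    register via the duplex-overhang correction (start + 2); ``"sense"``
    uses plus-strand reads only. ``min_covered_positions`` is the window
    coverage threshold: number of distinct occupied 5'-end positions a
    window needs before a score is computed. ``score_numerator`` selects the
    damped (``10*P/(1+U)``, default) or raw (``10*P``) numerator variant.
    """

    cycle: int = CYCLE
    cycles_per_window: int = 9
    strand_policy: str = "merged"  # "merged" | "sense"
    min_covered_positions: int = 10
    threshold: float = 150.0
    score_numerator: str = "damped"  # "damped" | "raw"
    read_lengths: tuple[int, ...] = (21,)

    def __post_init__(self) -> None:
        if self.strand_policy not in ("merged", "sense"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")
        if self.score_numerator not in ("damped", "raw"):
            raise ValueError(f"unknown score_numerator {self.score_numerator!r}")
        if self.cycle < 2 or self.cycles_per_window < 1:
            raise ValueError("cycle and cycles_per_window must be positive")

    @property
    def window_length(self) -> int:
        return self.cycle * self.cycles_per_window


def assign_register(position: int, anchor: int, cycle: int = CYCLE) -> int:
    """Cyclic register 1..cycle of a coordinate relative to the anchor."""
    return (position - anchor) % cycle + 1


def register_offset(r_from: int, r_to: int, cycle: int = CYCLE) -> int:
    """Cyclic offset (0..cycle-1) from one register to another."""
    for r in (r_from, r_to):
        if not 1 <= r <= cycle:
            raise ValueError(f"register {r} outside 1..{cycle}")
    return (r_to - r_from) % cycle


def phasing_score(P: float, U: float, k: int, numerator: str = "damped") -> float:
    """Window score from phased abundance P, unphased U and occupancy k."""
    if k < 3 or P <= 0:
        return 0.0
    ratio = 10.0 * P / (1.0 + U) if numerator == "damped" else 10.0 * P
    return (k - 2) * math.log1p(ratio)


def _phase_coordinates(
    reads: Iterable[AlignedRead], cfg: PhasingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct (phase coordinate, strand) groups with summed counts.

    The phase coordinate of a plus-strand read is its 5' end (= start);
    under the merged policy a minus-strand read contributes at start + 2,
    the duplex-overhang correction that co-registers it with its sense
    partner. Under the sense policy minus-strand reads are dropped.
    """
    grouped: dict[tuple[int, int], float] = {}
    for read in reads:
        if cfg.read_lengths and read.read_length not in cfg.read_lengths:
            continue
        if read.strand == "+":
            key = (read.start, 0)
        elif cfg.strand_policy == "merged":
            key = (read.start + 2, 1)
        else:
            continue
        grouped[key] = grouped.get(key, 0.0) + read.count
    if not grouped:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty
    keys = sorted(grouped)
    coords = np.array([k[0] for k in keys], dtype=int)
    strands = np.array([k[1] for k in keys], dtype=int)
    counts = np.array([grouped[k] for k in keys], dtype=float)
    return coords, strands, counts


def _rpm_factor(stats: LibraryStats | None) -> float:
    if stats is None:
        return 1.0
    if stats.total_mapped <= 0:
        raise ValueError("library has no mapped reads; RPM undefined")
    return 1e6 / stats.total_mapped


def window_phasing_score(
    reads: Iterable[AlignedRead],
    window_start: int,
    cfg: PhasingConfig = PhasingConfig(),
    stats: LibraryStats | None = None,
) -> float:
    """Score one window anchored (register 1) at its start coordinate."""
    coords, strands, counts = _phase_coordinates(reads, cfg)
    counts = counts * _rpm_factor(stats)
    return _score_window(coords, strands, counts, window_start, cfg)


def _score_window(
    coords: np.ndarray,
    strands: np.ndarray,
    rpm: np.ndarray,
    window_start: int,
    cfg: PhasingConfig,
) -> float:
    inside = (coords >= window_start) & (coords < window_start + cfg.window_length)
    if not inside.any():
        return 0.0
    in_register = inside & ((coords - window_start) % cfg.cycle == 0)
    P = float(rpm[in_register].sum())
    U = float(rpm[inside & ~in_register].sum())
    k = int(in_register.sum())  # distinct occupied (coordinate, strand) groups
    return phasing_score(P, U, k, cfg.score_numerator)


@dataclass
class PhasingTrack:
    """Per-coordinate phasing scores and above-threshold calls."""

    scores: dict[int, float]
    threshold: float
    config: PhasingConfig

    @property
    def calls(self) -> list[int]:
        return sorted(c for c, s in self.scores.items() if s > self.threshold)


def phasing_track(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    cfg: PhasingConfig = PhasingConfig(),
    stats: LibraryStats | None = None,
) -> PhasingTrack:
    """Slide the window in 1-nt steps across the region and score each start.

    A score is recorded only for windows meeting the coverage threshold
    (``min_covered_positions`` distinct occupied positions); calls use
    strict inequality score > threshold.
    """
    if region.length < cfg.window_length:
        raise ValueError(
            f"region of {region.length} nt is shorter than one "
            f"{cfg.window_length}-nt window"
        )
    region_reads = [r for r in reads if r.chrom == region.chrom]
    coords, strands, counts = _phase_coordinates(region_reads, cfg)
    rpm = counts * _rpm_factor(stats)
    scores: dict[int, float] = {}
    for start in range(region.start, region.end - cfg.window_length + 1):
        inside = (coords >= start) & (coords < start + cfg.window_length)
        if int(inside.sum()) < cfg.min_covered_positions:
            continue
        scores[start] = _score_window(coords, strands, rpm, start, cfg)
    return PhasingTrack(scores=scores, threshold=cfg.threshold, config=cfg)


@dataclass
class RegisterProfile:
    """Abundance (RPM) summed into the 21 cyclic registers of an anchor."""

    abundance: np.ndarray  # shape (cycle,), index r-1
    anchor: int
    strand_policy: str
    cycle: int = CYCLE

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (self.cycle,):
            raise ValueError(f"profile needs exactly {self.cycle} entries")
        if (self.abundance < 0).any():
            raise ValueError("register abundances must be >= 0")

    def __getitem__(self, register: int) -> float:
        if not 1 <= register <= self.cycle:
            raise ValueError(f"register {register} outside 1..{self.cycle}")
        return float(self.abundance[register - 1])

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# anchor={self.anchor}\tstrand_policy={self.strand_policy}\n")
            handle.write("register\trpm\n")
            for r in range(1, self.cycle + 1):
                handle.write(f"{r}\t{self[r]:.6g}\n")


def register_radial(
    reads: Iterable[AlignedRead],
    anchor: int,
    cfg: PhasingConfig = PhasingConfig(),
    stats: LibraryStats | None = None,
    region: GenomicInterval | None = None,
) -> RegisterProfile:
    """Sum 5'-end abundance into the 21 registers of ``anchor``.

    This is the tabular form of the radial ("spoke") graphs used to separate
    cascade generations: with the anchor one nucleotide 5' of the cleavage
    site, canonical secondary siRNAs stack on register 2 and the tertiary
    cascade (offset +9) on register 11.
    """
    read_list = [
        r for r in reads
        if region is None or region.contains(r.chrom, five_prime(r))
    ]
    coords, strands, counts = _phase_coordinates(read_list, cfg)
    rpm = counts * _rpm_factor(stats)
    abundance = np.zeros(cfg.cycle)
    for coord, value in zip(coords, rpm):
        abundance[(coord - anchor) % cfg.cycle] += value
    return RegisterProfile(abundance, anchor=anchor, strand_policy=cfg.strand_policy,
                           cycle=cfg.cycle)


def five_prime(read: AlignedRead) -> int:
    return read.start if read.strand == "+" else read.end - 1


def dominant_registers(profile: RegisterProfile, n: int) -> list[int]:
    """The n most abundant registers, ties broken by lower register index."""
    if n > profile.cycle:
        raise ValueError(f"cannot rank {n} of {profile.cycle} registers")
    order = sorted(range(1, profile.cycle + 1), key=lambda r: (-profile[r], r))
    return order[:n]


def matched_coordinate_test(
    track_a: PhasingTrack,
    track_b: PhasingTrack,
    coords: Sequence[int],
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of scores at matched coordinates.

    Missing coordinates score 0 (below any coverage threshold no score was
    assigned). Uses the exact null for n <= 25 pairs and the normal
    approximation above; returns (statistic, two-sided p).
    """
    if len(coords) < 5:
        raise ValueError("need >= 5 matched coordinates for a paired test")
    a = np.array([track_a.scores.get(c, 0.0) for c in coords])
    b = np.array([track_b.scores.get(c, 0.0) for c in coords])
    if np.allclose(a, b):
        return 0.0, 1.0
    method = "exact" if len(coords) <= 25 else "approx"
    try:
        result = sps.wilcoxon(a, b, method=method)
    except ValueError:
        result = sps.wilcoxon(a, b, method="approx")
    return float(result.statistic), float(result.pvalue)
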