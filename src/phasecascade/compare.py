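"""Condition comparison: the wild-type vs truncation-mutant analysis.

Runs every stage of the analysis on two conditions (each with replicate
sRNA, degradome and mRNA libraries plus optional AGO-IP libraries) over a
set of annotated loci and assembles a per-locus report: sRNA abundance,
phasing-score calls, register profiles with dominant registers and the
secondary-to-tertiary offset, cleavage-site efficiency, and the condition
tests. The pipeline reports the numbers descriptively and never
auto-classifies a locus as one-hit or two-hit — that interpretive call
belongs to the analyst.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .align_io import AlignedRead, GenomicInterval, LibraryStats
from .degradome import (
    efficiency_difference_test,
    fisher_cleavage_test,
    five_prime_profile,
    replicate_efficiencies,
    site_cleavage_rpm,
    transcript_fpkm,
)
from .phasing import (
    PhasingConfig,
    PhasingTrack,
    RegisterProfile,
    dominant_registers,
    phasing_track,
    register_offset,
    register_radial,
)
from .quant import locus_abundance
from .simulate import TasLocusModel

__all__ = [
    "ConditionLibraries",
    "ConditionPair",
    "LocusConditionResult",
    "ComparisonReport",
    "PipelineStageError",
    "loading_ratio",
    "coordinate_call_count",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class ConditionLibraries:
    """Replicate libraries of one condition (lists of read lists)."""

    srna: list[list[AlignedRead]]
    degradome: list[list[AlignedRead]] = field(default_factory=list)
    mrna: list[list[AlignedRead]] = field(default_factory=list)
    ip: list[list[AlignedRead]] = field(default_factory=list)


@dataclass
class ConditionPair:
    """Two conditions plus the locus annotations they share."""

    label_a: str
    label_b: str
    libraries_a: ConditionLibraries
    libraries_b: ConditionLibraries
    loci: list[TasLocusModel]

    def __post_init__(self) -> None:
        for label, libs in ((self.label_a, self.libraries_a),
                            (self.label_b, self.libraries_b)):
            if not libs.srna:
                raise ValueError(f"condition {label!r} has no sRNA library")


def loading_ratio(
    ip_profile: RegisterProfile, total_profile: RegisterProfile
) -> np.ndarray:
    """Per-register AGO-IP RPM / total-sRNA RPM (loading enrichment).

    NaN marks registers with zero total abundance (ratio undefined).
    Profiles must share anchor and strand policy.
    """
    if ip_profile.anchor != total_profile.anchor:
        raise ValueError(
            f"anchor mismatch: IP {ip_profile.anchor} vs total {total_profile.anchor}"
        )
    if ip_profile.strand_policy != total_profile.strand_policy:
        raise ValueError("strand-policy mismatch between profiles")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(
            total_profile.abundance > 0,
            ip_profile.abundance / total_profile.abundance,
            np.nan,
        )
    return ratios


def coordinate_call_count(track: PhasingTrack, locus: GenomicInterval) -> int:
    """Number of above-threshold phasing coordinates within the locus."""
    return sum(1 for c in track.calls if locus.start <= c < locus.end)


@dataclass
class LocusConditionResult:
    """All per-locus quantities for one condition (replicate-wise)."""

    srna_rpm: list[float]
    call_count: int
    track: PhasingTrack
    profile: RegisterProfile
    dominant: list[int]
    secondary_to_tertiary_offset: int
    site_counts: dict[int, int] = field(default_factory=dict)
    degradome_rpm: dict[int, list[float]] = field(default_factory=dict)
    fpkm: list[float] = field(default_factory=list)
    efficiency: dict[int, list[float | None]] = field(default_factory=dict)
    loading: np.ndarray | None = None


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    per_locus: dict[str, dict[str, LocusConditionResult]]
    tests: dict[str, dict[str, tuple[float, float]]]
    provenance: dict


def _pooled(replicates: Sequence[list[AlignedRead]]) -> list[AlignedRead]:
    return [read for rep in replicates for read in rep]


def _condition_result(
    label: str,
    libs: ConditionLibraries,
    locus: TasLocusModel,
    cfg: PhasingConfig,
) -> LocusConditionResult:
    region = locus.span
    try:
        srna_stats = [LibraryStats.from_reads(rep) for rep in libs.srna]
        srna_rpm = [
            locus_abundance(rep, region, st, read_length=21)
            for rep, st in zip(libs.srna, srna_stats)
        ]
    except ValueError as exc:
        raise PipelineStageError("srna_quant", f"{label}/{locus.locus_id}: {exc}")

    pooled = _pooled(libs.srna)
    pooled_stats = LibraryStats.from_reads(pooled)
    try:
        track = phasing_track(pooled, region, cfg, pooled_stats)
        profile = register_radial(pooled, locus.anchor, cfg, pooled_stats, region)
    except ValueError as exc:
        raise PipelineStageError("phasing", f"{label}/{locus.locus_id}: {exc}")
    dominant = dominant_registers(profile, 2)
    offset = register_offset(dominant[0], dominant[1])

    result = LocusConditionResult(
        srna_rpm=srna_rpm,
        call_count=coordinate_call_count(track, region),
        track=track,
        profile=profile,
        dominant=dominant,
        secondary_to_tertiary_offset=offset,
    )

    sites = [locus.to_genomic(t.scissile_coord) for t in locus.triggers if t.cleavable]
    if libs.degradome:
        try:
            for site in sites:
                rpms, counts = [], 0
                for rep in libs.degradome:
                    st = LibraryStats.from_reads(rep)
                    prof = five_prime_profile(rep, region, st)
                    rpms.append(site_cleavage_rpm(prof, site))
                    counts += sum(
                        r.count for r in rep
                        if r.chrom == region.chrom
                        and (r.start if r.strand == "+" else r.end - 1) == site
                    )
                result.degradome_rpm[site] = rpms
                result.site_counts[site] = counts
        except ValueError as exc:
            raise PipelineStageError("degradome", f"{label}/{locus.locus_id}: {exc}")
    if libs.mrna:
        try:
            result.fpkm = [
                transcript_fpkm(rep, region, LibraryStats.from_reads(rep))
                for rep in libs.mrna
            ]
        except ValueError as exc:
            raise PipelineStageError("mrna_quant", f"{label}/{locus.locus_id}: {exc}")
    if libs.degradome and libs.mrna:
        for site in sites:
            n = min(len(result.degradome_rpm[site]), len(result.fpkm))
            result.efficiency[site] = replicate_efficiencies(
                result.degradome_rpm[site][:n], result.fpkm[:n]
            )
    if libs.ip:
        ip_pooled = _pooled(libs.ip)
        ip_profile = register_radial(
            ip_pooled, locus.anchor, cfg, LibraryStats.from_reads(ip_pooled), region
        )
        result.loading = loading_ratio(ip_profile, profile)
    return result


def run_pipeline(
    pair: ConditionPair,
    cfg: PhasingConfig = PhasingConfig(),
    out_dir: str | Path | None = None,
) -> ComparisonReport:
    """Run every analysis stage on both conditions of every locus.

    Deterministic given the inputs and configuration. When ``out_dir`` is
    given, stage tables (register profiles, phasing tracks) and a
    provenance log (input digests, configuration, package version) are
    written there.
    """
    per_locus: dict[str, dict[str, LocusConditionResult]] = {}
    tests: dict[str, dict[str, tuple[float, float]]] = {}
    for locus in pair.loci:
        result_a = _condition_result(pair.label_a, pair.libraries_a, locus, cfg)
        result_b = _condition_result(pair.label_b, pair.libraries_b, locus, cfg)
        per_locus[locus.locus_id] = {pair.label_a: result_a, pair.label_b: result_b}

        locus_tests: dict[str, tuple[float, float]] = {}
        for site, counts_a in result_a.site_counts.items():
            total_a = sum(
                sum(r.count for r in rep) for rep in pair.libraries_a.degradome
            )
            total_b = sum(
                sum(r.count for r in rep) for rep in pair.libraries_b.degradome
            )
            counts_b = result_b.site_counts.get(site, 0)
            locus_tests[f"fisher_site_{site}"] = fisher_cleavage_test(
                counts_a, total_a, counts_b, total_b
            )
            effs_a = result_a.efficiency.get(site, [])
            effs_b = result_b.efficiency.get(site, [])
            defined = lambda v: [e for e in v if e is not None]
            if len(defined(effs_a)) >= 2 and len(defined(effs_b)) >= 2:
                locus_tests[f"welch_site_{site}"] = efficiency_difference_test(
                    effs_a, effs_b, alternative="greater"
                )
        tests[locus.locus_id] = locus_tests

    provenance = {
        "version": __version__,
        "label_a": pair.label_a,
        "label_b": pair.label_b,
        "loci": [l.locus_id for l in pair.loci],
        "config": vars(cfg) | {"read_lengths": list(cfg.read_lengths)},
        "input_digests": _digest_pair(pair),
    }
    report = ComparisonReport(
        label_a=pair.label_a, label_b=pair.label_b,
        per_locus=per_locus, tests=tests, provenance=provenance,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _digest_pair(pair: ConditionPair) -> dict[str, str]:
    digests = {}
    for label, libs in ((pair.label_a, pair.libraries_a),
                        (pair.label_b, pair.libraries_b)):
        h = hashlib.sha256()
        for kind in ("srna", "degradome", "mrna", "ip"):
            for rep in getattr(libs, kind):
                for read in rep:
                    h.update(
                        f"{kind}|{read.chrom}|{read.start}|{read.end}|"
                        f"{read.strand}|{read.count}\n".encode()
                    )
        digests[label] = h.hexdigest()
    return digests


def _write_report(report: ComparisonReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tests": {
        locus: {k: list(v) for k, v in t.items()} for locus, t in report.tests.items()
    }}
    for locus_id, conditions in report.per_locus.items():
        summary[locus_id] = {}
        for label, res in conditions.items():
            res.profile.to_tsv(out_dir / f"{locus_id}.{label}.registers.tsv")
            summary[locus_id][label] = {
                "srna_rpm": res.srna_rpm,
                "call_count": res.call_count,
                "dominant_registers": res.dominant,
                "secondary_to_tertiary_offset": res.secondary_to_tertiary_offset,
                "degradome_rpm": {str(k): v for k, v in res.degradome_rpm.items()},
                "fpkm": res.fpkm,
                "efficiency": {str(k): v for k, v in res.efficiency.items()},
            }
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
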