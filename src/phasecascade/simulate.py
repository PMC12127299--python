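"""Generative model of one-hit and two-hit *TAS*-locus read data.

The simulator emits the three library types the analysis consumes — small-RNA
reads, degradome (uncapped 5'-end) reads, and mRNA fragments — from an
explicit model of phased siRNA biogenesis:

* a trigger miRNA cleaves the transcript at a scissile bond located between
  the nucleotides complementary to trigger positions 10 and 11;
* the retained fragment (3' fragment in the one-hit model, 5' fragment in
  the two-hit model) is converted to dsRNA and diced into head-to-tail
  21-nt duplexes with 2-nt 3' overhangs, so sense-strand 5' ends fall every
  21 nt from the phase origin;
* a minority of duplex positions yield 22-nt (DCL2-type) products;
* a fraction of phased production is re-seeded by a 22-nt secondary siRNA,
  shifting the register by +9 (the tertiary cascade);
* off-phase degradation noise is uniform over the transcript;
* the degradome shows spikes at cleavable scissile coordinates over a
  uniform decay background, and mRNA fragments come from intact
  (uncleaved) transcripts only.

Counts are multinomially sampled at the configured depths under a single
seed, so equal seeds give byte-identical output files. Every simulation
returns a :class:`GroundTruth` recording what downstream modules should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align_io import AlignedRead, GenomicInterval, write_bed

__all__ = [
    "TriggerSite",
    "TasLocusModel",
    "SimConfig",
    "GroundTruth",
    "build_locus",
    "simulate_srna",
    "simulate_degradome",
    "simulate_mrna",
    "phased_positions",
    "random_transcript_sequence",
    "write_locus_fasta",
    "write_locus_gff3",
    "write_ground_truth",
    "write_config",
]

CYCLE = 21  #: DCL4 product length and register cycle
TERTIARY_OFFSET = 9  #: phase shift between secondary and tertiary siRNAs

#: decoy reference holding off-locus background reads (rest of the library)
BACKGROUND_CHROM = "chrB"
BACKGROUND_SPAN = 50_000


@dataclass(frozen=True)
class TriggerSite:
    """A miRNA binding site on the transcript.

    ``scissile_coord`` is the 0-based transcript coordinate of the first
    nucleotide of the 3' cleavage fragment, i.e. the nucleotide base-paired
    with trigger position 10; the scissile bond lies immediately 5' of it.
    The 5' site of a two-hit locus is bound but not cleaved.
    """

    scissile_coord: int
    trigger_length: int = 22
    cleavable: bool = True

    def __post_init__(self) -> None:
        if self.scissile_coord < 10:
            raise ValueError(
                "scissile_coord must be >= 10: ten trigger-complementary "
                "nucleotides lie 5' of the scissile bond"
            )
        if self.trigger_length not in (21, 22):
            raise ValueError("trigger_length must be 21 or 22 nt")

    @property
    def binding_interval(self) -> tuple[int, int]:
        """0-based half-open transcript interval complementary to the trigger."""
        return (
            self.scissile_coord - 10,
            self.scissile_coord + self.trigger_length - 10,
        )


@dataclass(frozen=True)
class TasLocusModel:
    """Annotation + generative model of a single *TAS* locus.

    ``phase_origin`` is the transcript coordinate of the first nucleotide of
    the first phased 21-mer; phasing proceeds toward the 3' end in the
    one-hit model (3' fragment retained) and toward the 5' end in the
    two-hit model (5' fragment retained).
    """

    locus_id: str
    chrom: str
    span: GenomicInterval
    model: str  # "one_hit" | "two_hit"
    triggers: tuple[TriggerSite, ...]
    phase_origin: int
    phase_direction: str  # "toward_3p" | "toward_5p"
    transcript_length: int
    deletion: tuple[int, int] | None = None  # original 1-based closed interval

    @property
    def cleavable_trigger(self) -> TriggerSite:
        return next(t for t in self.triggers if t.cleavable)

    @property
    def anchor(self) -> int:
        """Genomic register anchor: the canonical secondary phase lands on
        register 2 when profiles are anchored one nucleotide 5' of the
        cleavable scissile coordinate."""
        return self.span.start + self.cleavable_trigger.scissile_coord - 1

    def to_genomic(self, transcript_coord: int) -> int:
        return self.span.start + transcript_coord


def build_locus(
    model: str,
    transcript_length: int,
    triggers: Sequence[TriggerSite],
    deletion: tuple[int, int] | None = None,
    locus_id: str = "TAS_sim",
    chrom: str = "chr1",
    genome_offset: int = 1000,
) -> TasLocusModel:
    """Construct a validated locus model, applying an optional deletion.

    ``deletion`` is a 1-based closed transcript interval (the convention in
    which published CRISPR truncations are printed, e.g. 269-374) removed
    from the transcript; trigger coordinates 3' of it shift left by its
    length. A deletion overlapping a trigger binding site is rejected.
    """
    if model not in ("one_hit", "two_hit"):
        raise ValueError(f"model must be 'one_hit' or 'two_hit', got {model!r}")
    if transcript_length <= CYCLE:
        raise ValueError("transcript too short for one phased duplex")
    triggers = tuple(triggers)

    n_cleavable = sum(t.cleavable for t in triggers)
    if model == "one_hit":
        if len(triggers) != 1 or n_cleavable != 1:
            raise ValueError("one-hit locus requires exactly one cleavable trigger")
    else:
        if len(triggers) != 2 or n_cleavable != 1:
            raise ValueError(
                "two-hit locus requires two trigger sites of which exactly one "
                "(the 3' site) is cleavable"
            )
        cleavable = next(t for t in triggers if t.cleavable)
        other = next(t for t in triggers if not t.cleavable)
        if cleavable.scissile_coord <= other.scissile_coord:
            raise ValueError("two-hit cleavage occurs only at the 3' binding site")

    for trig in triggers:
        b0, b1 = trig.binding_interval
        if b0 < 0 or b1 > transcript_length:
            raise ValueError(
                f"trigger binding site [{b0}, {b1}) outside transcript of "
                f"length {transcript_length}"
            )

    if deletion is not None:
        d1, d2 = deletion
        if not (1 <= d1 <= d2 <= transcript_length):
            raise ValueError(
                f"deletion {d1}-{d2} (1-based closed) outside transcript of "
                f"length {transcript_length}"
            )
        del_start, del_end = d1 - 1, d2  # 0-based half-open
        del_len = del_end - del_start
        shifted = []
        for trig in triggers:
            b0, b1 = trig.binding_interval
            if b0 < del_end and del_start < b1:
                raise ValueError(
                    f"deletion {d1}-{d2} overlaps the trigger binding site "
                    f"[{b0}, {b1}); truncations must preserve miRNA binding sites"
                )
            if trig.scissile_coord >= del_end:
                trig = replace(trig, scissile_coord=trig.scissile_coord - del_len)
            shifted.append(trig)
        triggers = tuple(shifted)
        transcript_length -= del_len

    cleavable = next(t for t in triggers if t.cleavable)
    if model == "one_hit":
        phase_origin = cleavable.scissile_coord
        phase_direction = "toward_3p"
        if phase_origin + CYCLE > transcript_length:
            raise ValueError("no room for a phased duplex 3' of the cleavage site")
    else:
        phase_origin = cleavable.scissile_coord - CYCLE
        phase_direction = "toward_5p"
        if phase_origin < 0:
            raise ValueError("no room for a phased duplex 5' of the cleavage site")

    span = GenomicInterval(chrom, genome_offset, genome_offset + transcript_length, "+")
    return TasLocusModel(
        locus_id=locus_id,
        chrom=chrom,
        span=span,
        model=model,
        triggers=triggers,
        phase_origin=phase_origin,
        phase_direction=phase_direction,
        transcript_length=transcript_length,
        deletion=deletion,
    )


@dataclass
class SimConfig:
    """Rates and depths of the generative model.

    Depths are library totals (reads). Fractions are probabilities in [0, 1].
    ``transcript_copies`` sets the locus transcript copy number against the
    fixed off-locus ``library_background`` weight that represents the rest of
    the degradome/mRNA library, so locus RPM and FPKM scale the way a locus
    embedded in a real library does. ``decay_background`` is the uniform
    per-coordinate degradome decay rate per transcript copy.
    """

    srna_depth: int = 50_000
    phased_fraction: float = 0.85
    dcl2_fraction: float = 0.10
    tertiary_fraction: float = 0.15
    n_cycles: int = 9
    degradome_depth: int = 50_000
    mrna_depth: int = 50_000
    cleaved_fraction: float = 0.15
    decay_background: float = 0.0005
    transcript_copies: float = 100.0
    library_background: float = 10_000.0
    fragment_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phased_fraction", "dcl2_fraction", "tertiary_fraction",
                     "cleaved_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("srna_depth", "degradome_depth", "mrna_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.decay_background < 0 or self.transcript_copies < 0:
            raise ValueError("rates must be >= 0")
        if self.library_background < 0:
            raise ValueError("library_background must be >= 0")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one library type under the master seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Exported truth for downstream recovery checks.

    Registers follow the locus anchor convention (anchor one nucleotide 5'
    of the cleavable scissile coordinate), under which the secondary phase
    sits on register 2 and the tertiary cascade on register 11.
    """

    locus_id: str
    library: str
    anchor: int
    secondary_register: int = 2
    tertiary_register: int = 11
    class_totals: dict[str, int] = field(default_factory=dict)
    site_flux: dict[int, float] = field(default_factory=dict)  # genomic coord -> expected RPM
    intact_abundance: float = 0.0
    expected_fpkm: float = 0.0
    expected_efficiency: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert (self.tertiary_register - self.secondary_register) % CYCLE == TERTIARY_OFFSET


def phased_positions(locus: TasLocusModel, n_cycles: int) -> list[int]:
    """Sense-strand 5'-end transcript coordinates of the phased 21-mers.

    One-hit loci phase from the origin toward the 3' end; two-hit loci from
    the origin toward the 5' end. Positions without room for a full 21-mer
    are dropped.
    """
    step = CYCLE if locus.phase_direction == "toward_3p" else -CYCLE
    positions = []
    for j in range(n_cycles):
        p = locus.phase_origin + step * j
        if p < 0 or p + CYCLE > locus.transcript_length:
            break
        positions.append(p)
    return positions


def _duplex_reads(locus: TasLocusModel, p: int, length: int, label: str):
    """The sense read and its duplex partner for a phased position.

    The antisense strand of the duplex carries the canonical 2-nt 3'
    overhang: a 21-nt partner spans transcript [p-2, p+19). DCL2-type
    products keep the sense 5' coordinate and extend 3' by one nucleotide.
    """
    g = locus.to_genomic(p)
    sense = (locus.chrom, g, g + length, "+", label)
    anti_end = g + CYCLE - 2  # exclusive end of the antisense partner
    anti = (locus.chrom, anti_end - length, anti_end, "-", label)
    return sense, anti


def _sample_categories(
    categories: list[tuple], weights: list[float], depth: int,
    rng: np.random.Generator, library: str,
) -> list[AlignedRead]:
    """Multinomial draw of ``depth`` reads over weighted read groups."""
    if depth == 0 or not categories:
        return []
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return []
    counts = rng.multinomial(depth, w / total)
    reads = []
    for (chrom, start, end, strand, label), n in zip(categories, counts):
        if n > 0:
            reads.append(AlignedRead(chrom, start, end, strand, int(n), library, label))
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.name))
    return reads


def simulate_srna(
    locus: TasLocusModel, cfg: SimConfig
) -> tuple[list[AlignedRead], GroundTruth]:
    """Simulate the small-RNA library of one locus.

    Phased mass is spread uniformly over the duplex positions and split
    evenly between the two duplex strands; ``dcl2_fraction`` of it is
    emitted as 22-nt products, ``tertiary_fraction`` is re-seeded at a +9
    register offset, and ``1 - phased_fraction`` of the locus reads land
    uniformly at random transcript coordinates on either strand.
    """
    categories: list[tuple] = []
    weights: list[float] = []

    def add(entry, weight):
        if weight > 0:
            categories.append(entry)
            weights.append(weight)

    secondary = phased_positions(locus, cfg.n_cycles)
    tertiary = [
        p + TERTIARY_OFFSET
        for p in secondary
        if 0 <= p + TERTIARY_OFFSET and p + TERTIARY_OFFSET + CYCLE <= locus.transcript_length
    ]
    phase_classes = [
        ("secondary", secondary, (1.0 - cfg.tertiary_fraction)),
        ("tertiary", tertiary, cfg.tertiary_fraction),
    ]
    for label, positions, mass in phase_classes:
        if not positions or mass <= 0:
            continue
        per_pos = cfg.phased_fraction * mass / len(positions)
        for p in positions:
            for length, frac in ((CYCLE, 1.0 - cfg.dcl2_fraction), (CYCLE + 1, cfg.dcl2_fraction)):
                sense, anti = _duplex_reads(locus, p, length, label)
                tag = label if length == CYCLE else f"{label}_dcl2"
                add(sense[:4] + (tag,), per_pos * frac / 2.0)
                add(anti[:4] + (tag,), per_pos * frac / 2.0)

    noise_mass = 1.0 - cfg.phased_fraction
    n_noise_pos = max(locus.transcript_length - CYCLE, 1)
    if noise_mass > 0:
        per = noise_mass / (2 * n_noise_pos)
        for t in range(n_noise_pos):
            g = locus.to_genomic(t)
            add((locus.chrom, g, g + CYCLE, "+", "noise"), per)
            add((locus.chrom, g, g + CYCLE, "-", "noise"), per)

    reads = _sample_categories(categories, weights, cfg.srna_depth, cfg.rng(1), "srna")

    truth = GroundTruth(locus_id=locus.locus_id, library="srna", anchor=locus.anchor)
    for read in reads:
        key = read.name.removesuffix("_dcl2")
        truth.class_totals[key] = truth.class_totals.get(key, 0) + read.count
    return reads, truth


def simulate_degradome(
    locus: TasLocusModel, cfg: SimConfig
) -> tuple[list[AlignedRead], GroundTruth]:
    """Simulate degradome (uncapped 5'-end) reads for one locus.

    Cleavage signal sits exactly at each cleavable scissile coordinate with
    weight ``cleaved_fraction * transcript_copies``; uniform decay
    background covers the transcript at ``decay_background`` per copy per
    coordinate; ``library_background`` weight of unrelated degradome tags is
    placed on a decoy reference so RPM values behave as in a full library.
    """
    tag_len = 20  # degradome tag footprint
    categories: list[tuple] = []
    weights: list[float] = []
    truth = GroundTruth(locus_id=locus.locus_id, library="degradome", anchor=locus.anchor)

    site_weights: dict[int, float] = {}
    for trig in locus.triggers:
        g = locus.to_genomic(trig.scissile_coord)
        w = cfg.cleaved_fraction * cfg.transcript_copies if trig.cleavable else 0.0
        site_weights[g] = w
        if w > 0:
            categories.append((locus.chrom, g, g + tag_len, "+", "cleavage"))
            weights.append(w)

    bg_per = cfg.decay_background * cfg.transcript_copies
    if bg_per > 0:
        for t in range(locus.transcript_length):
            g = locus.to_genomic(t)
            categories.append((locus.chrom, g, g + tag_len, "+", "decay"))
            weights.append(bg_per)

    n_bg = 500  # decoy positions carrying the rest-of-library mass
    if cfg.library_background > 0:
        step = BACKGROUND_SPAN // n_bg
        for i in range(n_bg):
            categories.append(
                (BACKGROUND_CHROM, i * step, i * step + tag_len, "+", "library_bg")
            )
            weights.append(cfg.library_background / n_bg)

    total_w = sum(weights)
    for g, w in site_weights.items():
        truth.site_flux[g] = 1e6 * w / total_w if total_w > 0 else 0.0

    reads = _sample_categories(
        categories, weights, cfg.degradome_depth, cfg.rng(2), "degradome"
    )
    for read in reads:
        truth.class_totals[read.name] = truth.class_totals.get(read.name, 0) + read.count
    return reads, truth


def simulate_mrna(
    locus: TasLocusModel, cfg: SimConfig
) -> tuple[list[AlignedRead], GroundTruth]:
    """Simulate polyA-selected mRNA fragments (intact transcripts only).

    Cleaved transcripts lack the polyA tail or cap needed for library
    inclusion, so locus fragment mass is proportional to
    ``transcript_copies * (1 - cleaved_fraction)`` and to transcript length
    (longer transcripts shed more fragments), against the off-locus
    ``library_background`` pool.
    """
    frag = min(cfg.fragment_length, locus.transcript_length)
    categories: list[tuple] = []
    weights: list[float] = []

    intact = cfg.transcript_copies * (1.0 - cfg.cleaved_fraction)
    locus_weight = intact * locus.transcript_length / 1000.0
    n_starts = locus.transcript_length - frag + 1
    if locus_weight > 0:
        for t in range(n_starts):
            g = locus.to_genomic(t)
            categories.append((locus.chrom, g, g + frag, "+", "intact"))
            weights.append(locus_weight / n_starts)

    n_bg = 500
    if cfg.library_background > 0:
        step = BACKGROUND_SPAN // n_bg
        for i in range(n_bg):
            categories.append(
                (BACKGROUND_CHROM, i * step, i * step + frag, "+", "library_bg")
            )
            weights.append(cfg.library_background / n_bg)

    reads = _sample_categories(categories, weights, cfg.mrna_depth, cfg.rng(3), "mrna")

    total_w = locus_weight + (cfg.library_background if cfg.library_background > 0 else 0.0)
    truth = GroundTruth(locus_id=locus.locus_id, library="mrna", anchor=locus.anchor)
    truth.intact_abundance = intact
    if total_w > 0:
        expected_frags = cfg.mrna_depth * locus_weight / total_w
        truth.expected_fpkm = (
            expected_frags * 1e9 / (cfg.mrna_depth * locus.transcript_length)
            if cfg.mrna_depth > 0
            else 0.0
        )
    for read in reads:
        truth.class_totals[read.name] = truth.class_totals.get(read.name, 0) + read.count
    return reads, truth


# ---------------------------------------------------------------------------
# Sequence and annotation export
# ---------------------------------------------------------------------------

def random_transcript_sequence(length: int, seed: int = 0) -> str:
    """A synthetic transcript sequence (uniform ACGU alphabet, DNA letters)."""
    rng = np.random.default_rng([int(seed) % (2**31), 99])
    return "".join(rng.choice(list("ACGT"), size=length))


def write_locus_fasta(locus: TasLocusModel, path: str | Path, seed: int = 0) -> None:
    record = SeqRecord(
        Seq(random_transcript_sequence(locus.transcript_length, seed)),
        id=locus.locus_id,
        description=f"synthetic {locus.model} TAS transcript",
    )
    SeqIO.write([record], str(path), "fasta")


def write_locus_gff3(loci: Sequence[TasLocusModel], path: str | Path) -> None:
    """Write locus and trigger-site annotations as GFF3.

    The gene feature carries ``model=``; each trigger-site child carries
    ``scissile=`` (1-based genomic coordinate of the first nucleotide of
    the 3' fragment) and ``cleavable=``.
    """
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for locus in loci:
            handle.write(
                f"{locus.chrom}\tphasecascade\tgene\t{locus.span.start + 1}\t"
                f"{locus.span.end}\t.\t+\t.\t"
                f"ID={locus.locus_id};model={locus.model}\n"
            )
            for i, trig in enumerate(locus.triggers, start=1):
                b0, b1 = trig.binding_interval
                handle.write(
                    f"{locus.chrom}\tphasecascade\tmiRNA_target_site\t"
                    f"{locus.span.start + b0 + 1}\t{locus.span.start + b1}\t.\t+\t.\t"
                    f"ID={locus.locus_id}.site{i};Parent={locus.locus_id};"
                    f"scissile={locus.to_genomic(trig.scissile_coord) + 1};"
                    f"cleavable={'true' if trig.cleavable else 'false'}\n"
                )


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "locus_id\tlibrary\tanchor\tsecondary_register\ttertiary_register\t"
            "class_totals\tsite_flux\tintact_abundance\texpected_fpkm\n"
        )
        for t in truths:
            classes = ",".join(f"{k}={v}" for k, v in sorted(t.class_totals.items()))
            flux = ",".join(f"{k}={v:.6g}" for k, v in sorted(t.site_flux.items()))
            handle.write(
                f"{t.locus_id}\t{t.library}\t{t.anchor}\t{t.secondary_register}\t"
                f"{t.tertiary_register}\t{classes}\t{flux}\t"
                f"{t.intact_abundance:.6g}\t{t.expected_fpkm:.6g}\n"
            )


def write_config(cfg: SimConfig, path: str | Path) -> None:
    """Flat key=value dump of the configuration (seed included)."""
    with open(path, "w") as handle:
        for key, value in vars(cfg).items():
            handle.write(f"{key}={value}\n")


def export_library(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Write a simulated library as BED6 (read groups, count in score)."""
    write_bed(reads, path)
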