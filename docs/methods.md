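# Methods

## The biological model

A *TAS* transcript enters phased-siRNA biogenesis when a trigger-loaded
RISC cleaves it at a scissile bond located between the nucleotides
complementary to trigger positions 10 and 11. In the **one-hit** pathway a
single 22-nt trigger cleaves once and the 3′ fragment is retained; in the
**two-hit** pathway two 21-nt triggers bind, only the 3′ site is cleaved,
and the 5′ fragment is retained. The retained fragment is copied into
dsRNA and diced processively into 21-nt duplexes, so siRNA 5′ ends recur
every 21 nt from the cleavage site — the *phase*. A minority of duplex
positions are processed into 22-nt products; such 22-nt siRNAs can
re-target the precursor and seed a *tertiary* cascade whose phase is offset
by +9 nt (10 nt to the new scissile bond minus the 21-nt modulus:
(21·j + 9) mod 21 = 9).

Everything in the package is phrased in terms of observable read
coordinates; no sequence-level trigger:target scoring is attempted.

## Coordinate and register conventions

- Internal coordinates are 0-based half-open; printed 1-based annotation
  coordinates (deletion intervals, scissile positions in GFF3) are
  converted at the boundary.
- A read's biological 5′ end is `start` on the plus strand and `end − 1` on
  the minus strand.
- `scissile_coord` is the transcript coordinate of the **first nucleotide
  of the 3′ cleavage fragment**; degradome reads from that cleavage start
  exactly there. `TriggerSite` requires `scissile_coord ≥ 10` so the ten
  trigger-complementary nucleotides 5′ of the bond fit on the transcript.
- Register of coordinate `x` relative to anchor `a`: `((x − a) mod 21) + 1`.
  Profile anchors default to **one nucleotide 5′ of the cleavable scissile
  coordinate**, which places the canonical secondary phase on register 2
  and the tertiary cascade on register 11. The anchor is recorded in every
  profile so the convention is always explicit.

## Duplex geometry and strand merging

Dicer products carry 2-nt 3′ overhangs: the duplex partner of a sense
21-mer `[s, s+21)` is the antisense read `[s−2, s+19)`. For register
assignment under the `merged` strand policy, antisense **alignment starts**
are shifted +2 — the standard overhang correction — which maps a duplex
partner onto exactly its sense partner's register and doubles the occupancy
ceiling of a window (k_max 18 vs 9 sense-only). The `sense` policy drops
minus-strand reads instead. 22-nt (DCL2-type) products are modeled as
starting at the same 5′ coordinate as the 21-nt product and extending one
nucleotide 3′; this is a modeling choice, not an observed constraint.

## The phasing score

The score family implemented is the log-transformed register-concentration
statistic

    score(window) = (k − 2) · ln(1 + 10·P / (1 + U)),   k ≥ 3, else 0

computed per window start over a 189-nt window (nine 21-nt cycles) sliding
in 1-nt steps, with P/U in RPM and `k` the number of occupied in-register
(coordinate, strand) positions. Calls use strict `score > threshold`
(default 150). Two genuinely open conventions are exposed as configuration
rather than fixed:

- **Numerator variant.** The damped form divides by out-of-register
  abundance; under it, a locus with a strong tertiary cascade scores low
  because each generation is "noise" to the other, and the 150 threshold is
  only crossed by nearly pure single-phase signal. The `raw` variant
  (`(k−2)·ln(1+10·P)`) scores each register on its own abundance, so both
  cascade generations can be called at one locus. The damped form is the
  default; analyses of multi-generation loci should consider `raw`.
- **Window coverage threshold.** A window is scored only if it contains at
  least `min_covered_positions` (default 10) distinct occupied 5′-end
  positions; the reference usage mentions a coverage threshold without
  quantifying it.

With merged strands (k_max 18) the default threshold 150 requires
`ln(1 + 10P/(1+U)) > 9.4`, i.e. in-register abundance ≥ ~1200× the
out-of-register abundance; sense-only scoring (k_max 9) cannot reach 150 at
any abundance, which is why `merged` is the default policy.

## Degradome quantification and cleavage efficiency

Degradome 5′-end profiles are exact per-coordinate RPM; site quantification
matches the exact scissile coordinate (an optional ±1 slop window exists
but is off by default). Transcript abundance is FPKM
(`fragments·10⁹ / (total·length)`) over fragments overlapping the
transcript. Cleavage efficiency is the unitless ratio RPM/FPKM: an
arbitrary-scaled quantity whose absolute value depends on library
composition — only ratios and within-study comparisons are meaningful.
A zero FPKM leaves the efficiency *missing* (never 0 or ∞); missing values
propagate through group tests by exclusion.

Condition tests follow the designs the statistics support: Fisher's exact
test takes pooled per-condition site counts against the remaining library
(an exact test needs counts; pooling replicates is the only construction
yielding one 2×2 table per comparison), while the one-sided Welch t-test
consumes replicate efficiency vectors. Matched phasing-score comparisons
use the paired Wilcoxon signed-rank test, exact for ≤ 25 pairs.

## The simulator as study conditions

Defaults describe a deeply sequenced, strongly phased locus:
`srna_depth = 50 000` locus reads with `phased_fraction = 0.85`,
`dcl2_fraction = 0.10` (the minority DCL2 class), `tertiary_fraction =
0.15`, `n_cycles = 9` (one full 189-nt window of phased signal, so the
window is saturable at desk scale), uniform off-phase noise for the
remainder. Degradome and mRNA libraries (50 000 reads each) embed the locus
(`transcript_copies = 100`) in a fixed off-locus background pool
(`library_background = 10⁴` weight on a decoy reference), so the locus is a
~1 % component of its library and site RPM ∝ `cleaved_fraction·copies`
while FPKM ∝ `(1−cleaved_fraction)·copies` to first order — giving the
closed-form between-condition efficiency ratio `(f′/(1−f′))/(f/(1−f))`
used in estimator-recovery checks. `decay_background = 5·10⁻⁴` per copy per
coordinate puts uniform decay well below cleavage spikes. All counts are
multinomial at the configured depth under per-library seeded generators, so
identical seeds give byte-identical files.

What the generator does **not** emulate: sequence-dependent dicing
heterogeneity, positional decay structure, spliced or multimapping reads,
length distributions beyond the 21/22-nt phased classes, and
locus-to-locus interactions. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative assumptions, not
robustness to every artifact of real libraries.

## Numerical and design choices

- Multimapper allocation is a deliberately **simplified one-pass
  proportional split** by unique-read coverage within ±250 nt (window
  configurable), falling back to a uniform split when all neighborhoods are
  empty; totals are conserved exactly (float residue folded into the
  largest share). It implements the neighbor-coverage principle, not the
  iterative machinery of full sRNA aligners.
- Dominant-register ranking breaks ties toward the lower register index,
  making reports deterministic.
- Deletions are accepted as 1-based closed intervals (as printed for CRISPR
  truncations), converted internally, and rejected if they overlap a
  trigger binding site.
- Degenerate inputs: empty libraries raise (RPM undefined) rather than
  returning zeros; a zero simulation depth returns an empty read set;
  degenerate Fisher margins return p = 1 with a warning.
- The comparison pipeline never auto-classifies a locus as one-hit or
  two-hit from its signature; it reports the stage quantities with
  provenance (input digests, configuration, version) and leaves the
  interpretation to the analyst.

## Problem sizes

Tests and the acceptance script run on single loci of 700-nt transcripts
with libraries of 2 000–50 000 reads and 20–50 seed replicates per
property — sizes at which every multinomial expectation used in an
assertion is separated from its alternative by well over three standard
errors.

## Known limitations

- SAM support is a minimal unspliced subset (match-only CIGAR; counts in an
  `XC` tag); BED6 is the primary interchange format.
- The phasing-score family is implemented from its published functional
  form; per-pipeline calibrations of the 150 threshold differ between
  variants, so threshold and variant should always be reported together.
- Genome-wide de novo discovery of phased loci, miRNA target prediction,
  and figure rendering are out of scope; outputs are tables and bedGraph
  tracks.
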