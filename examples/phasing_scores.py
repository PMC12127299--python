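"""Phasing scores and register decomposition of a simulated cascade.

Simulates a one-hit locus whose phased production includes a tertiary
cascade (re-seeded by 22-nt secondary siRNAs at a +9 offset), computes the
sliding-window phasing-score track and the 21-spoke register profile, and
reports the dominant registers and their offset.
"""

from phasecascade import (
    LibraryStats,
    PhasingConfig,
    SimConfig,
    TriggerSite,
    build_locus,
    dominant_registers,
    phasing_track,
    register_offset,
    register_radial,
    simulate_srna,
)

locus = build_locus("one_hit", 700, [TriggerSite(140, 22, True)], locus_id="TAS_one")
cfg = SimConfig(srna_depth=50_000, phased_fraction=1.0, dcl2_fraction=0.1,
                tertiary_fraction=0.3, seed=5)
reads, truth = simulate_srna(locus, cfg)
stats = LibraryStats.from_reads(reads)

for numerator in ("damped", "raw"):
    phasing_cfg = PhasingConfig(score_numerator=numerator)
    track = phasing_track(reads, locus.span, phasing_cfg, stats)
    print(f"{numerator:>6} score: {len(track.scores)} scored coordinates, "
          f"{len(track.calls)} calls > {track.threshold:.0f}, "
          f"max score {max(track.scores.values()):.1f}")
print("The damped variant divides by out-of-register abundance, so the")
print("tertiary cascade suppresses the secondary score below threshold;")
print("the raw variant scores each register on its own abundance and calls")
print("the coordinates of both cascade generations.")

profile = register_radial(reads, truth.anchor, phasing_cfg, stats)
print("\nregister profile (RPM per spoke):")
for r in range(1, 22):
    bar = "#" * int(profile[r] / 2e4)
    print(f"  r{r:>2}: {profile[r]:>10.0f} {bar}")

secondary, tertiary = dominant_registers(profile, 2)
print(f"\ndominant registers: secondary={secondary}, tertiary={tertiary}, "
      f"offset={register_offset(secondary, tertiary)} nt")
print("A noise-free cascade puts secondary siRNAs on register 2 and the")
print("tertiary cascade on register 11 — a cyclic offset of 9 nt, the")
print("signature of re-targeting by a 22-nt secondary siRNA.")
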