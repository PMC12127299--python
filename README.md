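# phasecascade

Analysis toolkit for **phased secondary siRNA (ta-siRNA) biogenesis** at
plant *TAS* loci, built for researchers dissecting how trigger-miRNA
cleavage, phased dicing, and cascade re-targeting shape small-RNA output —
for example when comparing wild-type plants against CRISPR truncations of a
*TAS* transcript.

The package implements, as a reusable library:

- **Sliding-window phasing scores with 21-nt cyclic registers.** Each
  coordinate `x` gets a register `((x − anchor) mod 21) + 1`; a 189-nt
  window (nine complete 21-nt cycles) slides in 1-nt steps and scores the
  concentration of 5′-end abundance in the window-start register:

  `score = ln[(1 + 10·P/(1+U))^(k−2)]` for `k ≥ 3`, else 0,

  with `P` the in-register RPM, `U` the out-of-register RPM and `k` the
  occupied in-register cycle positions. Coordinates with score above a
  threshold (150 in the reference usage) are called phased. A raw-numerator
  variant (`ln[(1+10·P)^(k−2)]`) is pluggable.
- **Register ("radial") profiles** that decompose cascade generations: with
  the anchor one nucleotide 5′ of the trigger's scissile coordinate,
  canonical secondary siRNAs stack on register 2 and tertiary siRNAs —
  re-seeded by 22-nt secondary siRNAs — on register 11, a cyclic offset of
  9 nt (cleavage between trigger positions 10 and 11).
- **Degradome (PARE) cleavage-site quantification** — RPM of read 5′ ends
  exactly at a scissile coordinate — and the **cleavage-efficiency
  statistic** `degradome RPM / transcript FPKM`, with Fisher's exact test
  on pooled site counts and a one-sided Welch t-test on replicate
  efficiencies.
- **A generative simulator** of one-hit (single 22-nt trigger, 3′ fragment
  retained) and two-hit (dual 21-nt triggers, cleavage only at the 3′ site,
  5′ fragment retained) loci: phased 21-nt duplexes with 2-nt 3′ overhangs,
  a minority 22-nt DCL2 product class, a tertiary cascade at +9, uniform
  off-phase noise, degradome spikes over decay background, intact-transcript
  mRNA fragments, and CRISPR-style deletion intervals — with exported ground
  truth for every downstream stage.

## Worked example

`examples/phasing_scores.py` simulates a one-hit locus whose phased
production includes a 30 % tertiary cascade, scores it, and decomposes the
registers:

```
damped score: 276 scored coordinates, 0 calls > 150, max score 51.2
   raw score: 276 scored coordinates, 12 calls > 150, max score 250.6
...
register profile (RPM per spoke):
  r 2:     632480 ###############################
  r11:     268140 #############
dominant registers: secondary=2, tertiary=11, offset=9 nt
```

The two dominant spokes are the secondary phase (register 2) and the
tertiary cascade (register 11); their cyclic offset of 9 nt is the
signature of re-targeting by a 22-nt secondary siRNA. The damped score
treats the tertiary register as unphased mass, while the raw variant calls
the in-register coordinates of both generations.

`examples/wt_vs_deletion.py` runs the full wild-type vs truncation
comparison for both biogenesis models:

```
--- two_hit locus ---
   WT: sRNA RPM    914090  FPKM    8314  site RPM    1500  efficiency  0.180
  mut: sRNA RPM    914230  FPKM    2386  site RPM     460  efficiency  0.191
--- one_hit locus ---
   WT: sRNA RPM    913540  FPKM    8671  site RPM     940  efficiency  0.108
  mut: sRNA RPM    913000  FPKM    2871  site RPM    1240  efficiency  0.431
```

The two-hit deletion scenario shows the *stability* signature (intact
FPKM down ~3.5×, efficiency preserved); the one-hit scenario the
*processing* signature (efficiency up ~4×, phased output down). The other
examples cover the simulator's exported libraries and the closed-form
recovery of the efficiency ratio.

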