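"""Degradome cleavage-site quantification and the efficiency statistic.

Simulates degradome and mRNA libraries for a one-hit locus under two
conditions that differ only in the fraction of transcripts entering
cleavage, then recovers the cleavage-efficiency ratio
(degradome RPM at the scissile site / transcript FPKM) and compares it to
the generative closed form f/(1-f).
"""

import numpy as np

from phasecascade import (
    LibraryStats,
    SimConfig,
    TriggerSite,
    build_locus,
    cleavage_efficiency,
    efficiency_difference_test,
    fisher_cleavage_test,
    five_prime_profile,
    simulate_degradome,
    simulate_mrna,
    site_cleavage_rpm,
    transcript_fpkm,
)

locus = build_locus("one_hit", 700, [TriggerSite(140, 22, True)], locus_id="TAS_one")
site = locus.to_genomic(locus.cleavable_trigger.scissile_coord)

conditions = {"low_cleavage": 0.15, "high_cleavage": 0.30}
efficiencies, counts, totals = {}, {}, {}
for label, f in conditions.items():
    effs, cnt, tot = [], 0, 0
    for rep in range(2):
        cfg = SimConfig(cleaved_fraction=f, seed=10 + rep)
        deg, _ = simulate_degradome(locus, cfg)
        mrna, _ = simulate_mrna(locus, cfg)
        deg_stats = LibraryStats.from_reads(deg)
        profile = five_prime_profile(deg, locus.span, deg_stats)
        rpm = site_cleavage_rpm(profile, site)
        fpkm = transcript_fpkm(mrna, locus.span, LibraryStats.from_reads(mrna))
        effs.append(cleavage_efficiency(rpm, fpkm))
        cnt += sum(r.count for r in deg if r.chrom == locus.chrom and r.start == site)
        tot += deg_stats.total_mapped
    efficiencies[label], counts[label], totals[label] = effs, cnt, tot
    print(f"{label} (f={f}): site RPM/FPKM per replicate = "
          f"{[round(e, 3) for e in effs]}")

ratio = np.mean(efficiencies["high_cleavage"]) / np.mean(efficiencies["low_cleavage"])
f = conditions["low_cleavage"]
closed = (2 * f / (1 - 2 * f)) / (f / (1 - f))
print(f"\nmeasured efficiency ratio: {ratio:.3f}  (closed form {closed:.3f})")

odds, p_fisher = fisher_cleavage_test(
    counts["high_cleavage"], totals["high_cleavage"],
    counts["low_cleavage"], totals["low_cleavage"],
)
t, p_welch = efficiency_difference_test(
    efficiencies["high_cleavage"], efficiencies["low_cleavage"], "greater"
)
print(f"Fisher's exact (pooled site counts): odds={odds:.2f}, p={p_fisher:.3g}")
print(f"one-sided Welch t on replicate efficiencies: t={t:.2f}, p={p_welch:.3g}")
print("\nThe efficiency ratio tracks f/(1-f): doubling the cleaved fraction")
print("raises the degradome spike while depleting intact transcripts.")
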