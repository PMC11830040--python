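"""Dyad symmetry at CTCF motifs: strata spectra and distance to summits.

Builds motifs over a synthetic genome with peaks/summits over half of them,
simulates duplex dyads that are symmetrically unmodified near summits and
methylated elsewhere (the methylation-sensitive binding picture), and runs
the three motif analyses: stratum spectra with Cramér's V, the
distance-to-summit profile, and palindromic-motif orientation counts.
"""

import numpy as np

from cpgdyad import (
    DyadRecord,
    context_spectra,
    distance_profile,
    make_genome,
    palindrome_orientation,
    select_bound_motifs,
    simulate_annotations,
)
from cpgdyad.regulatory import summit_positions

sequences, cpgs, _ = make_genome(length_bp=200_000, seed=8)
ann = simulate_annotations(sequences, cpgs, seed=9, n_motifs=60,
                           palindromic_fraction=0.15, peak_fraction=0.5)
summits = summit_positions(ann.peaks)
motifs, bound = select_bound_motifs(ann.motifs, summits)

rng = np.random.default_rng(10)
dyads = []
for i, (chrom, pos) in enumerate(
    (c, int(p)) for c in cpgs for p in cpgs[c]
):
    if rng.random() > 0.2:
        continue
    near = any(abs(pos - s) < 100 for _, s in summits)
    if near:  # unmethylated, CTCF-compatible
        top = bottom = "C" if rng.random() < 0.85 else "5mC"
    else:
        top = bottom = "5mC" if rng.random() < 0.75 else "C"
        if rng.random() < 0.1:
            bottom = "C"  # some hemi-methylation away from summits
    dyads.append(DyadRecord(chrom, pos, top, bottom, read_id=f"r{i}"))

spectra = context_spectra([dyads], motifs, bound)
print(f"motifs: {len(motifs)}, bound by a summit: {len(bound)}")
for pair, res in spectra.cramers_v.items():
    print(f"  Cramer's V {pair[0]} vs {pair[1]}: {res.effect:.2f}")

profile = distance_profile(dyads, summits, max_dist=500)
print(f"dyads within 500 bp of a summit: {profile.n_retained}")
print(f"  Kruskal-Wallis H = {profile.kruskal.statistic:.1f}, "
      f"p = {profile.kruskal.pvalue:.2e}")
for cls, res in sorted(profile.point_biserial.items()):
    print(f"  r_pb({cls}) vs |distance| = {res.statistic:+.2f}")

summary = palindrome_orientation(motifs, ann.peaks, dyads)
print(f"palindromic motifs: {summary.n_palindromic}, bound: {summary.n_bound} "
      f"({summary.pct_bound:.1f}%)")
print("Symmetrically unmodified dyads concentrate near summits (negative "
      "r_pb for sym_C), while methylated dyads sit farther away — the "
      "methylation sensitivity expected of CTCF binding.")
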