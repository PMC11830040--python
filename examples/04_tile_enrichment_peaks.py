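"""Windowed 5hmC enrichment and validation of pulldown peaks against it.

Aggregates per-site calls into 500 bp tiles (tiles with < 10 CpG sites are
dropped), standardises the arcsine-transformed modification proportion to a
Z-score, then asks how many peaks (placed preferentially on enriched tiles,
as a pulldown would) land on tiles with Z > 0 and whether peak fold
enrichment tracks tile Z.
"""

import numpy as np

from cpgdyad import SiteCounts, aggregate_modification, peak_tile_concordance, tile_genome
from cpgdyad.simulate import simulate_peaks_for_scores

rng = np.random.default_rng(6)
tiles = tile_genome({"chr1": 200_000}, width_bp=500)
sites = []
for t in tiles:
    k = int(rng.integers(0, 50))  # per-tile 5hmC level
    for i in range(12):
        sites.append(SiteCounts(t.chrom, t.start + 4 * i, "+", 100 - k, 0, k))

records = aggregate_modification(sites, tiles, target="5hmC", min_cpg=10)
peaks = simulate_peaks_for_scores(
    [(r.interval, r.z) for r in records], n_peaks=150,
    enriched_fraction=0.9, seed=7,
)
summary = peak_tile_concordance(peaks, records)

zs = [r.z for r in records]
print(f"tiles retained: {len(records)}  (Z mean {np.mean(zs):.2e}, SD {np.std(zs):.2f})")
print(f"peaks assigned to a tile: {summary.n_assigned} "
      f"(unassigned: {summary.n_unassigned})")
print(f"peaks on enriched tiles (Z > 0): {100 * summary.fraction_z_positive:.1f}%")
print(f"Spearman rho, tile Z vs fold enrichment: "
      f"{summary.spearman.statistic:.2f} (p = {summary.spearman.pvalue:.2e})")
print("Most peaks validate against windowed enrichment, and stronger peaks "
      "sit on more strongly enriched tiles.")
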