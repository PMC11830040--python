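"""Phase reads over an imprinted DMR by methylation-state clustering.

No SNPs needed: at a germline DMR one parental allele is methylated and the
other is not, so encoding each read as a string of per-CpG states and
clustering the Hamming distance matrix (average linkage, cut at two
clusters) separates the alleles.
"""

import numpy as np

from cpgdyad import (
    ConfusionParams,
    GenomicInterval,
    phase_dmr,
    simulate_dmr_reads,
    simulate_truth,
)

dmr = GenomicInterval("chr7", 100_000, 101_000)
truth = simulate_truth(
    [("chr7", 100_010 + 30 * i) for i in range(30)], mode="dmr",
    params={"allele_ratio": 0.5, "p_5mC_methylated": 0.9,
            "p_5mC_unmethylated": 0.05},
    seed=4, confusion=ConfusionParams(),
)
calls, true_alleles = simulate_dmr_reads(truth, n_reads=300, seed=5,
                                         missing_rate=0.1)
result = phase_dmr(calls, dmr, max_absent_fraction=0.5)

assigned = result.allele_of()
accuracy = np.mean([assigned[r] == true_alleles[r] for r in assigned])
accuracy = max(accuracy, 1 - accuracy)
print(f"reads retained: {len(assigned)} (excluded: {len(result.excluded_reads)})")
print(f"allele ratio (methylated / all): {result.allele_ratio:.3f}")
print(f"mean 5mC fraction: methylated allele {result.mean_5mc_methylated:.2f}, "
      f"unmethylated {result.mean_5mc_unmethylated:.2f}")
print(f"agreement with planted alleles: {100 * accuracy:.1f}%")
print("A ~0.5 allele ratio with near-perfect assignment reflects biallelic "
      "coverage and clean allele-specific methylation at the locus.")
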