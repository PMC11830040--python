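# Methods

This note documents the models and procedures implemented in `cpgdyad`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Coordinates and data model

All coordinates are 0-based half-open. A CpG site is keyed by its
forward-strand C position; the reverse-strand C of the same dyad sits at
`pos + 1`, and per-strand pileup records are kept separate (`+` at `pos`,
`-` at `pos + 1`). Percent-modification values are always recomputed from
counts; any percentages present in input files are ignored, keeping counts
the single source of truth. The read-call table dialect is a declared
minimal column subset with a strict parser (unknown state codes, duplicate
read/site rows and count/depth inconsistencies are hard errors), insulating
the pipeline from upstream tool drift.

Soft-masking: masked regions may arrive as lowercase reference runs
(extracted by `softmask_intervals`) or as BED intervals; masked CpG sites
are dropped before any depth filtering or analysis.

## Accuracy benchmarking

The negative standard (whole-genome amplified) contains no modified bases,
so every modified call is a false positive; the positive standard is
enzymatically methylated, so 5mC calls are true positives and 5hmC calls are
classification errors. Two FPR readings coexist: `fpr` counts any modified
call on the negative standard (the definition used by `confusion_summary`),
while `fpr_5mc_only` excludes the 5hmC misclassifications; both are exposed
because accuracy tables for 5mC detection conventionally print the 5mC-only
rate. Precision, recall and F1 are computed from the rates
(`precision = TPR/(TPR+FPR)`, `recall = TPR/(TPR+FNR)`, F1 their harmonic
mean) by default. The count-based definitions are available under a flag;
they differ whenever the two standards contribute different call totals, so
the default favours comparability of rate-derived summaries across runs.
Summaries round rates to two decimals; raw values are retained.

GC stratification uses fixed-width windows (default 100 bp) computed
directly from the FASTA — GC fraction is (G+C)/(non-N), case-insensitive,
all-N windows omitted — and groups calls into twenty 5-percentage-point GC
bins. Computing GC from the FASTA rather than from a pre-averaged coverage
track can differ slightly at window edges; the formula itself is the
definition used here.

## Replicate deviation

"Matched CpG positions" means the same (chrom, position, strand) present
with depth at or above the threshold in **both** members of a pair; a
strand-merged comparison is available behind a flag. RMSD (and, for
cross-method pairs, MAD = median absolute deviation) of percent modification
is computed per pair and averaged over all pairs, with the mean matched-site
count reported alongside. For two binomial resamples at level *p* and depth
*d* the expected RMSD is `100·sqrt(2p(1−p)/d)`; the test suite checks the
implementation against this closed form within 2% relative error at 10⁵
sites.

## Windowed enrichment

Tiles are non-overlapping 500 bp windows from position 0 (final partial tile
retained and flagged). Per tile, the proportion of CpG-context base-calls
carrying the target modification is transformed as `asin(sqrt(p))` and
standardised to a Z-score. Numerical conventions:

- tiles with fewer than 10 distinct CpG dyads are dropped **before**
  standardisation, so Z is computed over retained tiles only;
- Z uses the population SD, pooled genome-wide (not per chromosome);
- a zero-SD collection yields Z = 0 everywhere.

Peak-to-tile assignment takes the tile with the maximal base-pair overlap,
keeps it only when that overlap covers at least half the peak, and breaks
ties toward the lower-coordinate tile. The "primary" feature class of a tile
is the class covering the most bases, ties broken by a fixed priority order
(promoter > 5'UTR > exon > intron > CGI > shore > shelf > intergenic).
Composition testing is a one-tailed binomial per class: n = peaks,
k = peaks on tiles primarily of that class, p = the background fraction of
tiles primarily of that class.

## Duplex dyad spectra

Only dyads with both strands called enter the spectrum; simplex calls never
do. Classification is unordered — (x, y) and (y, x) are the same class — but
an ordered (strand-aware) view is retained because the motif-orientation
analysis needs to know which strand carries the unmodified C. "Hetero" is
strictly {5mC, 5hmC}. The derived fractions are:
asymmetric = (hemi-5mC + hemi-5hmC + hetero)/total and
5hmC-partnered-with-5mC = hetero/(hemi-5hmC + hetero + sym-5hmC). Both
per-dyad and per-base-call denominators give identical proportions under
symmetric counting, so the per-dyad reading is reported.

The G-test uses `G = 2·Σ O·ln(O/E)` over classes with O > 0, expected
counts from the reference proportions times the observed total, df = number
of classes − 1, p from the chi-square distribution. Cramér's V drops classes
empty in both spectra (with a warning) before testing.

## Phasing

Encoding uses four nominal symbols (C, 5mC, 5hmC, absent). Defaults and the
reasoning where the procedure admits choices:

- `max_absent_fraction = 0.5` (midpoint convention; exposed as a flag) —
  reads with more than half their DMR positions uncalled are excluded;
- absent participates in the Hamming distance as a literal symbol; a masked
  variant (ignore positions absent in either read, rescale to the full
  position count) is available for robustness studies;
- clustering is agglomerative with average linkage (UPGMA) — the mean
  distance between reads and then between successive clusters — and the tree
  is cut into exactly two clusters, matching the two-allele use;
- the cluster with the higher mean 5mC code fraction is labelled
  "methylated"; an exact tie labels the larger cluster methylated with a
  warning;
- reads are processed in a canonical (sorted-ID) order, so the partition is
  invariant to input order;
- if every pairwise distance is zero the reads cannot be split and a flagged
  single-cluster result is returned.

On planted two-allele simulations (30 CpGs, per-site P(5mC) 0.9 vs 0.05, 200
reads per allele) phasing recovers the planted labels essentially perfectly;
with 400 reads the planted allele fraction itself fluctuates with SD ≈ 0.025
around 0.5, which bounds how tightly any estimator's ratio can sit near 0.5
on a single simulation.

## CTCF motif analyses

Two distinct binding predicates are used deliberately: for stratum spectra a
motif is *bound* when it contains a ChIP summit (half-open containment); for
palindromic-motif counts a motif is *bound* when it overlaps a peak interval
by ≥ 1 bp — summit and peak are different objects. Distance profiles use the
forward-C position of the dyad, absolute distance to the nearest summit
(ties to the lower coordinate), and truncate at 500 bp. Dunn's post-hoc test
is implemented from the standard pooled-rank formula with tie correction
(no pre-installed package provides it) and Holm–Bonferroni adjustment comes
from statsmodels. The point-biserial correlation is, by definition, the
Pearson correlation of the class indicator with distance, and is tested
against that identity. Asymmetric methylation at a motif means at least one
hemi-methylated (C:5mC) dyad inside the motif interval; hemi-5hmC and hetero
counts are reported separately so broader readings remain recoverable.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are exercised under:

| knob | default | meaning |
| --- | --- | --- |
| confusion P(5mC\|C) | 0.0056 | 5mC false-call rate on unmodified C |
| confusion P(5hmC\|C) | 0.0024 | 5hmC false-call rate on unmodified C |
| confusion P(5mC\|5mC) | 0.97 | 5mC TPR |
| confusion P(5hmC\|5mC) | 0.011 | 5hmC misclassification of methylated C |
| confusion row for true 5hmC | (0.02, 0.03, 0.95) | assumed — no ground-truth 5hmC control exists, so this row is a documented assumption |
| duplex rate | 0.32 | fraction of templates captured as duplex |
| dyad table | 0.235 / 0.525 / 0.029 / 0.063 / 0.020 / 0.128 | sym-C, sym-5mC, sym-5hmC, hemi-5mC, hemi-5hmC, hetero; the sym-5hmC entry is the remainder after the five directly specified classes |
| depth model | Poisson, log-linear GC term | `λ = mean_depth · exp(β(GC − 0.5))`; negative β depresses coverage at high GC |
| beta mixture | weights (0.38, 0.62), Beta(0.5, 10) and Beta(10, 0.5) | bimodal fully-unmethylated / fully-methylated site landscape |

Strand errors are independent given the true dyad state — the minimal
assumption in the absence of any measured strand-error correlation — and
noted as a knob. Genome construction compensates the background base
composition so that planted CpG dinucleotides do not push overall GC above
the target. Annotations tile each chromosome with non-overlapping primary
features; CpG-island shores are the 2 kb flanks and shelves the 2–4 kb
flanks, clipped at chromosome ends.

What the generator does **not** emulate: raw signal, basecall quality,
read-length distributions, indels/SNPs, correlated errors along a read,
context-dependent error motifs, and real genomic feature structure
(annotation geometry is simplified). Passing tests therefore demonstrate
that the statistics recover configured generative parameters and match
independent oracles — not that any particular biological dataset would
reproduce specific published values.

## Problem sizes

Defaults in tests and the acceptance script: 10⁵ sites/calls for frequency
recovery and closed-form RMSD checks, 50 seeded phasing simulations of 400
reads each, 400 tiles with 300 peaks for enrichment concordance. These sizes
put Monte-Carlo error well inside the asserted tolerances (3 binomial SE, 2%
relative for the RMSD closed form) while keeping a full run fast on a single
CPU.
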