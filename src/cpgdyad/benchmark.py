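"""Accuracy benchmarking against methylation standards and deviation metrics.

The standards design: a whole-genome-amplified negative control has no
modified bases, so every modified call is a false positive; an enzymatically
methylated positive control is (near-)fully 5mC, so non-5mC calls are errors
and 5hmC calls specifically are classification errors.

Derived accuracy metrics follow the rate-based definitions
``precision = TPR / (TPR + FPR)``, ``recall = TPR / (TPR + FNR)`` and
``F1 = 2 * precision * recall / (precision + recall)``; the conventional
count-based definitions are available under a flag (they differ when the two
standards contribute different call counts).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import STATES, GenomicInterval, ReadCall, SiteCounts, StatResult

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def percent_modification(n_C: int, n_5mC: int, n_5hmC: int) -> tuple[float, float]:
    """Percent 5mC and 5hmC of all C-state calls at a site.

    ``pct_X = 100 * n_X / (n_C + n_5mC + n_5hmC)``.
    """
    total = n_C + n_5mC + n_5hmC
    if min(n_C, n_5mC, n_5hmC) < 0:
        raise ValueError("negative count")
    if total == 0:
        raise ValueError("zero total count")
    return 100.0 * n_5mC / total, 100.0 * n_5hmC / total


def count_calls(calls: Iterable[ReadCall]) -> np.ndarray:
    """Counts of observed states (C, 5mC, 5hmC) over a call stream.

    Duplex records contribute both strand calls.
    """
    counts = np.zeros(3, dtype=np.int64)
    for c in calls:
        counts[_STATE_INDEX[c.call_state]] += 1
        if c.is_duplex:
            counts[_STATE_INDEX[c.partner_state]] += 1
    return counts


@dataclass
class ConfusionSummary:
    """Accuracy of 5mC detection from a pair of labelled standards."""

    tpr: float
    fpr: float
    precision: float
    recall: float
    f1: float
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((2, 3), dtype=np.int64))
    from_rates: bool = True

    @property
    def fnr(self) -> float:
        return 1.0 - self.tpr

    @property
    def fpr_5mc_only(self) -> float:
        """False 5mC calls over all negative-standard calls (excludes the
        5hmC misclassifications counted by ``fpr``)."""
        neg = self.matrix[0]
        return float(neg[1] / neg.sum())

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            k: round(getattr(self, k), ndigits)
            for k in ("tpr", "fnr", "fpr", "precision", "recall", "f1")
        }


def metrics_from_rates(tpr: float, fpr: float, fnr: float | None = None) -> tuple[float, float, float]:
    """Precision, recall, F1 from the rate-based definitions."""
    if fnr is None:
        fnr = 1.0 - tpr
    precision = tpr / (tpr + fpr)
    recall = tpr / (tpr + fnr)
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def confusion_summary(
    negative_calls: Iterable[ReadCall],
    positive_calls: Iterable[ReadCall],
    from_rates: bool = True,
) -> ConfusionSummary:
    """Summarise 5mC detection accuracy from the two standards.

    Negative standard: true state C everywhere; any 5mC or 5hmC call is a
    false positive.  Positive standard: true state 5mC; 5mC calls are true
    positives, anything else a false negative.  With ``from_rates`` (default)
    precision/recall/F1 come from the TPR/FPR/FNR rates; otherwise from raw
    TP/FP/FN counts.
    """
    neg = count_calls(negative_calls)
    pos = count_calls(positive_calls)
    if neg.sum() == 0 or pos.sum() == 0:
        raise ValueError("empty call stream for a standard")
    fpr = (neg[1] + neg[2]) / neg.sum()
    tpr = pos[1] / pos.sum()
    if from_rates:
        precision, recall, f1 = metrics_from_rates(tpr, fpr)
    else:
        tp = pos[1]
        fp = neg[1] + neg[2]
        fn = pos[0] + pos[2]
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
    return ConfusionSummary(
        tpr=float(tpr), fpr=float(fpr),
        precision=float(precision), recall=float(recall), f1=float(f1),
        matrix=np.vstack([neg, pos]), from_rates=from_rates,
    )


def classification_error_5hmc(calls: Iterable[ReadCall]) -> float:
    """Fraction of calls in a stream that are 5hmC (misclassification rate on
    a standard containing no 5hmC)."""
    counts = count_calls(calls)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty call stream")
    return float(counts[2] / total)


# ---------------------------------------------------------------------------
# FPR stratifications
# ---------------------------------------------------------------------------

def fpr_vs_gc(
    calls: Sequence[ReadCall],
    gc_windows: Sequence[tuple[GenomicInterval, float]],
    n_bins: int = 20,
) -> tuple[list[dict], StatResult]:
    """False-positive rate of modification calls binned by local GC content.

    Calls (all from an unmodified standard) are mapped to their GC window;
    windows are grouped into ``n_bins`` equal GC-percentage bins spanning
    0-100%.  The per-bin FPR is modified calls over all calls in the bin; a
    Pearson correlation between bin midpoints and bin FPRs is computed over
    non-empty bins (flagged undefined when fewer than 3 are non-empty).
    """
    lookup: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    for iv, gc in gc_windows:
        lookup[iv.chrom].append((iv.start, iv.end, gc))
    for v in lookup.values():
        v.sort()
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    n_all = np.zeros(n_bins, dtype=np.int64)
    n_mod = np.zeros(n_bins, dtype=np.int64)
    for c in calls:
        wins = lookup.get(c.chrom)
        if not wins:
            continue
        gc = None
        # windows are non-overlapping and sorted; binary search by start
        starts = [w[0] for w in wins]
        i = np.searchsorted(starts, c.cpg_pos, side="right") - 1
        if i >= 0 and wins[i][0] <= c.cpg_pos < wins[i][1]:
            gc = wins[i][2]
        if gc is None:
            continue
        b = min(int(gc * 100.0 / (100.0 / n_bins)), n_bins - 1)
        n_all[b] += 1
        if c.call_state != "C":
            n_mod[b] += 1
    rows = []
    mids, fprs = [], []
    for b in range(n_bins):
        if n_all[b] == 0:
            continue
        fpr = n_mod[b] / n_all[b]
        mid = (edges[b] + edges[b + 1]) / 2.0
        rows.append(
            {"gc_lo": edges[b], "gc_hi": edges[b + 1], "gc_mid": mid,
             "n_calls": int(n_all[b]), "fpr": float(fpr)}
        )
        mids.append(mid)
        fprs.append(fpr)
    if len(rows) < 3:
        res = StatResult("pearson", float("nan"), float("nan"),
                         n=len(rows), note="fewer than 3 non-empty bins")
    else:
        r, p = sps.pearsonr(mids, fprs)
        res = StatResult("pearson", float(r), float(p),
                         effect=float(r), effect_name="r", n=len(rows))
    return rows, res


def fpr_by_context(
    calls: Sequence[ReadCall],
    contexts: dict[str, Sequence[GenomicInterval]],
) -> dict[str, dict]:
    """Per-context-class FPR of modification calls from an unmodified standard.

    Context classes may overlap; a call is attributed to every class whose
    intervals contain it.  A ``genomic_mean`` row covers all calls.  Classes
    receiving zero calls are absent from the output.
    """
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for name, ivs in contexts.items():
        for iv in ivs:
            by_chrom.setdefault(name, {}).setdefault(iv.chrom, []).append(
                (iv.start, iv.end)
            )
    tallies: dict[str, list[int]] = {name: [0, 0] for name in contexts}
    tallies["genomic_mean"] = [0, 0]
    for c in calls:
        is_mod = c.call_state != "C"
        tallies["genomic_mean"][0] += 1
        tallies["genomic_mean"][1] += int(is_mod)
        for name in contexts:
            spans = by_chrom.get(name, {}).get(c.chrom, ())
            if any(s <= c.cpg_pos < e for s, e in spans):
                tallies[name][0] += 1
                tallies[name][1] += int(is_mod)
    return {
        name: {"n_calls": n, "n_modified": m, "fpr": m / n}
        for name, (n, m) in tallies.items()
        if n > 0
    }


# ---------------------------------------------------------------------------
# pileups from reads
# ---------------------------------------------------------------------------

def pileup_from_reads(
    calls: Iterable[ReadCall],
    min_depth: int = 5,
    mask: Sequence[GenomicInterval] | None = None,
) -> list[SiteCounts]:
    """Per-(site, strand) pileup of read calls with masking and a depth filter.

    Duplex records contribute the forward call at (cpg_pos, +) and the reverse
    call at (cpg_pos + 1, -); simplex ``-`` records likewise pile at
    cpg_pos + 1.  Sites inside mask intervals (compared at the forward-C
    position) are dropped before the depth filter.
    """
    masked: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in mask or ():
        masked[iv.chrom].append((iv.start, iv.end))

    def _is_masked(chrom: str, fwd_pos: int) -> bool:
        return any(s <= fwd_pos < e for s, e in masked.get(chrom, ()))

    counts: dict[tuple[str, int, str], np.ndarray] = defaultdict(
        lambda: np.zeros(3, dtype=np.int64)
    )
    for c in calls:
        if masked and _is_masked(c.chrom, c.cpg_pos):
            continue
        if c.is_duplex:
            counts[(c.chrom, c.cpg_pos, "+")][_STATE_INDEX[c.call_state]] += 1
            counts[(c.chrom, c.cpg_pos + 1, "-")][_STATE_INDEX[c.partner_state]] += 1
        else:
            pos = c.cpg_pos if c.strand == "+" else c.cpg_pos + 1
            counts[(c.chrom, pos, c.strand)][_STATE_INDEX[c.call_state]] += 1
    out = [
        SiteCounts(chrom, pos, strand, int(v[0]), int(v[1]), int(v[2]))
        for (chrom, pos, strand), v in counts.items()
    ]
    out.sort(key=lambda s: s.key)
    return [s for s in out if s.depth >= min_depth]


# ---------------------------------------------------------------------------
# intra- and inter-assay deviation
# ---------------------------------------------------------------------------

@dataclass
class DeviationSummary:
    """Mean pairwise deviation between replicates at one depth threshold."""

    method_pair: tuple[str, str]
    depth_threshold: int
    rmsd: float
    mad: float
    n_sites_compared: float
    n_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_sites_compared > 0 and self.rmsd == self.rmsd


def _pct_map(
    pileup: Sequence[SiteCounts], which: str, threshold: int,
    merge_strands: bool,
) -> dict[tuple, float]:
    """Site -> percent modification for sites at or above a depth threshold."""
    if not merge_strands:
        return {
            s.key: (s.pct_5mC if which == "5mC" else s.pct_5hmC)
            for s in pileup
            if s.depth >= threshold
        }
    merged: dict[tuple[str, int], np.ndarray] = defaultdict(
        lambda: np.zeros(3, dtype=np.int64)
    )
    for s in pileup:
        fwd = s.cpg_pos if s.strand == "+" else s.cpg_pos - 1
        merged[(s.chrom, fwd)] += np.array([s.n_C, s.n_5mC, s.n_5hmC])
    out = {}
    for key, v in merged.items():
        depth = int(v.sum())
        if depth >= threshold:
            n = v[1] if which == "5mC" else v[2]
            out[key] = 100.0 * n / depth
    return out


def _pair_deviation(
    a: Sequence[SiteCounts], b: Sequence[SiteCounts], threshold: int,
    which: str, merge_strands: bool,
) -> tuple[float, float, int]:
    pa = _pct_map(a, which, threshold, merge_strands)
    pb = _pct_map(b, which, threshold, merge_strands)
    common = pa.keys() & pb.keys()
    if not common:
        return float("nan"), float("nan"), 0
    diffs = np.array([pa[k] - pb[k] for k in common])
    rmsd = float(np.sqrt(np.mean(diffs**2)))
    mad = float(np.median(np.abs(diffs)))
    return rmsd, mad, len(common)


def intra_assay(
    replicates: Sequence[Sequence[SiteCounts]],
    depth_thresholds: Sequence[int] = (5, 10, 15),
    which: str = "5mC",
    merge_strands: bool = False,
    label: str = "intra",
) -> list[DeviationSummary]:
    """Mean pairwise RMSD between replicates of one method at several depths.

    For each unordered replicate pair and threshold, comparison is restricted
    to sites with depth >= threshold in *both* members; the RMSD of percent
    modification over matched sites is averaged over pairs, alongside the
    mean matched-site count.
    """
    if len(replicates) < 2:
        raise ValueError("intra-assay deviation needs >= 2 replicates")
    out = []
    for thr in depth_thresholds:
        rmsds, mads, ns = [], [], []
        for a, b in itertools.combinations(replicates, 2):
            rmsd, mad, n = _pair_deviation(a, b, thr, which, merge_strands)
            if n > 0:
                rmsds.append(rmsd)
                mads.append(mad)
            ns.append(n)
        out.append(
            DeviationSummary(
                method_pair=(label, label), depth_threshold=thr,
                rmsd=float(np.mean(rmsds)) if rmsds else float("nan"),
                mad=float(np.mean(mads)) if mads else float("nan"),
                n_sites_compared=float(np.mean(ns)) if ns else 0.0,
                n_pairs=len(ns),
            )
        )
    return out


def inter_assay(
    method_a_reps: Sequence[Sequence[SiteCounts]],
    method_b_reps: Sequence[Sequence[SiteCounts]],
    depth_thresholds: Sequence[int] = (5, 10, 15),
    which: str = "5mC",
    merge_strands: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> list[DeviationSummary]:
    """Mean pairwise RMSD and MAD between all cross pairs of two methods."""
    if not method_a_reps or not method_b_reps:
        raise ValueError("both methods need >= 1 replicate")
    out = []
    for thr in depth_thresholds:
        rmsds, mads, ns = [], [], []
        for a in method_a_reps:
            for b in method_b_reps:
                rmsd, mad, n = _pair_deviation(a, b, thr, which, merge_strands)
                if n > 0:
                    rmsds.append(rmsd)
                    mads.append(mad)
                ns.append(n)
        out.append(
            DeviationSummary(
                method_pair=labels, depth_threshold=thr,
                rmsd=float(np.mean(rmsds)) if rmsds else float("nan"),
                mad=float(np.mean(mads)) if mads else float("nan"),
                n_sites_compared=float(np.mean(ns)) if ns else 0.0,
                n_pairs=len(ns),
            )
        )
    return out


def depth_gc_correlation(
    pileup: Sequence[SiteCounts],
    gc_windows: Sequence[tuple[GenomicInterval, float]],
    below_mean_only: bool = False,
) -> StatResult:
    """Spearman correlation of per-window mean depth with window GC content.

    With ``below_mean_only`` the correlation is restricted to windows with GC
    below the mean GC of all windows carrying sites.
    """
    lookup: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    for iv, gc in gc_windows:
        lookup[iv.chrom].append((iv.start, iv.end, gc))
    for v in lookup.values():
        v.sort()
    depth_sum: dict[tuple[str, int], float] = defaultdict(float)
    n_sites: dict[tuple[str, int], int] = defaultdict(int)
    gc_of: dict[tuple[str, int], float] = {}
    for s in pileup:
        wins = lookup.get(s.chrom)
        if not wins:
            continue
        starts = [w[0] for w in wins]
        i = int(np.searchsorted(starts, s.cpg_pos, side="right")) - 1
        if i < 0 or not (wins[i][0] <= s.cpg_pos < wins[i][1]):
            continue
        key = (s.chrom, wins[i][0])
        depth_sum[key] += s.depth
        n_sites[key] += 1
        gc_of[key] = wins[i][2]
    if len(depth_sum) < 3:
        return StatResult("spearman", float("nan"), float("nan"),
                          n=len(depth_sum), note="fewer than 3 windows with sites")
    keys = sorted(depth_sum)
    depths = np.array([depth_sum[k] / n_sites[k] for k in keys])
    gcs = np.array([gc_of[k] for k in keys])
    if below_mean_only:
        keep = gcs < gcs.mean()
        depths, gcs = depths[keep], gcs[keep]
        if len(depths) < 3:
            return StatResult("spearman", float("nan"), float("nan"),
                              n=len(depths), note="too few below-mean windows")
    if np.all(depths == depths[0]) or np.all(gcs == gcs[0]):
        return StatResult("spearman", float("nan"), float("nan"),
                          n=len(depths), note="constant depth or GC")
    rho, p = sps.spearmanr(gcs, depths)
    return StatResult("spearman", float(rho), float(p),
                      effect=float(rho), effect_name="rho", n=len(depths))
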