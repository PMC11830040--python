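"""Windowed modification enrichment: arcsine Z-scores, peak validation,
feature composition.

Enrichment of a modification over an interval is the proportion of all
CpG-context base-calls in the interval carrying that modification,
arcsine-square-root transformed to approximate normality, then standardised
to a Z-score across all retained intervals (population SD, genome-wide
pooling).  Intervals with fewer than ``min_cpg`` distinct CpG sites are
discarded *before* standardisation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import GenomicInterval, NarrowPeak, SiteCounts, StatResult


@dataclass
class EnrichmentRecord:
    """Modification enrichment of one genomic interval."""

    interval: GenomicInterval
    n_calls: int
    n_mod: int
    n_cpg_sites: int
    proportion: float
    arcsine_value: float
    z: float = float("nan")


def tile_genome(
    chrom_sizes: dict[str, int], width_bp: int = 500
) -> list[GenomicInterval]:
    """Non-overlapping half-open tiles from position 0 of each chromosome.

    The final partial tile is retained and flagged via ``feature_class``.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    tiles = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, width_bp):
            end = min(start + width_bp, size)
            tiles.append(
                GenomicInterval(
                    chrom, start, end,
                    feature_class="partial_tile" if end - start < width_bp else None,
                )
            )
    return tiles


def aggregate_modification(
    pileup: Sequence[SiteCounts],
    intervals: Sequence[GenomicInterval],
    target: str = "5hmC",
    min_cpg: int = 10,
) -> list[EnrichmentRecord]:
    """Aggregate per-site calls over intervals and standardise enrichment.

    ``n_calls`` sums site depths, ``n_mod`` the target-state calls;
    ``n_cpg_sites`` counts distinct CpG dyads (strand records collapsed to
    the forward-C position).  Intervals failing ``min_cpg`` are dropped, then
    Z-scores are computed over the retained records only (population SD; a
    zero-SD collection yields z = 0 everywhere).
    """
    if target not in ("5mC", "5hmC"):
        raise ValueError(f"unknown target {target!r}")
    sites_by_chrom: dict[str, list[SiteCounts]] = defaultdict(list)
    for s in pileup:
        sites_by_chrom[s.chrom].append(s)
    for v in sites_by_chrom.values():
        v.sort(key=lambda s: s.cpg_pos)
    records = []
    for iv in intervals:
        sites = sites_by_chrom.get(iv.chrom, [])
        positions = [s.cpg_pos for s in sites]
        lo = int(np.searchsorted(positions, iv.start, side="left"))
        hi = int(np.searchsorted(positions, iv.end, side="left"))
        n_calls = 0
        n_mod = 0
        fwd_positions = set()
        for s in sites[lo:hi]:
            n_calls += s.depth
            n_mod += s.n_5hmC if target == "5hmC" else s.n_5mC
            fwd_positions.add(s.cpg_pos if s.strand == "+" else s.cpg_pos - 1)
        if len(fwd_positions) < min_cpg or n_calls == 0:
            continue
        prop = n_mod / n_calls
        records.append(
            EnrichmentRecord(
                interval=iv, n_calls=n_calls, n_mod=n_mod,
                n_cpg_sites=len(fwd_positions), proportion=prop,
                arcsine_value=math.asin(math.sqrt(prop)),
            )
        )
    if not records:
        raise ValueError("all intervals dropped by the CpG-count filter")
    vals = np.array([r.arcsine_value for r in records])
    sd = float(vals.std())  # population SD
    mean = float(vals.mean())
    for r in records:
        r.z = (r.arcsine_value - mean) / sd if sd > 0 else 0.0
    return records


def assign_peaks(
    peaks: Sequence[NarrowPeak],
    tiles: Sequence[GenomicInterval],
    min_overlap_fraction: float = 0.5,
) -> tuple[dict[int, GenomicInterval], list[int]]:
    """Assign each peak to the tile with maximal base-pair overlap.

    The assignment is kept only when that overlap covers at least
    ``min_overlap_fraction`` of the peak's length; ties resolve to the
    lower-coordinate tile.  Returns (peak index -> tile, unassigned indices).
    """
    tiles_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for t in tiles:
        tiles_by_chrom[t.chrom].append(t)
    for v in tiles_by_chrom.values():
        v.sort(key=lambda t: t.start)
    assigned: dict[int, GenomicInterval] = {}
    unassigned: list[int] = []
    for i, peak in enumerate(peaks):
        iv = peak.interval
        cand = tiles_by_chrom.get(iv.chrom, [])
        starts = [t.start for t in cand]
        lo = max(0, int(np.searchsorted(starts, iv.start, side="right")) - 1)
        best: GenomicInterval | None = None
        best_ov = 0
        for t in cand[lo:]:
            if t.start >= iv.end:
                break
            ov = iv.overlap(t)
            if ov > best_ov:  # strict: first (lowest-coordinate) tile wins ties
                best_ov = ov
                best = t
        if best is not None and best_ov >= min_overlap_fraction * len(iv):
            assigned[i] = best
        else:
            unassigned.append(i)
    return assigned, unassigned


@dataclass
class ConcordanceSummary:
    """Agreement between peaks and windowed enrichment."""

    fraction_z_positive: float
    spearman: StatResult
    n_assigned: int
    n_unassigned: int


def peak_tile_concordance(
    peaks: Sequence[NarrowPeak],
    records: Sequence[EnrichmentRecord],
    min_overlap_fraction: float = 0.5,
) -> ConcordanceSummary:
    """Fraction of assigned peaks whose tile is enriched (z > 0), plus the
    Spearman correlation of tile z with peak fold enrichment."""
    rec_by_tile = {
        (r.interval.chrom, r.interval.start, r.interval.end): r for r in records
    }
    tiles = [r.interval for r in records]
    assigned, unassigned = assign_peaks(peaks, tiles, min_overlap_fraction)
    if not assigned:
        raise ValueError("no peaks assigned to retained tiles")
    zs, fes = [], []
    n_pos = 0
    for i, tile in assigned.items():
        r = rec_by_tile[(tile.chrom, tile.start, tile.end)]
        zs.append(r.z)
        fes.append(peaks[i].fold_enrichment)
        if r.z > 0:
            n_pos += 1
    if len(zs) >= 3 and len(set(zs)) > 1 and len(set(fes)) > 1:
        rho, p = sps.spearmanr(zs, fes)
        sp = StatResult("spearman", float(rho), float(p),
                        effect=float(rho), effect_name="rho", n=len(zs))
    else:
        sp = StatResult("spearman", float("nan"), float("nan"),
                        n=len(zs), note="degenerate or too few assigned peaks")
    return ConcordanceSummary(
        fraction_z_positive=n_pos / len(assigned),
        spearman=sp,
        n_assigned=len(assigned),
        n_unassigned=len(unassigned),
    )


#: Tie-break priority for the primary feature class of a tile.
FEATURE_PRIORITY = (
    "promoter", "5utr", "exon", "intron", "CGI", "shore", "shelf", "intergenic"
)


def primary_feature_of_tiles(
    tiles: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
) -> dict[tuple[str, int, int], str]:
    """Primary feature class of each tile: largest covered base count, ties
    broken by a fixed priority order (promoter first, intergenic last)."""
    feats_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for f in features:
        if f.feature_class is None:
            raise ValueError("feature interval lacks a feature_class")
        feats_by_chrom[f.chrom].append(f)
    for v in feats_by_chrom.values():
        v.sort(key=lambda f: f.start)
    rank = {c: i for i, c in enumerate(FEATURE_PRIORITY)}
    out: dict[tuple[str, int, int], str] = {}
    for t in tiles:
        cover: dict[str, int] = defaultdict(int)
        for f in feats_by_chrom.get(t.chrom, []):
            if f.start >= t.end:
                break
            ov = t.overlap(f)
            if ov > 0:
                cover[f.feature_class] += ov
        if not cover:
            continue
        best = min(
            cover.items(),
            key=lambda kv: (-kv[1], rank.get(kv[0], len(rank))),
        )[0]
        out[(t.chrom, t.start, t.end)] = best
    return out


def composition_test(
    peak_classes: Sequence[str],
    background_classes: Sequence[str],
) -> dict[str, StatResult]:
    """One-tailed binomial tests of peak feature composition vs background.

    For each feature class: n = number of peaks, k = peaks whose assigned tile
    is primarily that class, p = background fraction of tiles primarily that
    class; the p-value is P(X >= k) under Binomial(n, p).  Classes absent from
    the background are skipped (noted in the result of remaining classes would
    be misleading, so they are simply omitted).
    """
    n = len(peak_classes)
    if n == 0:
        raise ValueError("no peak classes supplied")
    if not background_classes:
        raise ValueError("no background classes supplied")
    bg_total = len(background_classes)
    bg_counts: dict[str, int] = defaultdict(int)
    for c in background_classes:
        bg_counts[c] += 1
    peak_counts: dict[str, int] = defaultdict(int)
    for c in peak_classes:
        peak_counts[c] += 1
    out: dict[str, StatResult] = {}
    for cls, k in sorted(peak_counts.items()):
        if cls not in bg_counts:
            continue  # class absent from background: test undefined
        p = bg_counts[cls] / bg_total
        res = sps.binomtest(k, n, p, alternative="greater")
        out[cls] = StatResult(
            "binomial-one-tailed", float(k), float(res.pvalue), n=n,
            extras={"background_p": p, "k": k},
        )
    return out


def cross_method_correlation(
    records_a: Sequence[EnrichmentRecord],
    records_b: Sequence[EnrichmentRecord],
) -> StatResult:
    """Spearman correlation of Z-scores between two methods on matched tiles."""
    za = {
        (r.interval.chrom, r.interval.start, r.interval.end): r.z for r in records_a
    }
    zb = {
        (r.interval.chrom, r.interval.start, r.interval.end): r.z for r in records_b
    }
    common = sorted(za.keys() & zb.keys())
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched intervals; need >= 3")
    a = np.array([za[k] for k in common])
    b = np.array([zb[k] for k in common])
    rho, p = sps.spearmanr(a, b)
    return StatResult("spearman", float(rho), float(p),
                      effect=float(rho), effect_name="rho", n=len(common))
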