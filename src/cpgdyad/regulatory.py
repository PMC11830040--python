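"""CTCF-motif methylation-sensitivity analyses.

Three questions about duplex dyad states around CTCF binding:

1. Do dyad spectra differ between the genome background, CpGs inside CTCF
   motifs, and CpGs inside *bound* motifs (motifs containing a ChIP-seq
   summit)?  Quantified with Cramér's V and per-class paired t-tests across
   replicates (paired because the strata are nested subsets).
2. Does dyad class relate to distance from the nearest summit?  Kruskal–Wallis
   omnibus, Dunn's pairwise post-hoc with Holm–Bonferroni correction, and a
   per-class point-biserial correlation of the class indicator with absolute
   distance.
3. At palindromic motifs intersecting peaks, how often does asymmetric
   (hemi-)methylation occur, and on which strand does the unmodified C sit?
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import GenomicInterval, DyadRecord, NarrowPeak, StatResult
from . import stats as _stats


@dataclass(frozen=True)
class MotifSite:
    """A located sequence motif (~20 bp) containing at least one CpG."""

    interval: GenomicInterval
    motif_strand: str
    is_palindromic: bool = False
    cpg_positions: tuple[int, ...] = ()
    bound: bool = False

    def __post_init__(self) -> None:
        if self.motif_strand not in ("+", "-"):
            raise ValueError(f"invalid motif strand {self.motif_strand!r}")


def summit_positions(peaks: Iterable[NarrowPeak]) -> list[tuple[str, int]]:
    """Absolute (chrom, summit) positions of a peak collection."""
    return [(p.interval.chrom, p.summit) for p in peaks]


def select_bound_motifs(
    motifs: Sequence[MotifSite], summits: Iterable[tuple[str, int]]
) -> tuple[list[MotifSite], list[MotifSite]]:
    """Partition motifs by whether they contain a ChIP summit (half-open).

    Returns (all motifs with `bound` flags set, the bound subset).
    """
    summit_list = list(summits)
    flagged: list[MotifSite] = []
    bound: list[MotifSite] = []
    for m in motifs:
        is_bound = any(m.interval.contains(c, s) for c, s in summit_list)
        fm = MotifSite(
            interval=m.interval, motif_strand=m.motif_strand,
            is_palindromic=m.is_palindromic, cpg_positions=m.cpg_positions,
            bound=is_bound,
        )
        flagged.append(fm)
        if is_bound:
            bound.append(fm)
    return flagged, bound


def _dyads_in_intervals(
    dyads: Sequence[DyadRecord], intervals: Sequence[GenomicInterval]
) -> list[DyadRecord]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for d in dyads:
        for start, end in by_chrom.get(d.chrom, ()):
            if start <= d.cpg_pos < end:
                out.append(d)
                break
    return out


@dataclass
class ContextSpectra:
    """Per-stratum dyad spectra with association and paired per-class tests."""

    spectra: dict[str, "object"]  # stratum -> pooled DyadSpectrum
    per_replicate: dict[str, list["object"]]
    cramers_v: dict[tuple[str, str], StatResult]
    paired_tests: dict[str, dict[str, StatResult]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def context_spectra(
    dyad_replicates: Sequence[Sequence[DyadRecord]],
    motifs: Sequence[MotifSite],
    bound_motifs: Sequence[MotifSite],
) -> ContextSpectra:
    """Dyad spectra for nested strata: genome ⊃ motif CpGs ⊃ bound-motif CpGs.

    Each replicate's dyads are restricted to each stratum; Cramér's V is
    computed between pooled stratum count tables, and per-class paired
    two-tailed t-tests compare stratum proportions across replicates (paired
    because bound-motif CpGs are a subset of motif CpGs, which are a subset of
    the genome).
    """
    from .duplex import DYAD_CLASSES, DyadSpectrum, classify_dyads

    strata_intervals = {
        "motif": [m.interval for m in motifs],
        "bound_motif": [m.interval for m in bound_motifs],
    }
    per_rep: dict[str, list[DyadSpectrum]] = {
        "genome": [], "motif": [], "bound_motif": []
    }
    warnings: list[str] = []
    for rep in dyad_replicates:
        rep = list(rep)
        per_rep["genome"].append(classify_dyads(rep)[0])
        for name, ivs in strata_intervals.items():
            per_rep[name].append(classify_dyads(_dyads_in_intervals(rep, ivs))[0])
    pooled = {
        name: DyadSpectrum(
            {c: sum(s.counts[c] for s in specs) for c in DYAD_CLASSES}
        )
        for name, specs in per_rep.items()
    }
    assoc: dict[tuple[str, str], StatResult] = {}
    for a, b in (("genome", "motif"), ("genome", "bound_motif"), ("motif", "bound_motif")):
        if pooled[a].total and pooled[b].total:
            table = np.vstack([pooled[a].as_array(), pooled[b].as_array()])
            try:
                assoc[(a, b)] = _stats.cramers_v(table)
            except ValueError:
                warnings.append(f"degenerate table for pair ({a}, {b}); V skipped")
        else:
            warnings.append(f"empty stratum in pair ({a}, {b}); V skipped")
    paired: dict[str, dict[str, StatResult]] = {}
    n_rep = len(dyad_replicates)
    if n_rep >= 2:
        for a, b in (("genome", "motif"), ("genome", "bound_motif"), ("motif", "bound_motif")):
            per_class: dict[str, StatResult] = {}
            for cls in DYAD_CLASSES:
                try:
                    pa = [s.proportions[cls] for s in per_rep[a]]
                    pb = [s.proportions[cls] for s in per_rep[b]]
                except ValueError:
                    continue
                diffs = np.array(pa) - np.array(pb)
                if np.allclose(diffs, diffs[0]):
                    # zero variance of differences: t undefined
                    continue
                t, p = sps.ttest_rel(pa, pb)
                per_class[cls] = StatResult("paired-t", float(t), float(p), n=n_rep)
            paired[f"{a}_vs_{b}"] = per_class
    else:
        warnings.append("fewer than 2 replicates; paired t-tests skipped")
    return ContextSpectra(pooled, per_rep, assoc, paired, warnings)


@dataclass
class DistanceProfile:
    """Dyad-class distances to the nearest ChIP summit with associated tests."""

    distances: dict[str, np.ndarray]
    kruskal: StatResult | None
    dunn: list[tuple[str, str, StatResult]]
    point_biserial: dict[str, StatResult]
    max_dist: int
    n_retained: int


def nearest_summit_distance(
    chrom: str, pos: int, summits_by_chrom: dict[str, np.ndarray]
) -> int | None:
    """Absolute distance to the nearest summit on the same chromosome.

    Equidistant summits resolve to the lower coordinate (same distance).
    """
    arr = summits_by_chrom.get(chrom)
    if arr is None or arr.size == 0:
        return None
    return int(np.min(np.abs(arr - pos)))


def distance_profile(
    dyads: Sequence[DyadRecord],
    summits: Iterable[tuple[str, int]],
    max_dist: int = 500,
) -> DistanceProfile:
    """Relate dyad modification class to absolute distance from ChIP summits.

    Dyads farther than ``max_dist`` from every summit are excluded.  Requires
    at least two dyad classes among the retained dyads for the omnibus test.
    """
    summits_by_chrom: dict[str, list[int]] = {}
    for c, s in summits:
        summits_by_chrom.setdefault(c, []).append(s)
    arr_by_chrom = {c: np.sort(np.array(v)) for c, v in summits_by_chrom.items()}
    dist_by_class: dict[str, list[int]] = {}
    flat_classes: list[str] = []
    flat_dists: list[int] = []
    for d in dyads:
        dist = nearest_summit_distance(d.chrom, d.cpg_pos, arr_by_chrom)
        if dist is None or dist > max_dist:
            continue
        cls = d.dyad_class
        dist_by_class.setdefault(cls, []).append(dist)
        flat_classes.append(cls)
        flat_dists.append(dist)
    groups = {k: np.array(v, dtype=float) for k, v in dist_by_class.items()}
    if len(groups) < 2:
        raise ValueError(
            "distance profile needs >= 2 dyad classes within max_dist "
            f"(found {len(groups)})"
        )
    h, p = sps.kruskal(*groups.values())
    kruskal = StatResult(
        "kruskal-wallis", float(h), float(p),
        df=len(groups) - 1, n=len(flat_dists),
    )
    dunn = _stats.dunn_posthoc(groups)
    dists = np.array(flat_dists, dtype=float)
    classes = np.array(flat_classes)
    pb = {
        cls: _stats.point_biserial((classes == cls).astype(float), dists)
        for cls in groups
    }
    return DistanceProfile(
        distances=groups, kruskal=kruskal, dunn=dunn,
        point_biserial=pb, max_dist=max_dist, n_retained=len(flat_dists),
    )


@dataclass
class PalindromeSummary:
    """Counts of palindromic motifs, bound motifs, and asymmetric methylation."""

    n_palindromic: int
    n_bound: int
    pct_bound: float
    n_bound_with_asymmetric_methylation: int
    pct_with_asymmetric_methylation: float
    motif_strand_c_fraction: float | None
    n_asymmetric_dyads_at_bound: int
    warnings: list[str] = field(default_factory=list)


def palindrome_orientation(
    motifs: Sequence[MotifSite],
    peaks: Sequence[NarrowPeak],
    dyads: Sequence[DyadRecord],
) -> PalindromeSummary:
    """Asymmetric-methylation orientation at bound palindromic motifs.

    A palindromic motif is *bound* if its interval overlaps any peak interval
    by at least 1 bp (peak-overlap predicate, distinct from the summit-
    containment predicate used for spectra).  A bound motif shows asymmetric
    methylation if at least one hemi-methylated (C:5mC) dyad lies inside it.
    Among those hemi-methylated dyads, the motif-strand-C fraction is the
    share whose unmodified C sits on the motif strand (top state for ``+``
    motifs, bottom state for ``-``).
    """
    palindromic = [m for m in motifs if m.is_palindromic]
    peak_ivs = [p.interval for p in peaks]
    bound = [
        m for m in palindromic
        if any(m.interval.overlap(iv) > 0 for iv in peak_ivs)
    ]
    warnings = []
    n_with_asym = 0
    strand_c = 0
    n_asym_dyads = 0
    for m in bound:
        hemi = [
            d for d in dyads
            if d.chrom == m.interval.chrom
            and m.interval.start <= d.cpg_pos < m.interval.end
            and d.dyad_class == "hemi_5mC"
        ]
        if hemi:
            n_with_asym += 1
        for d in hemi:
            n_asym_dyads += 1
            motif_strand_state = d.top_state if m.motif_strand == "+" else d.bottom_state
            if motif_strand_state == "C":
                strand_c += 1
    pct_bound = 100.0 * len(bound) / len(palindromic) if palindromic else float("nan")
    if not palindromic:
        warnings.append("no palindromic motifs supplied")
    pct_asym = 100.0 * n_with_asym / len(bound) if bound else float("nan")
    frac = strand_c / n_asym_dyads if n_asym_dyads else None
    if not bound:
        warnings.append("zero bound palindromic motifs; fractions undefined")
    return PalindromeSummary(
        n_palindromic=len(palindromic),
        n_bound=len(bound),
        pct_bound=pct_bound,
        n_bound_with_asymmetric_methylation=n_with_asym,
        pct_with_asymmetric_methylation=pct_asym,
        motif_strand_c_fraction=frac,
        n_asymmetric_dyads_at_bound=n_asym_dyads,
        warnings=warnings,
    )
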