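"""CpG-dyad symmetry classification from duplex reads.

A duplex read calls both strands of one molecule, so every covered CpG yields
an unordered pair of states from {C, 5mC, 5hmC} — six dyad classes:
three symmetric (C:C, 5mC:5mC, 5hmC:5hmC), two hemi-modified (C:5mC, C:5hmC)
and one hetero-modified (5mC:5hmC).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np

from .core import DYAD_CLASSES, DyadRecord, ReadCall, StatResult
from . import stats as _stats


@dataclass
class DyadSpectrum:
    """Counts and proportions over the six unordered dyad classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in DYAD_CLASSES}
    )

    def __post_init__(self) -> None:
        for c in DYAD_CLASSES:
            self.counts.setdefault(c, 0)
        unknown = set(self.counts) - set(DYAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown dyad classes: {unknown}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative dyad count")

    @classmethod
    def from_proportions(
        cls, proportions: dict[str, float], total: int = 1_000_000
    ) -> "DyadSpectrum":
        """Build a spectrum with counts proportional to given class fractions."""
        if abs(sum(proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        return cls({c: round(total * proportions.get(c, 0.0)) for c in DYAD_CLASSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            raise ValueError("empty spectrum has no proportions")
        return {c: self.counts[c] / t for c in DYAD_CLASSES}

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in DYAD_CLASSES], dtype=float)


def dyads_from_read_calls(calls: Iterable[ReadCall]) -> list[DyadRecord]:
    """Extract DyadRecords from the duplex rows of a read-call stream."""
    return [
        DyadRecord(
            chrom=c.chrom, cpg_pos=c.cpg_pos,
            top_state=c.call_state, bottom_state=c.partner_state,
            read_id=c.read_id,
        )
        for c in calls
        if c.is_duplex
    ]


def classify_dyads(
    records: Iterable[DyadRecord],
) -> tuple[DyadSpectrum, dict[str, set[str]]]:
    """Classify duplex dyad records into the six unordered classes.

    Returns the spectrum plus a per-read class-presence table (read_id -> set
    of classes occurring at least once on that read), the input for
    UpSet-style summaries.
    """
    counts: Counter[str] = Counter()
    per_read: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        cls = rec.dyad_class
        counts[cls] += 1
        per_read[rec.read_id].add(cls)
    return DyadSpectrum({c: counts.get(c, 0) for c in DYAD_CLASSES}), dict(per_read)


def asymmetric_fraction(spectrum: DyadSpectrum) -> float:
    """Percent of dyads that are not symmetric (hemi-modified or hetero)."""
    t = spectrum.total
    if t == 0:
        raise ValueError("empty spectrum")
    asym = (
        spectrum.counts["hemi_5mC"]
        + spectrum.counts["hemi_5hmC"]
        + spectrum.counts["hetero"]
    )
    return 100.0 * asym / t


def hmc_partner_fraction(spectrum: DyadSpectrum) -> float:
    """Percent of 5hmC-containing dyads whose partner strand carries 5mC.

    5hmC-containing dyads are hemi_5hmC (partner C), hetero (partner 5mC) and
    sym_5hmC (partner 5hmC); the numerator is the hetero class.
    """
    denom = (
        spectrum.counts["hemi_5hmC"]
        + spectrum.counts["hetero"]
        + spectrum.counts["sym_5hmC"]
    )
    if denom == 0:
        raise ValueError("no 5hmC-containing dyads")
    return 100.0 * spectrum.counts["hetero"] / denom


def spectrum_gtest(observed: DyadSpectrum, expected: DyadSpectrum) -> StatResult:
    """G-test of an observed spectrum against expected class proportions."""
    exp_props = expected.as_array()
    exp_total = exp_props.sum()
    if exp_total == 0:
        raise ValueError("empty expected spectrum")
    return _stats.g_test(observed.as_array(), exp_props / exp_total)


def spectrum_association(a: DyadSpectrum, b: DyadSpectrum) -> StatResult:
    """Cramér's V between two spectra (2 x 6 contingency of counts)."""
    table = np.vstack([a.as_array(), b.as_array()])
    return _stats.cramers_v(table)
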