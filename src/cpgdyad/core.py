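"""Core domain types shared by every analysis stage.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open ``[start, end)``.  A CpG site is keyed
by the position of its forward-strand C; the reverse-strand C of the same dyad
sits at ``pos + 1``.  Per-strand pileup records therefore appear at ``pos``
(``+``) and ``pos + 1`` (``-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The three cytosine states the base-caller distinguishes in CpG context.
STATES = ("C", "5mC", "5hmC")

#: Single-letter codes used by the on-disk read-call dialect.
STATE_CODES = {"c": "C", "m": "5mC", "h": "5hmC"}
CODE_OF_STATE = {v: k for k, v in STATE_CODES.items()}

#: The six unordered CpG-dyad modification classes.
DYAD_CLASSES = ("sym_C", "sym_5mC", "sym_5hmC", "hemi_5mC", "hemi_5hmC", "hetero")

#: Unordered pair -> dyad class.
_DYAD_OF_PAIR = {
    frozenset(["C"]): "sym_C",
    frozenset(["5mC"]): "sym_5mC",
    frozenset(["5hmC"]): "sym_5hmC",
    frozenset(["C", "5mC"]): "hemi_5mC",
    frozenset(["C", "5hmC"]): "hemi_5hmC",
    frozenset(["5mC", "5hmC"]): "hetero",
}


def dyad_class(state_a: str, state_b: str) -> str:
    """Unordered dyad class of a pair of strand states.

    ``dyad_class(x, y) == dyad_class(y, x)`` for all states.
    """
    try:
        return _DYAD_OF_PAIR[frozenset([state_a, state_b])]
    except KeyError:
        raise ValueError(f"unknown dyad states: {state_a!r}, {state_b!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    feature_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Base pairs shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class NarrowPeak:
    """ENCODE narrowPeak record: an interval plus point-source metadata."""

    interval: GenomicInterval
    summit_offset: int
    fold_enrichment: float = 0.0
    neg_log10_q: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be nonnegative")

    @property
    def summit(self) -> int:
        """Absolute summit coordinate."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class ReadCall:
    """One modification call of a CpG-context cytosine on one read.

    ``cpg_pos`` is always the forward-strand C position of the dyad.  For
    simplex records ``strand`` names the strand that was actually called and
    ``partner_state`` is ``None``.  For duplex records ``call_state`` is the
    forward-strand call and ``partner_state`` the reverse-strand call.
    """

    read_id: str
    chrom: str
    cpg_pos: int
    strand: str
    call_state: str
    is_duplex: bool = False
    partner_state: str | None = None

    def __post_init__(self) -> None:
        if self.call_state not in STATES:
            raise ValueError(f"unknown call state {self.call_state!r}")
        if self.is_duplex:
            if self.partner_state not in STATES:
                raise ValueError("duplex record requires a partner state")
        elif self.partner_state is not None:
            raise ValueError("simplex record cannot carry a partner state")


@dataclass
class SiteCounts:
    """Per-CpG-site per-strand pileup counts.

    Percentages are always derived from the counts (the modification level of
    a site is the fraction of reads carrying that state, times 100).
    """

    chrom: str
    cpg_pos: int
    strand: str
    n_C: int
    n_5mC: int
    n_5hmC: int

    def __post_init__(self) -> None:
        if min(self.n_C, self.n_5mC, self.n_5hmC) < 0:
            raise ValueError("negative count in pileup record")

    @property
    def depth(self) -> int:
        return self.n_C + self.n_5mC + self.n_5hmC

    @property
    def pct_5mC(self) -> float:
        d = self.depth
        return 100.0 * self.n_5mC / d if d else 0.0

    @property
    def pct_5hmC(self) -> float:
        d = self.depth
        return 100.0 * self.n_5hmC / d if d else 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.cpg_pos, self.strand)


@dataclass(frozen=True)
class DyadRecord:
    """A fully called CpG dyad from one duplex read (both strands present)."""

    chrom: str
    cpg_pos: int
    top_state: str
    bottom_state: str
    read_id: str = "."

    def __post_init__(self) -> None:
        for s in (self.top_state, self.bottom_state):
            if s not in STATES:
                raise ValueError(f"unknown dyad state {s!r}")

    @property
    def dyad_class(self) -> str:
        return dyad_class(self.top_state, self.bottom_state)


@dataclass
class StatResult:
    """A named test statistic with its p-value and optional effect size."""

    test_name: str
    statistic: float
    pvalue: float
    df: float | None = None
    effect: float | None = None
    effect_name: str | None = None
    n: int | None = None
    note: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pvalue == self.pvalue and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")
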