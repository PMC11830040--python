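"""Readers and writers for the plain-text formats the pipeline consumes.

Dialects
--------
bedMethyl (tab-separated, one line per site/strand/modification):
    ``chrom  start  end  mod_code  depth  strand  n_mod  n_canonical  n_other_mod``
    with ``mod_code`` in ``{m, h}``.  The two lines of one (site, strand) agree
    on depth; percentages are never read from disk, only recomputed.

read-call (tab-separated):
    ``read_id  chrom  cpg_pos  strand  call_state  is_duplex  partner_state``
    with states coded ``c/m/h`` and ``partner_state = .`` for simplex rows.

BED3/6 and ENCODE narrowPeak (10 columns) follow their usual definitions;
all intervals are 0-based half-open.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator

from pyfaidx import Fasta

from .core import (
    CODE_OF_STATE,
    STATE_CODES,
    GenomicInterval,
    NarrowPeak,
    ReadCall,
    SiteCounts,
)


class ParseError(ValueError):
    """Malformed line in an input table; carries the 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# bedMethyl pileups
# ---------------------------------------------------------------------------

def read_pileup(path: str | os.PathLike, min_depth: int = 0) -> list[SiteCounts]:
    """Read a bedMethyl-dialect pileup, keeping sites with depth >= min_depth.

    The ``m`` and ``h`` lines of one (site, strand) are merged into a single
    :class:`SiteCounts`; depth is re-derived from the three counts.
    """
    path = os.fspath(path)
    sites: dict[tuple[str, int, str], SiteCounts] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, start_s, end_s, mod_code, depth_s, strand, n_mod_s, n_can_s, n_other_s = fields
            try:
                start, end = int(start_s), int(end_s)
                depth, n_mod, n_can, n_other = (
                    int(depth_s), int(n_mod_s), int(n_can_s), int(n_other_s)
                )
            except ValueError:
                raise ParseError(path, lineno, "non-integer numeric field") from None
            if mod_code not in ("m", "h"):
                raise ParseError(path, lineno, f"unknown mod code {mod_code!r}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
            if end != start + 1:
                raise ParseError(path, lineno, "pileup record must span one base")
            if min(n_mod, n_can, n_other) < 0:
                raise ParseError(path, lineno, "negative count")
            if depth != n_mod + n_can + n_other:
                raise ParseError(path, lineno, "depth does not equal sum of counts")
            if mod_code == "m":
                n_5mC, n_5hmC = n_mod, n_other
            else:
                n_5hmC, n_5mC = n_mod, n_other
            key = (chrom, start, strand)
            rec = SiteCounts(chrom, start, strand, n_can, n_5mC, n_5hmC)
            prev = sites.get(key)
            if prev is not None and (prev.n_C, prev.n_5mC, prev.n_5hmC) != (
                rec.n_C, rec.n_5mC, rec.n_5hmC
            ):
                raise ParseError(path, lineno, f"inconsistent counts for site {key}")
            sites[key] = rec
    return [s for s in sorted(sites.values(), key=lambda s: s.key) if s.depth >= min_depth]


def write_pileup(
    sites: Iterable[SiteCounts], path: str | os.PathLike, sort: bool = False
) -> None:
    """Write SiteCounts as bedMethyl dialect (two lines per site: m then h).

    Input must be sorted by (chrom, cpg_pos, strand) unless ``sort=True``.
    """
    records = list(sites)
    keys = [s.key for s in records]
    if sort:
        records.sort(key=lambda s: s.key)
    elif keys != sorted(keys):
        raise ValueError("pileup records are not sorted; pass sort=True to sort")
    with open(path, "w") as fh:
        for s in records:
            base = f"{s.chrom}\t{s.cpg_pos}\t{s.cpg_pos + 1}"
            fh.write(f"{base}\tm\t{s.depth}\t{s.strand}\t{s.n_5mC}\t{s.n_C}\t{s.n_5hmC}\n")
            fh.write(f"{base}\th\t{s.depth}\t{s.strand}\t{s.n_5hmC}\t{s.n_C}\t{s.n_5mC}\n")


# ---------------------------------------------------------------------------
# read-level calls
# ---------------------------------------------------------------------------

def read_read_calls(path: str | os.PathLike) -> Iterator[ReadCall]:
    """Stream ReadCall records from a read-call dialect table.

    Rejects unknown state codes and duplicate (read_id, chrom, cpg_pos) rows.
    """
    path = os.fspath(path)
    seen: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(path, lineno, f"expected 7 columns, got {len(fields)}")
            read_id, chrom, pos_s, strand, state_c, dup_s, partner_c = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer position") from None
            if state_c not in STATE_CODES:
                raise ParseError(path, lineno, f"unknown state code {state_c!r}")
            if dup_s not in ("0", "1"):
                raise ParseError(path, lineno, f"invalid duplex flag {dup_s!r}")
            is_duplex = dup_s == "1"
            if is_duplex:
                if partner_c not in STATE_CODES:
                    raise ParseError(path, lineno, f"unknown partner code {partner_c!r}")
                partner = STATE_CODES[partner_c]
            else:
                if partner_c != ".":
                    raise ParseError(path, lineno, "simplex row must have partner '.'")
                partner = None
            key = (read_id, chrom, pos)
            if key in seen:
                raise ParseError(path, lineno, f"duplicate call {key}")
            seen.add(key)
            yield ReadCall(
                read_id=read_id,
                chrom=chrom,
                cpg_pos=pos,
                strand=strand,
                call_state=STATE_CODES[state_c],
                is_duplex=is_duplex,
                partner_state=partner,
            )


def write_read_calls(calls: Iterable[ReadCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in calls:
            partner = CODE_OF_STATE[c.partner_state] if c.is_duplex else "."
            fh.write(
                f"{c.read_id}\t{c.chrom}\t{c.cpg_pos}\t{c.strand}\t"
                f"{CODE_OF_STATE[c.call_state]}\t{int(c.is_duplex)}\t{partner}\n"
            )


# ---------------------------------------------------------------------------
# intervals and peaks
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | os.PathLike, kind: str = "bed"
) -> list[GenomicInterval] | list[NarrowPeak]:
    """Read BED3/BED6 (`kind="bed"`) or 10-column narrowPeak (`kind="narrowpeak"`)."""
    path = os.fspath(path)
    if kind not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown interval kind {kind!r}")
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if kind == "bed":
                    if len(f) < 3:
                        raise ParseError(path, lineno, "BED needs >= 3 columns")
                    iv = GenomicInterval(
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        name=f[3] if len(f) > 3 else ".",
                        strand=f[5] if len(f) > 5 else ".",
                    )
                    out.append(iv)
                else:
                    if len(f) != 10:
                        raise ParseError(
                            path, lineno, f"narrowPeak needs 10 columns, got {len(f)}"
                        )
                    iv = GenomicInterval(
                        chrom=f[0], start=int(f[1]), end=int(f[2]),
                        name=f[3], strand=f[5],
                    )
                    out.append(
                        NarrowPeak(
                            interval=iv,
                            summit_offset=int(f[9]),
                            fold_enrichment=float(f[6]),
                            neg_log10_q=float(f[8]),
                        )
                    )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED6 (name column carries feature_class if set)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.feature_class if iv.feature_class is not None else iv.name
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_narrowpeaks(peaks: Iterable[NarrowPeak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t.\t"
                f"{p.fold_enrichment:g}\t-1\t{p.neg_log10_q:g}\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content_windows(
    reference: str | os.PathLike, window_bp: int
) -> tuple[list[tuple[GenomicInterval, float]], float]:
    """Tile each reference sequence into fixed windows and compute GC per tile.

    GC fraction is (#G + #C) / (#non-N bases), case-insensitive; windows that
    are entirely N are omitted.  Also returns the genome mean GC, defined as
    the total G+C count divided by the total non-N length across sequences.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    fa = Fasta(os.fspath(reference), as_raw=True, read_ahead=10_000_000)
    tiles: list[tuple[GenomicInterval, float]] = []
    total_gc = 0
    total_non_n = 0
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        if not seq:
            continue
        for start in range(0, len(seq), window_bp):
            chunk = seq[start : start + window_bp]
            non_n = len(chunk) - chunk.count("N")
            gc = chunk.count("G") + chunk.count("C")
            total_gc += gc
            total_non_n += non_n
            if non_n == 0:
                continue
            iv = GenomicInterval(name, start, start + len(chunk))
            tiles.append((iv, gc / non_n))
    if total_non_n == 0:
        raise ValueError("reference contains no non-N bases")
    return tiles, total_gc / total_non_n


def softmask_intervals(reference: str | os.PathLike) -> list[GenomicInterval]:
    """Extract lowercase (soft-masked) runs of a FASTA as intervals."""
    fa = Fasta(os.fspath(reference), as_raw=True, read_ahead=10_000_000)
    out: list[GenomicInterval] = []
    for name in fa.keys():
        seq = str(fa[name][:])
        start = None
        for i, base in enumerate(seq):
            if base.islower():
                if start is None:
                    start = i
            elif start is not None:
                out.append(GenomicInterval(name, start, i, feature_class="mask"))
                start = None
        if start is not None:
            out.append(GenomicInterval(name, start, len(seq), feature_class="mask"))
    return out
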