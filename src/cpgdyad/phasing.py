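"""SNP-free allele phasing of reads over an imprinted DMR.

At a germline differentially methylated region the two parental alleles carry
near-opposite methylation states, so reads can be separated without any
sequence variant: encode each read as a string of per-CpG modification states
(absent positions included as a fourth symbol), build the pairwise Hamming
distance matrix, cluster agglomeratively with average (mean-distance)
linkage, cut the dendrogram into two clusters, and label the cluster with the
higher mean 5mC fraction as the methylated allele.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import GenomicInterval, ReadCall

#: Integer codes for the encoded read matrix.
CODE_C, CODE_5MC, CODE_5HMC, CODE_ABSENT = 0, 1, 2, 3
_STATE_CODE = {"C": CODE_C, "5mC": CODE_5MC, "5hmC": CODE_5HMC}


@dataclass
class EncodedReadMatrix:
    """Reads x DMR-CpG matrix of nominal modification-state codes."""

    read_ids: list[str]
    positions: list[int]
    codes: np.ndarray  # shape (n_reads, n_positions), dtype int8
    absent_fraction: np.ndarray
    excluded_reads: list[str]
    chrom: str

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def mean_5mc_fraction(self, rows: np.ndarray) -> float:
        """Fraction of non-absent codes equal to 5mC over the given reads."""
        sub = self.codes[rows]
        present = sub != CODE_ABSENT
        n_present = present.sum()
        if n_present == 0:
            return 0.0
        return float((sub == CODE_5MC).sum() / n_present)


def encode_dmr_reads(
    calls: Iterable[ReadCall],
    dmr: GenomicInterval,
    max_absent_fraction: float = 0.5,
) -> EncodedReadMatrix:
    """Encode the reads covering a DMR as modification-state strings.

    DMR CpG positions are the union of CpG sites covered by any read within
    the DMR, ordered; a read's code at an uncovered position is ABSENT.  Reads
    whose absent fraction exceeds ``max_absent_fraction`` are excluded (and
    listed).  Duplex records are encoded by their forward-strand call.
    """
    per_read: dict[str, dict[int, int]] = defaultdict(dict)
    positions: set[int] = set()
    for c in calls:
        if c.chrom != dmr.chrom or not (dmr.start <= c.cpg_pos < dmr.end):
            continue
        positions.add(c.cpg_pos)
        per_read[c.read_id][c.cpg_pos] = _STATE_CODE[c.call_state]
    ordered = sorted(positions)
    if len(ordered) < 2:
        raise ValueError(f"DMR {dmr.chrom}:{dmr.start}-{dmr.end} covers < 2 CpG sites")
    pos_index = {p: i for i, p in enumerate(ordered)}
    read_ids, rows, fracs, excluded = [], [], [], []
    for read_id in sorted(per_read):
        row = np.full(len(ordered), CODE_ABSENT, dtype=np.int8)
        for p, code in per_read[read_id].items():
            row[pos_index[p]] = code
        absent = float((row == CODE_ABSENT).sum() / len(ordered))
        if absent > max_absent_fraction:
            excluded.append(read_id)
            continue
        read_ids.append(read_id)
        rows.append(row)
        fracs.append(absent)
    if len(read_ids) < 2:
        raise ValueError("fewer than 2 reads retained after absent-fraction filter")
    return EncodedReadMatrix(
        read_ids=read_ids,
        positions=ordered,
        codes=np.vstack(rows),
        absent_fraction=np.array(fracs),
        excluded_reads=excluded,
        chrom=dmr.chrom,
    )


def hamming_matrix(matrix: EncodedReadMatrix, masked: bool = False) -> np.ndarray:
    """Pairwise Hamming distances between encoded reads.

    By default ABSENT is a literal fourth symbol, so an absent position
    mismatches any called state (the nominal-encoding convention).  With
    ``masked=True`` positions absent in either read are ignored and the
    mismatch count is rescaled to the full position count (comparable scale;
    pairs with no co-covered position get the maximum distance).
    """
    codes = matrix.codes
    n, m = codes.shape
    if not masked:
        # mismatch count = m * normalized hamming
        diff = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
        return diff.astype(float)
    present = codes != CODE_ABSENT
    both = present[:, None, :] & present[None, :, :]
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    n_both = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_both > 0, diff.sum(axis=2) / np.maximum(n_both, 1), 1.0)
    out = frac * m
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class PhasingResult:
    """Two-cluster partition of DMR reads with allele labels."""

    methylated_reads: list[str]
    unmethylated_reads: list[str]
    mean_5mc_methylated: float
    mean_5mc_unmethylated: float
    excluded_reads: list[str]
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def allele_ratio(self) -> float:
        """Methylated reads over all retained reads."""
        total = len(self.methylated_reads) + len(self.unmethylated_reads)
        return len(self.methylated_reads) / total if total else float("nan")

    def allele_of(self) -> dict[str, str]:
        out = {r: "methylated" for r in self.methylated_reads}
        out.update({r: "unmethylated" for r in self.unmethylated_reads})
        return out


def phase_alleles(
    distances: np.ndarray, matrix: EncodedReadMatrix
) -> PhasingResult:
    """Split reads into two allele clusters by average-linkage clustering.

    The dendrogram built from mean distances between reads (then between
    successive clusters) is cut into exactly two clusters; the cluster with
    the higher mean 5mC code fraction is labelled methylated.  The result is
    invariant to read input order.  If every pairwise distance is zero the
    reads cannot be split and a degenerate single-cluster result is returned.
    """
    n = matrix.n_reads
    if distances.shape != (n, n):
        raise ValueError("distance matrix does not match read matrix")
    warnings: list[str] = []
    if np.all(distances == 0):
        return PhasingResult(
            methylated_reads=list(matrix.read_ids),
            unmethylated_reads=[],
            mean_5mc_methylated=matrix.mean_5mc_fraction(np.arange(n)),
            mean_5mc_unmethylated=float("nan"),
            excluded_reads=matrix.excluded_reads,
            degenerate=True,
            warnings=["all pairwise distances zero; single-cluster result"],
        )
    # canonical read order to make the partition independent of input order
    order = np.argsort(np.array(matrix.read_ids))
    dist_sorted = distances[np.ix_(order, order)]
    condensed = squareform(dist_sorted, checks=False)
    tree = linkage(condensed, method="average")
    labels_sorted = fcluster(tree, t=2, criterion="maxclust")
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    rows1 = np.flatnonzero(labels == 1)
    rows2 = np.flatnonzero(labels == 2)
    if len(rows2) == 0:
        warnings.append("maxclust cut produced a single cluster")
        rows2 = np.array([], dtype=int)
    m1 = matrix.mean_5mc_fraction(rows1)
    m2 = matrix.mean_5mc_fraction(rows2) if len(rows2) else float("nan")
    if len(rows2) == 0 or m1 > m2 or (m1 == m2 and len(rows1) >= len(rows2)):
        meth_rows, unmeth_rows = rows1, rows2
        m_meth, m_unmeth = m1, m2
        if len(rows2) and m1 == m2:
            warnings.append("tied mean 5mC; larger cluster labelled methylated")
    else:
        meth_rows, unmeth_rows = rows2, rows1
        m_meth, m_unmeth = m2, m1
    ids = np.array(matrix.read_ids)
    return PhasingResult(
        methylated_reads=sorted(ids[meth_rows]),
        unmethylated_reads=sorted(ids[unmeth_rows]),
        mean_5mc_methylated=m_meth,
        mean_5mc_unmethylated=m_unmeth,
        excluded_reads=matrix.excluded_reads,
        degenerate=len(unmeth_rows) == 0,
        warnings=warnings,
    )


def phase_dmr(
    calls: Iterable[ReadCall],
    dmr: GenomicInterval,
    max_absent_fraction: float = 0.5,
    masked_hamming: bool = False,
) -> PhasingResult:
    """Convenience pipeline: encode, Hamming distances, two-allele phasing."""
    matrix = encode_dmr_reads(calls, dmr, max_absent_fraction)
    dist = hamming_matrix(matrix, masked=masked_hamming)
    return phase_alleles(dist, matrix)


def allele_spectra(
    result: PhasingResult,
    dyads: Iterable,
    genome_spectrum=None,
):
    """Per-allele dyad spectra, with G-tests against a genome-wide spectrum.

    ``dyads`` are DyadRecords whose read_ids intersect the phased reads.
    Returns {allele: (DyadSpectrum, StatResult or None)}; an allele with zero
    dyads is omitted (with a warning in the result's warnings list).
    """
    from .duplex import classify_dyads, spectrum_gtest

    allele_of = result.allele_of()
    by_allele: dict[str, list] = {"methylated": [], "unmethylated": []}
    for d in dyads:
        allele = allele_of.get(d.read_id)
        if allele is not None:
            by_allele[allele].append(d)
    out = {}
    for allele, recs in by_allele.items():
        if not recs:
            result.warnings.append(f"no dyads for {allele} allele; spectrum omitted")
            continue
        spectrum, _ = classify_dyads(recs)
        test = (
            spectrum_gtest(spectrum, genome_spectrum)
            if genome_spectrum is not None
            else None
        )
        out[allele] = (spectrum, test)
    return out
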