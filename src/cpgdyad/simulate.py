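"""Ground-truthed synthetic data: genomes, methylomes, read calls, annotations.

The generator emulates the downstream products of a nanopore 5mC/5hmC
sequencing study on a mammalian genome: per-CpG modification calls with a
bimodal 5mC landscape and rare 5hmC, duplex dyad records drawn from a
configurable six-class dyad table, methylation standards passed through a
base-caller confusion matrix, imprinted two-allele DMRs, and annotation sets
(features, CpG islands with shores and shelves, CTCF-like motifs, peaks).

Default parameters are the observed operating point of the modified-base
caller on whole-genomic methylation standards and of duplex capture on
high-duplex flow cells: TPR(5mC) = 0.97, P(5mC|C) = 0.0056, P(5hmC|C) =
0.0024, P(5hmC|5mC) = 0.011, duplex rate 0.32, and genome-wide dyad class
proportions (sym_5mC 52.5%, sym_C 23.5%, hemi_5mC 6.3%, hemi_5hmC 2.0%,
hetero 12.8%, sym_5hmC 2.9% as the remainder).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .core import DYAD_CLASSES, STATES, GenomicInterval, NarrowPeak, ReadCall
from .regulatory import MotifSite

# ---------------------------------------------------------------------------
# default generative parameters
# ---------------------------------------------------------------------------

#: Genome-wide unordered dyad class proportions (sym_5hmC is the remainder).
DEFAULT_DYAD_TABLE: dict[str, float] = {
    "sym_C": 0.235,
    "sym_5mC": 0.525,
    "sym_5hmC": 0.029,
    "hemi_5mC": 0.063,
    "hemi_5hmC": 0.020,
    "hetero": 0.128,
}

#: Fraction of sequenced templates recovered as duplex (both-strand) reads.
DEFAULT_DUPLEX_RATE = 0.32

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass
class ConfusionParams:
    """Base-caller call probabilities P(observed | true) as a 3x3 row-stochastic
    matrix over (C, 5mC, 5hmC), with an optional monotone GC modifier that
    scales the false-positive (off-diagonal from true C) probabilities.
    """

    matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # observed:  C       5mC     5hmC
                [1.0 - 0.0056 - 0.0024, 0.0056, 0.0024],  # true C
                [0.019, 0.970, 0.011],                     # true 5mC
                [0.020, 0.030, 0.950],                     # true 5hmC (assumed)
            ]
        )
    )
    gc_modifier: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("confusion entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")
        self.matrix = m

    @classmethod
    def identity(cls) -> "ConfusionParams":
        return cls(matrix=np.eye(3))

    def row(self, true_state: str, gc: float | None = None) -> np.ndarray:
        """Call distribution for one true state, GC-adjusted if configured."""
        probs = self.matrix[_STATE_INDEX[true_state]].copy()
        if self.gc_modifier is not None and gc is not None and true_state == "C":
            scale = float(self.gc_modifier(gc))
            if scale < 0:
                raise ValueError("gc modifier must be nonnegative")
            probs[1] *= scale
            probs[2] *= scale
            if probs[1] + probs[2] >= 1.0:
                raise ValueError("GC-scaled false-positive probability >= 1")
            probs[0] = 1.0 - probs[1] - probs[2]
        return probs


@dataclass
class DepthModel:
    """Per-site sequencing depth: Poisson with a log-linear GC adjustment.

    ``lambda(site) = mean_depth * exp(gc_coefficient * (gc - 0.5))``; negative
    coefficients depress coverage at high GC, reproducing the depth-GC
    anticorrelation seen in nanopore WGS data.
    """

    mean_depth: float = 10.0
    gc_coefficient: float = 0.0
    duplex_rate: float = DEFAULT_DUPLEX_RATE

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.duplex_rate <= 1.0):
            raise ValueError("duplex_rate must lie in [0, 1]")

    def rate(self, gc: float | None) -> float:
        if gc is None:
            return self.mean_depth
        return self.mean_depth * math.exp(self.gc_coefficient * (gc - 0.5))


@dataclass
class MethylomeTruth:
    """Per-site generative truth plus the confusion parameters used to emit calls.

    ``mode`` is one of ``dyad_table`` (each site carries one of the six dyad
    classes, orientation of asymmetric classes fixed per site), ``beta_mixture``
    (each strand of each template is modified independently with the site's
    mixture-drawn 5mC probability), or ``dmr`` (two alleles with distinct
    per-site modification probabilities; templates are labelled by allele).
    """

    sites: list[tuple[str, int]]
    mode: str
    confusion: ConfusionParams
    # dyad_table mode: ordered per-site strand states
    site_top: list[str] | None = None
    site_bottom: list[str] | None = None
    # beta_mixture mode: per-site per-strand modification probabilities
    site_p_5mC: np.ndarray | None = None
    site_p_5hmC: np.ndarray | None = None
    # dmr mode
    allele_p_5mC: tuple[float, float] | None = None
    allele_ratio: float | None = None

    def template_states(self, i: int, rng: np.random.Generator) -> tuple[str, str]:
        """Draw the true (top, bottom) strand states of one template at site i."""
        if self.mode == "dyad_table":
            return self.site_top[i], self.site_bottom[i]
        if self.mode == "beta_mixture":
            pm = float(self.site_p_5mC[i])
            ph = float(self.site_p_5hmC[i]) if self.site_p_5hmC is not None else 0.0
            out = []
            for _ in range(2):
                u = rng.random()
                if u < ph:
                    out.append("5hmC")
                elif u < ph + pm:
                    out.append("5mC")
                else:
                    out.append("C")
            return out[0], out[1]
        raise ValueError(f"template_states undefined for mode {self.mode!r}")


def _ordered_pair_of_class(cls: str, flip: bool) -> tuple[str, str]:
    pairs = {
        "sym_C": ("C", "C"),
        "sym_5mC": ("5mC", "5mC"),
        "sym_5hmC": ("5hmC", "5hmC"),
        "hemi_5mC": ("5mC", "C"),
        "hemi_5hmC": ("5hmC", "C"),
        "hetero": ("5mC", "5hmC"),
    }
    top, bottom = pairs[cls]
    return (bottom, top) if flip else (top, bottom)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def make_genome(
    n_chroms: int = 1,
    length_bp: int = 100_000,
    gc_profile: float | Callable[[float], float] = 0.41,
    cpg_density: float = 0.01,
    seed: int = 0,
    mask_fraction: float = 0.0,
    high_gc_segments: int = 0,
    high_gc_length: int = 1_000,
    high_gc_level: float = 0.65,
) -> tuple[dict[str, str], dict[str, np.ndarray], list[GenomicInterval]]:
    """Build random chromosome sequences with planted CpG dinucleotides.

    ``gc_profile`` is the target overall GC fraction (constant, or a callable
    of the fractional chromosome position evaluated per kilobase block); the
    background base composition is compensated so that planted CpGs do not
    inflate GC beyond the target.  ``cpg_density`` is CpGs per base pair.
    Optional ``high_gc_segments`` plants GC-rich runs (CpG-island-like) whose
    coordinates are returned; ``mask_fraction`` lowercases random segments to
    emulate repeat soft-masking.

    Returns (sequences, CpG forward-C positions per chromosome, high-GC
    segment intervals).  Deterministic for a fixed seed.
    """
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    if not (0.0 < cpg_density <= 0.1):
        raise ValueError("cpg_density must lie in (0, 0.1]")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    cpgs: dict[str, np.ndarray] = {}
    segments: list[GenomicInterval] = []
    block = 1000
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        bases = np.empty(length_bp, dtype="U1")
        for start in range(0, length_bp, block):
            stop = min(start + block, length_bp)
            gc = gc_profile(start / length_bp) if callable(gc_profile) else gc_profile
            # planted CpGs contribute pure GC over a 2*density fraction of bases
            g_bg = (gc - 2 * cpg_density) / (1 - 2 * cpg_density)
            if not (0.0 <= g_bg < 1.0):
                raise ValueError(
                    f"cpg_density {cpg_density} incompatible with GC target {gc}"
                )
            p = [(1 - g_bg) / 2, g_bg / 2, g_bg / 2, (1 - g_bg) / 2]
            bases[start:stop] = rng.choice(
                np.array(["A", "C", "G", "T"]), size=stop - start, p=p
            )
        # CpG-island-like high-GC runs
        for _ in range(high_gc_segments):
            s = int(rng.integers(8_000, max(8_001, length_bp - high_gc_length - 8_000)))
            seg = GenomicInterval(chrom, s, s + high_gc_length, feature_class="high_gc")
            segments.append(seg)
            g = high_gc_level
            p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
            bases[s : s + high_gc_length] = rng.choice(
                np.array(["A", "C", "G", "T"]), size=high_gc_length, p=p
            )
        # plant CpGs on even offsets so dinucleotides never overlap
        candidates = np.arange(0, length_bp - 1, 2)
        n_cpg = int(round(cpg_density * length_bp))
        pos = np.sort(rng.choice(candidates, size=n_cpg, replace=False))
        bases[pos] = "C"
        bases[pos + 1] = "G"
        seq = "".join(bases)
        if mask_fraction > 0:
            seq = _apply_softmask(seq, mask_fraction, rng)
        sequences[chrom] = seq
        cpgs[chrom] = pos
    return sequences, cpgs, segments


def _apply_softmask(seq: str, fraction: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq), dtype="U1")
    n_masked = 0
    target = fraction * len(seq)
    while n_masked < target:
        width = int(rng.integers(200, 1000))
        start = int(rng.integers(0, max(1, len(seq) - width)))
        run = arr[start : start + width]
        arr[start : start + width] = np.char.lower(run)
        n_masked += width
    return "".join(arr)


# ---------------------------------------------------------------------------
# methylome truth
# ---------------------------------------------------------------------------

def simulate_truth(
    cpgs: dict[str, np.ndarray] | Sequence[tuple[str, int]],
    mode: str = "dyad_table",
    params: dict | None = None,
    seed: int = 0,
    confusion: ConfusionParams | None = None,
) -> MethylomeTruth:
    """Draw per-site generative truth for the given CpG sites.

    Modes:

    - ``dyad_table`` — each site gets one of the six dyad classes, sampled from
      ``params["table"]`` (default: the genome-wide proportions above).
    - ``beta_mixture`` — each site gets a 5mC probability drawn from a two-
      component Beta mixture (``weights``, ``alpha``, ``beta``; defaults give
      the bimodal fully-methylated / fully-unmethylated landscape) plus a flat
      per-strand 5hmC probability ``hmc_rate``.
    - ``dmr`` — two alleles with per-site 5mC probabilities
      ``p_5mC_methylated`` / ``p_5mC_unmethylated`` and template-level
      ``allele_ratio``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if isinstance(cpgs, dict):
        sites = [(c, int(p)) for c in sorted(cpgs) for p in cpgs[c]]
    else:
        sites = [(c, int(p)) for c, p in cpgs]
    confusion = confusion or ConfusionParams()
    n = len(sites)
    if mode == "dyad_table":
        table = dict(params.get("table", DEFAULT_DYAD_TABLE))
        probs = np.array([table.get(c, 0.0) for c in DYAD_CLASSES], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("dyad class probabilities must sum to 1")
        classes = rng.choice(len(DYAD_CLASSES), size=n, p=probs)
        flips = rng.random(n) < 0.5
        top, bottom = [], []
        for k, flip in zip(classes, flips):
            t, b = _ordered_pair_of_class(DYAD_CLASSES[k], bool(flip))
            top.append(t)
            bottom.append(b)
        return MethylomeTruth(sites, mode, confusion, site_top=top, site_bottom=bottom)
    if mode == "beta_mixture":
        weights = np.asarray(params.get("weights", (0.38, 0.62)), dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        alpha = params.get("alpha", (0.5, 10.0))
        beta = params.get("beta", (10.0, 0.5))
        hmc_rate = float(params.get("hmc_rate", 0.0))
        comp = rng.choice(len(weights), size=n, p=weights)
        p_m = np.array(
            [rng.beta(alpha[k], beta[k]) for k in comp]
        ) * (1.0 - hmc_rate)
        return MethylomeTruth(
            sites, mode, confusion,
            site_p_5mC=p_m, site_p_5hmC=np.full(n, hmc_rate),
        )
    if mode == "dmr":
        ratio = float(params.get("allele_ratio", 0.5))
        p_meth = float(params.get("p_5mC_methylated", 0.9))
        p_unmeth = float(params.get("p_5mC_unmethylated", 0.05))
        if not (0.0 < ratio < 1.0):
            raise ValueError("allele_ratio must lie in (0, 1)")
        return MethylomeTruth(
            sites, mode, confusion,
            allele_p_5mC=(p_meth, p_unmeth), allele_ratio=ratio,
        )
    raise ValueError(f"unknown truth mode {mode!r}")


# ---------------------------------------------------------------------------
# read-call emission
# ---------------------------------------------------------------------------

def _observe(state: str, confusion: ConfusionParams, gc: float | None,
             rng: np.random.Generator) -> str:
    probs = confusion.row(state, gc)
    return STATES[rng.choice(3, p=probs)]


def simulate_read_calls(
    truth: MethylomeTruth,
    depth: DepthModel,
    seed: int = 0,
    gc_of_site: Callable[[str, int], float] | None = None,
) -> list[ReadCall]:
    """Emit simplex and duplex read calls from per-site truth.

    Per site, the template count is Poisson with a GC-adjusted mean.  Each
    template's true strand states pass through the confusion matrix
    independently per strand; a fraction ``duplex_rate`` of templates emit a
    duplex record (both strands on one record), the rest a simplex record on
    one uniformly chosen strand.
    """
    if truth.mode == "dmr":
        raise ValueError("use simulate_dmr_reads for dmr-mode truth")
    rng = np.random.default_rng(seed)
    calls: list[ReadCall] = []
    counter = 0
    for i, (chrom, pos) in enumerate(truth.sites):
        gc = gc_of_site(chrom, pos) if gc_of_site is not None else None
        n_templates = rng.poisson(depth.rate(gc))
        for _ in range(n_templates):
            top, bottom = truth.template_states(i, rng)
            read_id = f"r{counter:08d}"
            counter += 1
            if rng.random() < depth.duplex_rate:
                calls.append(
                    ReadCall(
                        read_id=read_id, chrom=chrom, cpg_pos=pos, strand="+",
                        call_state=_observe(top, truth.confusion, gc, rng),
                        is_duplex=True,
                        partner_state=_observe(bottom, truth.confusion, gc, rng),
                    )
                )
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                state = top if strand == "+" else bottom
                calls.append(
                    ReadCall(
                        read_id=read_id, chrom=chrom, cpg_pos=pos, strand=strand,
                        call_state=_observe(state, truth.confusion, gc, rng),
                    )
                )
    return calls


def simulate_dmr_reads(
    truth: MethylomeTruth,
    n_reads: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    duplex: bool = True,
) -> tuple[list[ReadCall], dict[str, str]]:
    """Emit whole-DMR reads from two-allele truth, with known allele labels.

    Each read is one template spanning the DMR: it is assigned an allele with
    probability ``allele_ratio`` (methylated), covers each CpG independently
    with probability ``1 - missing_rate``, and calls each covered strand
    through the confusion matrix.  Returns (calls, read_id -> allele).
    """
    if truth.mode != "dmr":
        raise ValueError("simulate_dmr_reads requires dmr-mode truth")
    rng = np.random.default_rng(seed)
    p_meth, p_unmeth = truth.allele_p_5mC
    calls: list[ReadCall] = []
    alleles: dict[str, str] = {}
    for r in range(n_reads):
        read_id = f"d{r:06d}"
        methylated = rng.random() < truth.allele_ratio
        alleles[read_id] = "methylated" if methylated else "unmethylated"
        p_m = p_meth if methylated else p_unmeth
        for chrom, pos in truth.sites:
            if rng.random() < missing_rate:
                continue
            top = "5mC" if rng.random() < p_m else "C"
            if duplex:
                bottom = "5mC" if rng.random() < p_m else "C"
                calls.append(
                    ReadCall(
                        read_id=read_id, chrom=chrom, cpg_pos=pos, strand="+",
                        call_state=_observe(top, truth.confusion, None, rng),
                        is_duplex=True,
                        partner_state=_observe(bottom, truth.confusion, None, rng),
                    )
                )
            else:
                calls.append(
                    ReadCall(
                        read_id=read_id, chrom=chrom, cpg_pos=pos, strand="+",
                        call_state=_observe(top, truth.confusion, None, rng),
                    )
                )
    return calls, alleles


def simulate_standards(
    n_sites: int,
    depth: int,
    confusion: ConfusionParams | None = None,
    seed: int = 0,
    positive_meth_fraction: float = 1.0,
    chrom: str = "chrS",
) -> tuple[list[ReadCall], list[ReadCall]]:
    """Simulate the two methylation standards used for accuracy benchmarking.

    Negative set: every true state is C (whole-genome-amplified, modification
    free).  Positive set: true state 5mC at a fraction
    ``positive_meth_fraction`` of templates (enzymatic methylation is >= 95%
    efficient per the manufacturer), C otherwise.  All calls are simplex on
    the forward strand; states pass through the confusion matrix.
    """
    confusion = confusion or ConfusionParams()
    rng = np.random.default_rng(seed)
    n_calls = n_sites * depth

    def _emit(true_states: np.ndarray, prefix: str) -> list[ReadCall]:
        out: list[ReadCall] = []
        observed = np.empty(n_calls, dtype=np.int64)
        for s in range(3):
            idx = np.flatnonzero(true_states == s)
            if idx.size:
                observed[idx] = rng.choice(3, size=idx.size, p=confusion.matrix[s])
        positions = np.repeat(np.arange(n_sites) * 2, depth)
        for k in range(n_calls):
            out.append(
                ReadCall(
                    read_id=f"{prefix}{k:08d}", chrom=chrom,
                    cpg_pos=int(positions[k]), strand="+",
                    call_state=STATES[observed[k]],
                )
            )
        return out

    negative = _emit(np.zeros(n_calls, dtype=np.int64), "neg")
    true_pos = np.where(
        rng.random(n_calls) < positive_meth_fraction, 1, 0
    ).astype(np.int64)
    positive = _emit(true_pos, "pos")
    return negative, positive


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class Annotations:
    """Synthetic annotation bundle for one genome."""

    features: list[GenomicInterval]
    cgis: list[GenomicInterval]
    shores: list[GenomicInterval]
    shelves: list[GenomicInterval]
    motifs: list[MotifSite]
    peaks: list[NarrowPeak]


def cgi_flanks(
    cgi: GenomicInterval, chrom_length: int
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Shores (2 kb immediately up/downstream of a CGI) and shelves (2-4 kb)."""
    shores, shelves = [], []
    for lo, hi, out in (
        (cgi.start - 2000, cgi.start, shores),
        (cgi.end, cgi.end + 2000, shores),
        (cgi.start - 4000, cgi.start - 2000, shelves),
        (cgi.end + 2000, cgi.end + 4000, shelves),
    ):
        lo, hi = max(0, lo), min(chrom_length, hi)
        if lo < hi:
            cls = "shore" if out is shores else "shelf"
            out.append(GenomicInterval(cgi.chrom, lo, hi, feature_class=cls))
    return shores, shelves


def simulate_annotations(
    sequences: dict[str, str],
    cpgs: dict[str, np.ndarray],
    seed: int = 0,
    high_gc_segments: list[GenomicInterval] | None = None,
    n_cgi_per_chrom: int = 2,
    n_motifs: int = 50,
    motif_length: int = 20,
    palindromic_fraction: float = 0.15,
    peak_fraction: float = 0.5,
    summit_in_motif_fraction: float = 1.0,
    peak_halfwidth: int = 150,
    fold_enrichment_mean: float = 5.0,
) -> Annotations:
    """Generate a self-consistent annotation set for a synthetic genome.

    Primary feature classes (promoter, exon, intron, intergenic) tile each
    chromosome without overlap; CpG islands sit on high-GC segments when
    provided, with shores and shelves derived by the 2 kb / 2-4 kb flank
    construction; motifs are ~20 bp intervals containing at least one CpG,
    a configurable fraction flagged palindromic; a configurable fraction of
    motifs receives a narrowPeak whose summit lies inside the motif.
    """
    rng = np.random.default_rng(seed)
    features: list[GenomicInterval] = []
    cgis: list[GenomicInterval] = []
    shores: list[GenomicInterval] = []
    shelves: list[GenomicInterval] = []
    motifs: list[MotifSite] = []
    peaks: list[NarrowPeak] = []

    for chrom, seq in sequences.items():
        length = len(seq)
        if length < 10_000:
            raise ValueError("chromosome too small for shelf construction")
        # alternate gene models and intergenic gaps along the chromosome
        pos = 0
        while pos < length:
            inter_len = int(rng.integers(2_000, 6_000))
            stop = min(pos + inter_len, length)
            features.append(
                GenomicInterval(chrom, pos, stop, feature_class="intergenic")
            )
            pos = stop
            if pos >= length:
                break
            gene_len = int(min(rng.integers(3_000, 8_000), length - pos))
            if gene_len < 1_500:
                features.append(
                    GenomicInterval(chrom, pos, length, feature_class="intergenic")
                )
                break
            # promoter = 1 kb upstream of the gene start (forward-strand genes)
            prom_len = min(1_000, gene_len // 3)
            features.append(
                GenomicInterval(chrom, pos, pos + prom_len, feature_class="promoter")
            )
            g = pos + prom_len
            gene_end = pos + gene_len
            exon = True
            while g < gene_end:
                part = int(min(rng.integers(200, 900), gene_end - g))
                cls = "exon" if exon else "intron"
                features.append(GenomicInterval(chrom, g, g + part, feature_class=cls))
                g += part
                exon = not exon
            pos = gene_end
        # CpG islands on high-GC segments if supplied, else random placements
        chrom_segs = [s for s in (high_gc_segments or []) if s.chrom == chrom]
        for k in range(n_cgi_per_chrom):
            if k < len(chrom_segs):
                seg = chrom_segs[k]
                cgi = GenomicInterval(chrom, seg.start, seg.end, feature_class="CGI")
            else:
                s = int(rng.integers(4_000, length - 5_000))
                cgi = GenomicInterval(chrom, s, s + 1_000, feature_class="CGI")
            cgis.append(cgi)
            sh, shf = cgi_flanks(cgi, length)
            shores.extend(sh)
            shelves.extend(shf)

    # motifs centred on CpG sites (>= 1 CpG each, by construction)
    all_sites = [(c, int(p)) for c in sorted(cpgs) for p in cpgs[c]]
    eligible = [
        (c, p) for c, p in all_sites
        if p >= motif_length and p + motif_length < len(sequences[c])
    ]
    idx = rng.choice(len(eligible), size=min(n_motifs, len(eligible)), replace=False)
    n_palin = int(round(palindromic_fraction * len(idx)))
    for j, k in enumerate(sorted(idx)):
        chrom, p = eligible[k]
        start = p - motif_length // 2 + 1
        iv = GenomicInterval(chrom, start, start + motif_length, name=f"motif{j}")
        contained = [
            int(q) for q in cpgs[chrom] if start <= q < start + motif_length
        ]
        motifs.append(
            MotifSite(
                interval=iv,
                motif_strand="+" if rng.random() < 0.5 else "-",
                is_palindromic=j < n_palin,
                cpg_positions=tuple(contained),
            )
        )
    # peaks over a fraction of motifs, summits inside the motif
    for j, m in enumerate(motifs):
        if rng.random() >= peak_fraction:
            continue
        centre = (m.interval.start + m.interval.end) // 2
        start = max(0, centre - peak_halfwidth)
        end = min(len(sequences[m.interval.chrom]), centre + peak_halfwidth)
        if rng.random() < summit_in_motif_fraction:
            summit = int(rng.integers(m.interval.start, m.interval.end))
        else:
            summit = int(rng.integers(start, end))
        fe = float(rng.lognormal(math.log(fold_enrichment_mean), 0.4))
        peaks.append(
            NarrowPeak(
                interval=GenomicInterval(
                    m.interval.chrom, start, end, name=f"peak{j}"
                ),
                summit_offset=summit - start,
                fold_enrichment=fe,
                neg_log10_q=float(rng.uniform(2, 30)),
            )
        )
    return Annotations(features, cgis, shores, shelves, motifs, peaks)


def simulate_peaks_for_scores(
    scored_tiles: list[tuple[GenomicInterval, float]],
    n_peaks: int,
    enriched_fraction: float = 0.9,
    seed: int = 0,
    peak_width: int = 200,
) -> list[NarrowPeak]:
    """Place peaks preferentially on positively scored tiles.

    A fraction ``enriched_fraction`` of peaks lands inside tiles with score
    > 0 (uniformly among them), the rest uniformly among all tiles; fold
    enrichment increases log-linearly with the host tile's score plus noise.
    Each peak is centred in its tile so its maximal-overlap assignment is the
    host tile.
    """
    rng = np.random.default_rng(seed)
    positive = [t for t in scored_tiles if t[1] > 0]
    if not scored_tiles:
        raise ValueError("no tiles supplied")
    peaks: list[NarrowPeak] = []
    for j in range(n_peaks):
        pool = positive if (positive and rng.random() < enriched_fraction) else scored_tiles
        iv, score = pool[int(rng.integers(len(pool)))]
        width = min(peak_width, len(iv))
        centre = (iv.start + iv.end) // 2
        start = max(iv.start, centre - width // 2)
        end = min(iv.end, start + width)
        fe = float(np.exp(0.5 * score + rng.normal(0, 0.2)) + 1.0)
        peaks.append(
            NarrowPeak(
                interval=GenomicInterval(iv.chrom, start, end, name=f"p{j}"),
                summit_offset=(end - start) // 2,
                fold_enrichment=fe,
                neg_log10_q=float(rng.uniform(2, 30)),
            )
        )
    return peaks
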