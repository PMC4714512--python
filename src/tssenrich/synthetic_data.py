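"""Synthetic genomes, gene models, expression tables and ChIP/input reads.

The generator emulates the inputs of a histone-variant ChIP-seq TSS
analysis: a small multi-chromosome genome, non-overlapping transcripts with
strands and exon blocks, log-normal FPKM values with a configurable
zero-expression fraction, a uniform Poisson read background (the input
library), and ChIP reads formed by that background plus a Gaussian
TSS-proximal enrichment kernel whose centre sits a configurable distance
downstream of the TSS.  Enrichment amplitude is either independent of
expression or coupled monotonically to the FPKM rank percentile, so the two
qualitative deposition modes seen for replication-independent H3 variants
(expression-independent vs expression-dependent) can both be simulated with
known ground truth.

All coordinates are 0-based half-open.  The TSS of a minus-strand gene is
``tx_end - 1`` (the 5' base of the transcript).  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "GeneModel",
    "EnrichmentSpec",
    "GenePlacementError",
    "READ_COLUMNS",
    "generate_genome",
    "simulate_expression",
    "rank_percentiles",
    "simulate_reads",
    "simulate_peaks",
    "mirror_dataset",
]

#: Column layout of the read table (one mapped fragment per row).
READ_COLUMNS = ("chrom", "start", "end", "strand")


class GenePlacementError(RuntimeError):
    """Raised when transcripts cannot be placed without overlap."""


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of named chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand, transcript bounds and exon blocks.

    ``utr5``/``utr3`` blocks are optional annotations used only by the peak
    annotator; the generator leaves them empty (no CDS is simulated).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = field(default=())
    utr3: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon blocks must be sorted, "
                                 "non-overlapping and within transcript bounds")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: the 5' base of the transcript."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: the 3' base of the transcript."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        gaps = []
        prev = None
        for s, e in self.exons:
            if prev is not None and s > prev:
                gaps.append((prev, s))
            prev = e
        return tuple(gaps)


@dataclass(frozen=True)
class EnrichmentSpec:
    """TSS-proximal enrichment kernel for ChIP read simulation.

    Fragment midpoints of enrichment reads are drawn from a Gaussian centred
    at ``TSS + strand-signed kernel_offset`` with s.d. ``kernel_width``.  The
    expected number of enrichment reads per gene is ``amplitude * c(g)``
    with ``c(g) = 1`` in independent mode and
    ``c(g) = percentile(g) ** coupling_exponent`` in dependent mode, where
    ``percentile`` is the gene's FPKM rank percentile in ``(0, 1]``.
    """

    kernel_offset: int = 500
    kernel_width: int = 500
    amplitude: float = 30.0
    coupling_mode: str = "independent"
    coupling_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.coupling_mode not in ("independent", "dependent"):
            raise ValueError("coupling_mode must be 'independent' or 'dependent'")


def _place_exons(rng: np.random.Generator, tx_start: int, tx_end: int,
                 n_exons: int) -> tuple[tuple[int, int], ...]:
    """First exon begins at tx_start, last ends at tx_end; cuts alternate
    exon/intron boundaries with every segment at least 1 bp."""
    if n_exons == 1:
        return ((tx_start, tx_end),)
    n_cuts = 2 * (n_exons - 1)
    interior = np.arange(tx_start + 1, tx_end)
    cuts = np.sort(rng.choice(interior, size=n_cuts, replace=False))
    bounds = [tx_start, *cuts.tolist(), tx_end]
    return tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons))


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    tx_length_range: tuple[int, int] = (1500, 3000),
    max_exons: int = 5,
    max_tries_per_gene: int = 1000,
) -> tuple[GenomeModel, list[GeneModel]]:
    """Generate equal-length chromosomes and non-overlapping transcripts.

    Strands are fair coins, transcript lengths uniform over
    ``tx_length_range`` (inclusive), exon counts uniform over
    ``1..max_exons``.  Placement is rejection sampling against the already
    placed transcripts; failure after ``max_tries_per_gene`` attempts raises
    :class:`GenePlacementError` naming the constraint.
    """
    if n_chroms <= 0 or chrom_length <= 0:
        raise ValueError("n_chroms and chrom_length must be positive")
    lo, hi = tx_length_range
    if not 0 < lo <= hi:
        raise ValueError("tx_length_range must satisfy 0 < lo <= hi")
    if hi > chrom_length:
        raise GenePlacementError(
            f"max transcript length {hi} exceeds chromosome length {chrom_length}")

    genome = GenomeModel(tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms)))
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    genes: list[GeneModel] = []
    width = max(5, len(str(max(n_genes, 1))))
    for i in range(n_genes):
        placed = False
        for _ in range(max_tries_per_gene):
            chrom = genome.names[int(rng.integers(0, n_chroms))]
            tx_len = int(rng.integers(lo, hi + 1))
            tx_start = int(rng.integers(0, chrom_length - tx_len + 1))
            tx_end = tx_start + tx_len
            occ = occupied[chrom]
            j = bisect.bisect_left(occ, (tx_start, tx_start))
            clash = (j > 0 and occ[j - 1][1] > tx_start) or (
                j < len(occ) and occ[j][0] < tx_end)
            if clash:
                continue
            occ.insert(j, (tx_start, tx_end))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            n_exons = int(rng.integers(1, max_exons + 1))
            exons = _place_exons(rng, tx_start, tx_end, n_exons)
            genes.append(GeneModel(f"gene{i:0{width}d}", chrom, strand,
                                   tx_start, tx_end, exons))
            placed = True
            break
        if not placed:
            raise GenePlacementError(
                f"could not place gene {i + 1}/{n_genes} without transcript overlap "
                f"after {max_tries_per_gene} attempts "
                f"({n_chroms} chromosome(s) of {chrom_length} bp)")
    return genome, genes


def simulate_expression(
    genes: list[GeneModel],
    zero_fraction: float = 0.15,
    lognormal_mu: float = 1.0,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene FPKM table with an exact zero-expression fraction.

    Exactly ``round(zero_fraction * n)`` genes receive FPKM 0; the rest are
    drawn log-normal.  Returns a DataFrame with columns ``gene_id, fpkm``
    in gene order.
    """
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must be in [0, 1)")
    n = len(genes)
    rng = np.random.default_rng(seed)
    fpkm = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=n)
    n_zero = round(zero_fraction * n)
    if n_zero:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        fpkm[zero_idx] = 0.0
    return pd.DataFrame({"gene_id": [g.gene_id for g in genes], "fpkm": fpkm})


def rank_percentiles(expr: pd.DataFrame) -> pd.Series:
    """FPKM rank percentile per gene, in ``(0, 1]``.

    Genes are ordered ascending by FPKM with gene_id as the deterministic
    tie-break; the gene at sorted position ``i`` of ``n`` gets
    ``(i + 1) / n``.
    """
    ordered = expr.sort_values(["fpkm", "gene_id"], kind="mergesort")
    n = len(ordered)
    pct = pd.Series(np.arange(1, n + 1) / n, index=ordered["gene_id"].to_numpy())
    return pct.reindex([*expr["gene_id"]])


def _clip_fragments(mids: np.ndarray, fragment_length: int,
                    chrom_length: int) -> tuple[np.ndarray, np.ndarray]:
    # Clip the midpoint, not the ends: every fragment keeps its exact
    # length and its floor-midpoint, so binning is midpoint-faithful and
    # (for odd lengths) reflection about the chromosome is exact.
    lo = fragment_length // 2
    hi = chrom_length - (fragment_length - lo)
    mids = np.clip(mids, lo, hi)
    start = mids - lo
    return start, start + fragment_length


def simulate_reads(
    genome: GenomeModel,
    genes: list[GeneModel],
    expr: pd.DataFrame,
    spec: EnrichmentSpec | None,
    background_depth: float,
    fragment_length: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate mapped fragments as a (chrom, start, end, strand) table.

    Background: per chromosome, ``Poisson(background_depth * length / 1000)``
    fragments with uniform midpoints.  With an :class:`EnrichmentSpec`, each
    gene additionally contributes ``Poisson(amplitude * c(g))`` fragments
    whose midpoints are Gaussian around ``TSS + strand-signed kernel_offset``
    with s.d. ``kernel_width``.  ``spec=None`` yields a pure-background
    (input-control-like) library.  Read strands are fair coins; fragments
    are clipped to chromosome bounds.
    """
    if background_depth < 0:
        raise ValueError("background_depth must be >= 0")
    for name, length in genome.chromosomes:
        if fragment_length >= length:
            raise ValueError(
                f"fragment_length {fragment_length} >= length of {name} ({length})")
    rng = np.random.default_rng(seed)
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []

    for name, length in genome.chromosomes:
        n_bg = rng.poisson(background_depth * length / 1000)
        mids = rng.integers(0, length, size=n_bg)
        s, e = _clip_fragments(mids, fragment_length, length)
        chroms.append(np.full(n_bg, name, dtype=object))
        starts.append(s)
        ends.append(e)

    if spec is not None and genes:
        if spec.coupling_mode == "dependent":
            pct = rank_percentiles(expr)
            coupling = {g: float(p) ** spec.coupling_exponent
                        for g, p in pct.items()}
        else:
            coupling = {g.gene_id: 1.0 for g in genes}
        lengths = genome.lengths
        for gene in genes:
            lam = spec.amplitude * coupling[gene.gene_id]
            n_enr = rng.poisson(lam)
            sign = 1 if gene.strand == "+" else -1
            centre = gene.tss + sign * spec.kernel_offset
            mids = np.rint(rng.normal(centre, spec.kernel_width, size=n_enr)).astype(int)
            s, e = _clip_fragments(mids, fragment_length, lengths[gene.chrom])
            chroms.append(np.full(n_enr, gene.chrom, dtype=object))
            starts.append(s)
            ends.append(e)

    start = np.concatenate(starts) if starts else np.array([], dtype=int)
    end = np.concatenate(ends) if ends else np.array([], dtype=int)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    strand = np.where(rng.integers(0, 2, size=len(start)) == 0, "+", "-")
    return pd.DataFrame({"chrom": chrom, "start": start.astype(int),
                         "end": end.astype(int), "strand": strand})


def simulate_peaks(genome: GenomeModel, n_peaks: int, peak_width: int = 400,
                   seed: int = 0) -> pd.DataFrame:
    """Uniform random peak intervals, as a stand-in for called peaks.

    Midpoints are uniform over the genome (chromosomes weighted by length);
    intervals are clipped to chromosome bounds.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(lengths), size=n_peaks, p=probs)
    rows = []
    for i in range(n_peaks):
        name, length = genome.chromosomes[which[i]]
        mid = int(rng.integers(0, length))
        s, e = _clip_fragments(np.array([mid]), peak_width, length)
        rows.append((name, int(s[0]), int(e[0])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def mirror_dataset(
    genome: GenomeModel,
    genes: list[GeneModel],
    reads: pd.DataFrame,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Reflect every chromosome end-for-end: coordinates map x -> L - x.

    Gene strands flip, transcript bounds and exon blocks mirror, and each
    read interval [s, e) becomes [L - e, L - s).  The aggregation profile of
    the mirrored dataset is exactly that of the original, which makes this
    the reference construction for strand-symmetry checks.
    """
    lengths = genome.lengths
    mirrored_genes = []
    for g in genes:
        L = lengths[g.chrom]
        exons = tuple(sorted((L - e, L - s) for s, e in g.exons))
        utr5 = tuple(sorted((L - e, L - s) for s, e in g.utr5))
        utr3 = tuple(sorted((L - e, L - s) for s, e in g.utr3))
        mirrored_genes.append(replace(
            g, strand="-" if g.strand == "+" else "+",
            tx_start=L - g.tx_end, tx_end=L - g.tx_start,
            exons=exons, utr5=utr5, utr3=utr3))
    L_per_read = reads["chrom"].map(lengths).to_numpy()
    mirrored = reads.copy()
    mirrored["start"] = L_per_read - reads["end"].to_numpy()
    mirrored["end"] = L_per_read - reads["start"].to_numpy()
    mirrored["strand"] = np.where(reads["strand"].to_numpy() == "+", "-", "+")
    return mirrored_genes, mirrored
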