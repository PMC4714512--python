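"""Strand-aware metagene (aggregation) profiles of signal around TSSs.

For every gene the signal bins covering ``[TSS - window, TSS + window]``
are extracted in transcription orientation: positive offsets always mean
downstream of the TSS in the direction of transcription, so minus-strand
profiles are reversed before averaging.  Profiles are taken at the native
bin resolution of the signal track, with no sub-bin interpolation.  Genes
whose window exceeds chromosome bounds are skipped and reported rather
than edge-padded, keeping the mean unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_signal import SignalTrack
from .expression_groups import ExpressionGroups
from .synthetic_data import GeneModel

__all__ = ["SkipRecord", "WindowOverflowError", "MetageneMatrix",
           "AggregationProfile", "extract_gene_profile",
           "build_metagene_matrix", "aggregate_profiles"]


class WindowOverflowError(ValueError):
    """A gene's TSS window extends beyond its chromosome's bin vector."""


@dataclass(frozen=True)
class SkipRecord:
    gene_id: str
    reason: str


@dataclass(frozen=True)
class MetageneMatrix:
    """Gene x offset grid of signal values in transcription orientation."""

    gene_ids: tuple[str, ...]
    offsets: np.ndarray          # signed offsets in bins, symmetric, includes 0
    values: np.ndarray           # shape (n_genes, n_offsets)
    window_bp: int
    bin_size: int

    @property
    def offsets_bp(self) -> np.ndarray:
        return self.offsets * self.bin_size


@dataclass(frozen=True)
class AggregationProfile:
    """Per-group mean signal vs signed distance from TSS.

    ``table`` columns: group, offset_bp, mean, se, n.  SE is the sample
    standard deviation over genes divided by sqrt(n); reported as 0 when
    n = 1 (flagged by the n column).
    """

    table: pd.DataFrame
    window_bp: int
    bin_size: int
    skipped: tuple[SkipRecord, ...]

    def group(self, label: str) -> pd.DataFrame:
        return (self.table[self.table["group"] == label]
                .sort_values("offset_bp").reset_index(drop=True))


def _window_bins(signal: SignalTrack, window_bp: int) -> int:
    if window_bp % signal.bin_size != 0:
        raise ValueError(
            f"window_bp ({window_bp}) must be a multiple of the bin size "
            f"({signal.bin_size})")
    return window_bp // signal.bin_size


def extract_gene_profile(signal: SignalTrack, gene: GeneModel,
                         window_bp: int) -> np.ndarray:
    """Signal values of the bins covering TSS ± window, oriented 5'→3'.

    Raises :class:`WindowOverflowError` if the window leaves the chromosome
    and ``KeyError`` if the chromosome is absent from the track.
    """
    w = _window_bins(signal, window_bp)
    if gene.chrom not in signal.values:
        raise KeyError(f"chromosome {gene.chrom!r} absent from signal track")
    vec = signal.values[gene.chrom]
    tss_bin = gene.tss // signal.bin_size
    lo, hi = tss_bin - w, tss_bin + w
    if lo < 0 or hi >= len(vec):
        raise WindowOverflowError(
            f"{gene.gene_id}: TSS window bins [{lo}, {hi}] exceed "
            f"chromosome {gene.chrom} ({len(vec)} bins)")
    profile = vec[lo:hi + 1].astype(float)
    return profile if gene.strand == "+" else profile[::-1]


def build_metagene_matrix(
    signal: SignalTrack,
    genes: list[GeneModel],
    window_bp: int,
) -> tuple[MetageneMatrix, list[SkipRecord]]:
    """Stack per-gene profiles; overflow genes become skip records."""
    w = _window_bins(signal, window_bp)
    rows, ids, skipped = [], [], []
    for gene in genes:
        try:
            rows.append(extract_gene_profile(signal, gene, window_bp))
            ids.append(gene.gene_id)
        except WindowOverflowError as exc:
            skipped.append(SkipRecord(gene.gene_id, str(exc)))
    values = (np.vstack(rows) if rows
              else np.empty((0, 2 * w + 1)))
    matrix = MetageneMatrix(tuple(ids), np.arange(-w, w + 1), values,
                            window_bp, signal.bin_size)
    return matrix, skipped


def _summarize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = values.shape[0]
    mean = values.mean(axis=0)
    se = (values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.zeros(values.shape[1]))
    return mean, se, n


def aggregate_profiles(
    signal: SignalTrack,
    genes: list[GeneModel],
    groups: ExpressionGroups | None = None,
    window_bp: int = 3000,
) -> AggregationProfile:
    """Mean ± SE signal per offset, for all genes and per expression group.

    The "all" profile averages every non-skipped gene.  With ``groups``
    given, one additional profile per decile label is produced over that
    decile's members; a group emptied by skips is omitted (recorded as a
    skip entry).
    """
    matrix, skipped = build_metagene_matrix(signal, genes, window_bp)
    offsets_bp = matrix.offsets_bp
    records: list[dict] = []

    def emit(label: str, values: np.ndarray) -> None:
        mean, se, n = _summarize(values)
        for o, m, s in zip(offsets_bp, mean, se):
            records.append({"group": label, "offset_bp": int(o),
                            "mean": float(m), "se": float(s), "n": n})

    if matrix.values.shape[0]:
        emit("all", matrix.values)
    row_of = {g: i for i, g in enumerate(matrix.gene_ids)}
    if groups is not None:
        for k, label in enumerate(groups.labels):
            idx = [row_of[g] for g in groups.members(k) if g in row_of]
            if not idx:
                skipped = [*skipped, SkipRecord(label, "group empty after skips")]
                continue
            emit(label, matrix.values[idx])

    table = pd.DataFrame(records,
                         columns=["group", "offset_bp", "mean", "se", "n"])
    return AggregationProfile(table=table, window_bp=window_bp,
                              bin_size=signal.bin_size,
                              skipped=tuple(skipped))
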