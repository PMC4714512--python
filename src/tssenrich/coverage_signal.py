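"""Binned read counting, RPKM normalization and ChIP−input subtraction.

The signal definition is: count fragment midpoints in fixed-width genomic
bins (1000 bp by default), normalize each library to RPKM
(reads per kilobase per million mapped reads), then subtract the input
control track from the ChIP track bin by bin.  The resulting per-bin RPKM
difference is the "ChIP-seq signal intensity" consumed by the aggregation
and increment modules; negative values are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import GenomeModel

__all__ = ["BinTrack", "SignalTrack", "count_reads_in_bins",
           "rpkm_normalize", "subtract_control"]


@dataclass(frozen=True)
class BinTrack:
    """Per-chromosome fixed-width bin vectors of counts or RPKM values.

    ``total_reads`` records the library size used (or to be used) for RPKM
    normalization.  The last bin of each chromosome may cover fewer than
    ``bin_size`` bases but is normalized with the nominal bin size.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    value_kind: str  # "count" or "rpkm"
    total_reads: int

    def __post_init__(self) -> None:
        if self.value_kind not in ("count", "rpkm"):
            raise ValueError("value_kind must be 'count' or 'rpkm'")

    def geometry(self) -> tuple[tuple[str, int], ...]:
        return tuple((c, len(v)) for c, v in self.values.items())


@dataclass(frozen=True)
class SignalTrack:
    """Per-bin ChIP − input RPKM difference; values may be negative."""

    bin_size: int
    values: dict[str, np.ndarray]
    provenance: tuple[str, str] = ("chip", "control")

    def geometry(self) -> tuple[tuple[str, int], ...]:
        return tuple((c, len(v)) for c, v in self.values.items())


def count_reads_in_bins(reads: pd.DataFrame, genome: GenomeModel,
                        bin_size: int = 1000) -> BinTrack:
    """Count fragment midpoints into fixed-width bins.

    Each read contributes exactly 1 to the single bin containing its
    interval midpoint ``floor((start + end) / 2)``, so the sum over all bins
    equals the number of reads.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    lengths = genome.lengths
    values = {name: np.zeros(-(-length // bin_size), dtype=np.int64)
              for name, length in genome.chromosomes}

    if len(reads):
        unknown = ~reads["chrom"].isin(lengths)
        if unknown.any():
            bad = reads[unknown].iloc[0]
            raise ValueError(
                f"read {bad['chrom']}:{bad['start']}-{bad['end']} is on a "
                "chromosome absent from the genome")
        chrom_len = reads["chrom"].map(lengths).to_numpy()
        start = reads["start"].to_numpy()
        end = reads["end"].to_numpy()
        bad_mask = (start < 0) | (end > chrom_len) | (start >= end)
        if bad_mask.any():
            bad = reads[bad_mask].iloc[0]
            raise ValueError(
                f"read {bad['chrom']}:{bad['start']}-{bad['end']} violates "
                "0 <= start < end <= chromosome length")
        mids = (start + end) // 2
        bins = mids // bin_size
        for name, grp in pd.DataFrame({"chrom": reads["chrom"], "bin": bins}
                                      ).groupby("chrom", sort=False):
            counts = np.bincount(grp["bin"].to_numpy(),
                                 minlength=len(values[name]))
            values[name] += counts.astype(np.int64)

    return BinTrack(bin_size=bin_size, values=values, value_kind="count",
                    total_reads=int(len(reads)))


def rpkm_normalize(track: BinTrack) -> BinTrack:
    """RPKM per bin: ``count * 1e9 / (bin_size * total_reads)``.

    For 1000-bp bins this reduces to ``count * 1e6 / total_reads``.
    """
    if track.value_kind != "count":
        raise ValueError("rpkm_normalize expects a count-valued track")
    if track.total_reads <= 0:
        raise ValueError("cannot RPKM-normalize a track with total_reads = 0")
    factor = 1e9 / (track.bin_size * track.total_reads)
    values = {c: v.astype(float) * factor for c, v in track.values.items()}
    return BinTrack(bin_size=track.bin_size, values=values,
                    value_kind="rpkm", total_reads=track.total_reads)


def subtract_control(chip: BinTrack, control: BinTrack) -> SignalTrack:
    """Per-bin ChIP − control RPKM difference; negatives are preserved."""
    if chip.value_kind != "rpkm" or control.value_kind != "rpkm":
        raise ValueError("both tracks must be RPKM-valued")
    if chip.bin_size != control.bin_size:
        raise ValueError(f"bin size mismatch: {chip.bin_size} vs {control.bin_size}")
    if chip.geometry() != control.geometry():
        mism = sorted(set(chip.geometry()) ^ set(control.geometry()))
        raise ValueError(f"track geometry mismatch: {mism}")
    values = {c: chip.values[c] - control.values[c] for c in chip.values}
    return SignalTrack(bin_size=chip.bin_size, values=values)
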