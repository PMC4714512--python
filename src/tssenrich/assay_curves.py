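"""Normalization of tetrasome thermal-stability and FRAP recovery curves.

Thermal stability: raw fluorescence F(T) measured over a 26–95 °C gradient
is rescaled as ``F_norm(T) = [F(T) - F(26)] / [F(95) - F(26)]``, anchoring
the curve at 0 (26 °C) and 1 (95 °C).  The normalization is exactly
invariant to affine gain/offset transforms of the raw signal.  A
half-dissociation temperature is summarized by linear interpolation at the
first 0.5 crossing.

FRAP: after background subtraction, the ratio of bleached to unbleached
area intensity is normalized to its value at the last pre-bleach time
point, so the pre-bleach anchor is exactly 1 and full recovery returns
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = ["MeltCurve", "FrapSeries", "HalfTemperature",
           "normalize_melt_curve", "melt_half_temperature",
           "average_melt_replicates", "frap_relative_intensity"]

ANCHOR_LOW_C = 26.0
ANCHOR_HIGH_C = 95.0


@dataclass(frozen=True)
class MeltCurve:
    """Ordered (temperature °C, raw fluorescence) pairs including 26 and 95."""

    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)

    def _anchor(self, temp_c: float) -> float:
        idx = np.nonzero(np.isclose(self.temperature, temp_c))[0]
        if not len(idx):
            raise ValueError(f"curve lacks the {temp_c:g} °C anchor point")
        return float(self.fluorescence[idx[0]])


@dataclass(frozen=True)
class FrapSeries:
    """Time course of (bleached, unbleached, background) intensities.

    ``n_prebleach`` leading points precede the bleach; at every point the
    background-corrected unbleached intensity must be positive.
    """

    time_min: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    background: np.ndarray
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.time_min, self.bleached, self.unbleached, self.background)]
        if len({a.shape for a in arrays}) != 1 or arrays[0].ndim != 1:
            raise ValueError("all channels must be equal-length 1-D")
        if not np.all(np.diff(arrays[0]) > 0):
            raise ValueError("time points must be strictly increasing")
        if not 1 <= self.n_prebleach <= len(arrays[0]):
            raise ValueError("series must include at least one pre-bleach point")
        if np.any(arrays[2] - arrays[3] <= 0):
            raise ValueError("unbleached - background must be > 0 at all points")
        for name, a in zip(("time_min", "bleached", "unbleached", "background"),
                           arrays):
            object.__setattr__(self, name, a)


class HalfTemperature(NamedTuple):
    temperature_c: float
    multiple_crossings: bool


def normalize_melt_curve(curve: MeltCurve) -> pd.DataFrame:
    """Pointwise ``[F(T) - F(26)] / [F(95) - F(26)]``.

    Output is exactly 0 at 26 °C and exactly 1 at 95 °C; a degenerate curve
    with F(95) = F(26) is rejected.
    """
    f26 = curve._anchor(ANCHOR_LOW_C)
    f95 = curve._anchor(ANCHOR_HIGH_C)
    if f95 == f26:
        raise ValueError("degenerate curve: F(95) equals F(26)")
    norm = (curve.fluorescence - f26) / (f95 - f26)
    return pd.DataFrame({"temperature": curve.temperature,
                         "normalized_fluorescence": norm})


def melt_half_temperature(normalized: pd.DataFrame) -> HalfTemperature:
    """Temperature of the first 0.5 crossing, linearly interpolated.

    A sample landing exactly on 0.5 is returned as-is.  The flag marks
    curves that cross 0.5 more than once.
    """
    t = normalized["temperature"].to_numpy(dtype=float)
    y = normalized["normalized_fluorescence"].to_numpy(dtype=float)
    shifted = y - 0.5
    crossings = []
    for i in range(len(y)):
        if shifted[i] == 0.0:
            crossings.append(float(t[i]))
        elif i + 1 < len(y) and shifted[i] * shifted[i + 1] < 0:
            frac = shifted[i] / (y[i] - y[i + 1])
            crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
    if not crossings:
        raise ValueError("normalized curve never crosses 0.5")
    return HalfTemperature(crossings[0], len(crossings) > 1)


def average_melt_replicates(curves: Sequence[MeltCurve]) -> pd.DataFrame:
    """Pointwise mean ± s.d. of replicate curves after normalization.

    Replicates must share their temperature grid.
    """
    if not curves:
        raise ValueError("no replicate curves given")
    grid = curves[0].temperature
    stacked = []
    for c in curves:
        if not np.array_equal(c.temperature, grid):
            raise ValueError("replicate curves must share the temperature grid")
        stacked.append(normalize_melt_curve(c)["normalized_fluorescence"].to_numpy())
    arr = np.vstack(stacked)
    return pd.DataFrame({"temperature": grid,
                         "mean": arr.mean(axis=0),
                         "sd": arr.std(axis=0, ddof=1) if len(curves) > 1
                               else np.zeros(len(grid))})


def frap_relative_intensity(series: FrapSeries) -> pd.DataFrame:
    """Background-corrected bleached/unbleached ratio, pre-bleach = 1.

    ``r(t) = (bleached - background) / (unbleached - background)`` divided
    by its value at the last pre-bleach point.
    """
    r = (series.bleached - series.background) / (
        series.unbleached - series.background)
    r_pre = r[series.n_prebleach - 1]
    if r_pre == 0:
        raise ValueError("pre-bleach relative intensity is zero")
    return pd.DataFrame({"time_min": series.time_min,
                         "relative_intensity": r / r_pre})
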