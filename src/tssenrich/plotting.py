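"""Figure helpers: aggregation profiles, increment curves, melt/FRAP curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .genomic_annotation import CategoryDistribution  # noqa: E402
from .increment_analysis import IncrementCurve  # noqa: E402
from .tss_aggregation import AggregationProfile  # noqa: E402

__all__ = ["plot_aggregation", "plot_increment", "plot_category_distribution"]


def plot_aggregation(profile: AggregationProfile, path: str | Path) -> None:
    """One mean line per group against signed distance from the TSS."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in profile.table.groupby("group", sort=False):
        grp = grp.sort_values("offset_bp")
        ax.plot(grp["offset_bp"], grp["mean"],
                lw=2 if label == "all" else 1, label=label)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("ChIP - input signal (RPKM)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_increment(curve: IncrementCurve, path: str | Path) -> None:
    """Mean increment per expression decile with ± SE envelope."""
    t = curve.table
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t["decile"], t["increment"], marker="o")
    ax.plot(t["decile"], t["increment"] + t["se"], ls=":", color="grey")
    ax.plot(t["decile"], t["increment"] - t["se"], ls=":", color="grey")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("expression decile (low -> high FPKM)")
    ax.set_ylabel("signal increment (RPKM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_category_distribution(dist: CategoryDistribution,
                               path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    t = dist.table
    ax.bar(t["category"], t["percentage"])
    ax.set_ylabel("% of peaks")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
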