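"""Expression-decile stratification of genes by FPKM.

Genes with FPKM = 0 are excluded; the remainder are ordered ascending by
FPKM (ties broken by gene_id) and split into ten groups of
equal-as-possible size, labelled q0-10% through q90-100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DECILE_LABELS", "ExpressionGroups", "assign_deciles"]

DECILE_LABELS: tuple[str, ...] = tuple(
    f"q{10 * k}-{10 * (k + 1)}%" for k in range(10))


@dataclass(frozen=True)
class ExpressionGroups:
    """Partition of nonzero-FPKM genes into ten ordered percentile groups."""

    assignment: dict[str, int]          # gene_id -> group index 0..9
    excluded: frozenset[str]            # gene_ids with fpkm == 0
    labels: tuple[str, ...] = field(default=DECILE_LABELS)

    def members(self, group: int) -> list[str]:
        return [g for g, k in self.assignment.items() if k == group]

    def group_sizes(self) -> list[int]:
        sizes = [0] * len(self.labels)
        for k in self.assignment.values():
            sizes[k] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, k, self.labels[k]) for g, k in self.assignment.items()]
        return pd.DataFrame(rows, columns=["gene_id", "group", "label"])


def assign_deciles(expr: pd.DataFrame) -> ExpressionGroups:
    """Assign each nonzero-FPKM gene to one of ten expression deciles.

    The gene at ascending-sorted position ``i`` of ``n`` goes to group
    ``floor(10 * i / n)``, the standard equal-as-possible split: group sizes
    differ by at most one, and group index is non-decreasing in FPKM.
    Raises ``ValueError`` with fewer than 10 nonzero-FPKM genes.
    """
    if expr["gene_id"].duplicated().any():
        dup = expr["gene_id"][expr["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id in expression table: {dup!r}")
    if (expr["fpkm"] < 0).any():
        raise ValueError("FPKM values must be non-negative")
    zero = expr["fpkm"] == 0
    excluded = frozenset(expr.loc[zero, "gene_id"])
    nonzero = expr.loc[~zero]
    n = len(nonzero)
    if n < 10:
        raise ValueError(f"need at least 10 genes with FPKM > 0, got {n}")
    ordered = nonzero.sort_values(["fpkm", "gene_id"], kind="mergesort")
    groups = (10 * np.arange(n)) // n
    assignment = dict(zip(ordered["gene_id"], (int(k) for k in groups)))
    return ExpressionGroups(assignment=assignment, excluded=excluded)
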