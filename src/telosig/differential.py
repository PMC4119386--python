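"""Group means, the signed fold statistic, and multi-threshold count tables.

Differential expression here is fold-based: for each gene the mean linear
"density" of expression per sample group is compared between a focal group
(the focal cell type at one timepoint) and each other cell group. The signed
fold is the *symmetric relative difference*: with pseudocounted means
a' = a + ε (focal) and b' = b + ε (other),

    f = +(a' − b')/b'   if a' ≥ b'   (up-regulated in the focal group)
    f = −(b' − a')/a'   otherwise    (down-regulated)

so "up-regulated more than onefold" (f > 1) is exactly a' > 2·b', the
conventional two-fold-ratio reading, and f is antisymmetric under swapping
the two groups. The literal one-sided form (always dividing by the focal
mean) is available as ``formula="literal"`` for comparison, but note it can
never exceed 1 in the up direction when the other mean is positive.

Counting genes beyond a ladder of thresholds (1, 2, 5, 10 by default), per
comparison and per direction, gives the summary count grid; "combined" rows
count a gene only if it passes the threshold in BOTH focal timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_THRESHOLDS = (1.0, 2.0, 5.0, 10.0)


@dataclass
class GroupMeans:
    """Gene × sample-group table of mean linear expression."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("group means must be non-negative (linear scale)")

    @property
    def groups(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class FoldChangeTable:
    """Per-gene signed folds for one (focal group, other group) comparison."""

    focal: str
    other: str
    folds: pd.Series
    pseudocount: float

    @property
    def label(self) -> str:
        return f"{self.focal} versus {self.other}"

    def up_mask(self, threshold: float) -> pd.Series:
        return self.folds > threshold

    def down_mask(self, threshold: float) -> pd.Series:
        return -self.folds > threshold


@dataclass
class CountSummary:
    """Comparison × (direction, threshold) grid of differential gene counts."""

    table: pd.DataFrame  # index: comparison row label; columns like "up>1"

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="comparison")


def group_means(matrix: ExpressionMatrix, meta: SampleMetadata) -> GroupMeans:
    """Arithmetic mean over replicate columns per (cell type, timepoint) group."""
    if matrix.scale != "linear":
        raise ValueError("group means are defined on linear intensities")
    meta.check_covers(matrix)
    labels = meta.groups().loc[matrix.values.columns]
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise ValueError(f"sample {bad!r} has no group label")
    gm = matrix.values.T.groupby(labels, sort=False).mean().T
    if gm.isna().any().any():
        raise ValueError("a sample group has zero columns")
    return GroupMeans(gm)


def fold_change(a, b, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                formula: Literal["symmetric", "literal"] = "symmetric"):
    """Signed fold between focal mean(s) ``a`` and other mean(s) ``b``.

    Vectorized over array inputs. ``symmetric`` (default) is the relative
    difference with the smaller mean in the denominator, signed toward the
    focal group; ``literal`` always divides by the focal mean.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(a, dtype=float) + pseudocount
    b = np.asarray(b, dtype=float) + pseudocount
    if formula == "symmetric":
        out = np.where(a >= b, (a - b) / b, -(b - a) / a)
    elif formula == "literal":
        out = (a - b) / a
    else:
        raise ValueError(f"unknown fold formula {formula!r}")
    return out if out.ndim else float(out)


def pairwise_fold_tables(gm: GroupMeans, focal_groups: Sequence[str],
                         other_groups: Sequence[str],
                         pseudocount: float = DEFAULT_PSEUDOCOUNT,
                         formula: Literal["symmetric", "literal"] = "symmetric"
                         ) -> list[FoldChangeTable]:
    """One fold table per ordered (focal group, other group) pair."""
    overlap = set(focal_groups) & set(other_groups)
    if overlap:
        raise ValueError(f"focal and other group sets overlap: {sorted(overlap)}")
    for g in list(focal_groups) + list(other_groups):
        if g not in gm.table.columns:
            raise ValueError(f"group {g!r} absent from group means")
    tables = []
    for f in focal_groups:
        for o in other_groups:
            folds = pd.Series(
                fold_change(gm.table[f].to_numpy(), gm.table[o].to_numpy(),
                            pseudocount, formula),
                index=gm.table.index)
            tables.append(FoldChangeTable(focal=f, other=o, folds=folds,
                                          pseudocount=pseudocount))
    return tables


def threshold_counts(tables: Iterable[FoldChangeTable],
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     combined_label: str | None = None) -> CountSummary:
    """Count genes beyond each threshold, per comparison and direction.

    Thresholds use strict inequality ("more than onefold"). When more than one
    focal group compares against the same other group, an extra combined row
    counts genes passing the threshold in EVERY focal group for that other
    group; its label prefix defaults to the longest common prefix of the focal
    labels (e.g. ``TC5``/``TC10`` → ``TCs``).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no fold tables given")
    thresholds = sorted(thresholds)
    cols = [f"up>{_fmt(t)}" for t in thresholds] + [f"down>{_fmt(t)}" for t in thresholds]

    rows: dict[str, list[int]] = {}
    by_other: dict[str, list[FoldChangeTable]] = {}
    for tb in tables:
        rows[tb.label] = ([int(tb.up_mask(t).sum()) for t in thresholds]
                          + [int(tb.down_mask(t).sum()) for t in thresholds])
        by_other.setdefault(tb.other, []).append(tb)

    focal_labels = sorted({tb.focal for tb in tables})
    if len(focal_labels) > 1:
        if combined_label is None:
            import os.path
            prefix = os.path.commonprefix(focal_labels).rstrip("_")
            combined_label = (prefix + "s") if prefix else "combined"
        for other, tbs in by_other.items():
            if len(tbs) < 2:
                continue
            up = [int(np.logical_and.reduce([tb.up_mask(t) for tb in tbs]).sum())
                  for t in thresholds]
            down = [int(np.logical_and.reduce([tb.down_mask(t) for tb in tbs]).sum())
                    for t in thresholds]
            rows[f"{combined_label} versus {other}"] = up + down

    return CountSummary(pd.DataFrame.from_dict(rows, orient="index", columns=cols))


def _fmt(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def write_fold_table(table: FoldChangeTable, path: str | Path) -> None:
    df = pd.DataFrame({"fold": table.folds})
    df.to_csv(path, sep="\t", index_label="symbol")
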