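"""Cell-type-specific signatures, top-k ranking, and hierarchical clustering.

A gene belongs to the focal type's *specific signature* at threshold t only if
its fold passes t against EVERY other cell group; the two focal timepoints are
combined under a ``both`` rule (passes in each timepoint's full comparison set)
or an ``either`` rule (passes the full set in at least one timepoint).

Sample relationships are summarized by agglomerative hierarchical clustering
on a Pearson-correlation dissimilarity (d = 1 − r) computed over a chosen gene
subset — typically the union of all differential genes. The agglomerator is a
plain O(n³) implementation with a deterministic tie-break: among all
minimum-dissimilarity cluster pairs, the pair whose (sorted) representative
leaf labels are lexicographically smallest merges first. Dendrograms export to
Newick with ultrametric branch lengths (leaf depth = merge height / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .differential import FoldChangeTable
from .expression_io import ExpressionMatrix

Linkage = Literal["average", "complete", "single"]
TimepointRule = Literal["both", "either"]


@dataclass
class SignatureSet:
    """Up/down gene lists specific to the focal type at one threshold."""

    up: frozenset[str]
    down: frozenset[str]
    threshold: float
    timepoint_rule: TimepointRule
    # smallest |fold| across all comparisons, per signature gene (audit column)
    min_fold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("signature up and down sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def write(self, path: str | Path) -> None:
        rows = [{"symbol": g, "direction": "up",
                 "min_fold": self.min_fold.get(g, float("nan"))}
                for g in sorted(self.up)]
        rows += [{"symbol": g, "direction": "down",
                  "min_fold": self.min_fold.get(g, float("nan"))}
                 for g in sorted(self.down)]
        pd.DataFrame(rows, columns=["symbol", "direction", "min_fold"]).to_csv(
            path, sep="\t", index=False)


def specific_signature(tables: Iterable[FoldChangeTable], threshold: float,
                       timepoint_rule: TimepointRule = "both") -> SignatureSet:
    """Intersect fold tables into the focal-type-specific up/down signature.

    ``tables`` must cover every (focal timepoint group, other group) pair;
    a missing pair raises, naming it. A gene qualifying up under one timepoint
    and down under the other (possible only under ``either``) is contradictory
    and excluded from both sets.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no fold tables given")
    focal_groups = sorted({t.focal for t in tables})
    other_groups = sorted({t.other for t in tables})
    lookup: dict[tuple[str, str], FoldChangeTable] = {}
    for t in tables:
        lookup[(t.focal, t.other)] = t
    for f in focal_groups:
        for o in other_groups:
            if (f, o) not in lookup:
                raise ValueError(f"missing comparison pair: {f!r} versus {o!r}")
    if timepoint_rule not in ("both", "either"):
        raise ValueError(f"unknown timepoint rule {timepoint_rule!r}")

    genes = tables[0].folds.index
    per_tp_up, per_tp_down = [], []
    for f in focal_groups:
        up = np.logical_and.reduce(
            [lookup[(f, o)].up_mask(threshold).to_numpy() for o in other_groups])
        down = np.logical_and.reduce(
            [lookup[(f, o)].down_mask(threshold).to_numpy() for o in other_groups])
        per_tp_up.append(up)
        per_tp_down.append(down)
    combine = np.logical_and if timepoint_rule == "both" else np.logical_or
    up_mask = combine.reduce(per_tp_up)
    down_mask = combine.reduce(per_tp_down)
    both = up_mask & down_mask
    up_mask &= ~both
    down_mask &= ~both

    all_folds = pd.concat([t.folds.abs() for t in tables], axis=1)
    min_fold = all_folds.min(axis=1)
    up = frozenset(genes[up_mask])
    down = frozenset(genes[down_mask])
    return SignatureSet(
        up=up, down=down, threshold=threshold, timepoint_rule=timepoint_rule,
        min_fold={g: float(min_fold[g]) for g in up | down})


def top_k_genes(table: FoldChangeTable, k: int,
                direction: Literal["up", "down"]) -> list[str]:
    """The k genes with largest |fold| in one direction, ties broken by symbol.

    Returns fewer than k genes when fewer qualify (no padding).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction == "up":
        sub = table.folds[table.folds > 0]
    elif direction == "down":
        sub = -table.folds[table.folds < 0]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    df = pd.DataFrame({"mag": sub, "symbol": sub.index.astype(str)})
    df = df.sort_values(["mag", "symbol"], ascending=[False, True])
    return list(df["symbol"].iloc[:k])


def pearson_dissimilarity(matrix: ExpressionMatrix,
                          rows: Sequence[str] | None = None) -> pd.DataFrame:
    """Sample × sample dissimilarity d = 1 − Pearson r over a gene subset."""
    genes = list(rows) if rows is not None else list(matrix.values.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sub = matrix.values.loc[genes]
    sd = sub.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"sample {bad!r} has zero variance over the gene subset")
    r = np.corrcoef(sub.to_numpy(), rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over named leaves.

    ``merges`` holds (cluster id a, cluster id b, height); leaves carry ids
    0..n−1 in ``leaves`` order and merge i creates cluster id n+i, scipy
    linkage-matrix style.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def clades(self) -> set[frozenset[str]]:
        """Leaf-name sets of every internal cluster (and every leaf singleton)."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {
            i: frozenset([name]) for i, name in enumerate(self.leaves)}
        out = set(members.values())
        for i, (a, b, _) in enumerate(self.merges):
            members[n + i] = members[a] | members[b]
            out.add(members[n + i])
        return out

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (half merge heights)."""
        n = len(self.leaves)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: name for i, name in enumerate(self.leaves)}
        for i, (a, b, h) in enumerate(self.merges):
            ha, hb = h / 2.0, h / 2.0
            bl_a = ha - height[a] / 2.0
            bl_b = hb - height[b] / 2.0
            node[n + i] = f"({node[a]}:{bl_a:g},{node[b]}:{bl_b:g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(d: pd.DataFrame, linkage: Linkage = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric dissimilarity table.

    Deterministic: among minimum-distance pairs, the pair whose sorted
    representative leaf labels compare lexicographically smallest merges first.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    labels = list(d.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    if list(d.columns) != labels:
        raise ValueError("dissimilarity table must be square with matching ids")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0.0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")

    # active clusters: id -> (representative sorted labels, member leaf indices)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = dm[i, j]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for pair, dd in dist.items():
            a, b = sorted(pair)
            key = tuple(sorted((rep[a], rep[b])))
            if dd < best_d or (dd == best_d and best_pair is not None
                               and key < best_pair[1]):
                best_pair, best_d = ((a, b), key), dd
        (a, b), _ = best_pair
        new = next_id
        next_id += 1
        members = active[a] + active[b]
        merges.append((a, b, float(best_d)))
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "average":
                na, nb = len(active[a]), len(active[b])
                dd = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                dd = max(da, db)
            else:
                dd = min(da, db)
            dist[frozenset((new, other))] = dd
        dist.pop(frozenset((a, b)))
        del active[a], active[b]
        active[new] = members
        rep[new] = tuple(sorted(rep[a] + rep[b]))

    return Dendrogram(leaves=labels, merges=merges)


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")
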