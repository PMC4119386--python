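"""Hypergeometric over-representation and a local co-expression network.

Enrichment tests whether a signature overlaps a named gene set more than
random draws from the gene universe would: with universe size N, set size K,
signature size n and overlap k, the upper-tail p-value is
P(X ≥ k) for X ~ Hypergeometric(N, K, n), adjusted across the collection with
Benjamini–Hochberg. Gene-set collections are user-supplied (GMT format); no
ontology or pathway databases are fetched.

The co-expression network is a local, data-driven companion to protein
association lookups: nodes are genes, and an undirected edge links two genes
whose expression profiles correlate with |Pearson r| at or above a threshold
across samples. Signatures export as newline-delimited symbol lists suitable
for pasting into external multi-protein query forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix
from .signature_cluster import SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named symbol sets plus the universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("gene universe is empty")
        self.sets = {name: frozenset(s) & self.universe
                     for name, s in self.sets.items()}


def read_gmt(path: str | Path, universe: Sequence[str]) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated symbols per line)."""
    sets, desc = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs >= 3 fields: {line[:60]!r}")
        sets[fields[0]] = frozenset(fields[2:])
        desc[fields[0]] = fields[1]
    return GeneSetCollection(sets=sets, universe=frozenset(universe),
                             descriptions=desc)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in gsc.sets.items():
        d = (gsc.descriptions or {}).get(name, "")
        lines.append("\t".join([name, d] + sorted(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(signature: SignatureSet | Sequence[str],
                              gsc: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric test of a signature against every gene set.

    Signature genes outside the universe are dropped with a warning. Returns a
    DataFrame (index: set name) with overlap k, set size K, signature size n,
    universe size N, p (P(X ≥ k)) and BH-adjusted q, sorted by p.
    """
    genes = signature.genes if isinstance(signature, SignatureSet) else frozenset(signature)
    if not genes:
        raise ValueError("empty signature")
    inside = genes & gsc.universe
    dropped = genes - gsc.universe
    if dropped:
        logger.warning("enrichment: %d signature genes outside universe dropped",
                       len(dropped))
    if not inside:
        raise ValueError("no signature gene lies in the universe")
    N = len(gsc.universe)
    n = len(inside)
    rows = {}
    for name, members in gsc.sets.items():
        K = len(members)
        k = len(inside & members)
        # sf(k-1) = P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows[name] = {"k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p")


def coexpression_network(matrix: ExpressionMatrix, genes: Sequence[str],
                         r_threshold: float = 0.8) -> nx.Graph:
    """Undirected network with edges where |Pearson r| ≥ r_threshold.

    Needs ≥ 3 samples; zero-variance genes are excluded with a warning. Edge
    weights store |r|; the threshold is recorded as a graph attribute.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must lie in (0, 1]")
    if matrix.n_samples < 3:
        raise ValueError("co-expression needs at least 3 samples")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[list(genes)]
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = list(sd.index[sd == 0])
        logger.warning("co-expression: dropping zero-variance genes %s", dropped[:5])
        sub = sub.loc[sd > 0]
    g = nx.Graph(r_threshold=float(r_threshold))
    g.add_nodes_from(sub.index)
    if sub.shape[0] >= 2:
        r = np.corrcoef(sub.to_numpy())
        names = list(sub.index)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                w = abs(float(r[i, j]))
                if w >= r_threshold:
                    g.add_edge(names[i], names[j], weight=w)
    return g


def write_network(graph: nx.Graph, edge_list_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    rows = [{"gene_a": a, "gene_b": b, "abs_r": d["weight"]}
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "abs_r"]).to_csv(
        edge_list_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)


def export_string_query(signature: SignatureSet | Sequence[str],
                        path: str | Path) -> None:
    """Write a newline-delimited symbol list for external multi-protein queries."""
    genes = sorted(signature.genes if isinstance(signature, SignatureSet)
                   else signature)
    if not genes:
        raise ValueError("cannot export an empty signature")
    Path(path).write_text("\n".join(genes) + "\n")
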