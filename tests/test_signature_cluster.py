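"""Signature intersection, top-k ranking, correlation distance, clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from telosig.differential import FoldChangeTable, group_means, pairwise_fold_tables
from telosig.expression_io import ExpressionMatrix
from telosig.signature_cluster import (
    Dendrogram,
    hierarchical_cluster,
    pearson_dissimilarity,
    specific_signature,
    top_k_genes,
)
from telosig.synthetic_data import generate_dataset

from conftest import small_config

OTHERS = ["MSC", "Fb", "ATII", "ABC", "PAC", "T-BL", "T-LL"]


def _tables(up_vs: dict[str, set[str]], genes=("gA", "gB", "gC")):
    """Fold tables over both timepoints where gene g is 'up' (+1.5) against the
    other groups listed in up_vs[g], else flat (0.0)."""
    tables = []
    for f in ("TC5", "TC10"):
        for o in OTHERS:
            folds = pd.Series(
                {g: 1.5 if o in up_vs.get(g, set()) else 0.0 for g in genes})
            tables.append(FoldChangeTable(f, o, folds, 1.0))
    return tables


class TestSpecificSignature:
    def test_gene_up_against_six_of_seven_excluded(self):
        tables = _tables({"gA": set(OTHERS), "gB": set(OTHERS[:-1])})
        sig = specific_signature(tables, threshold=1.0, timepoint_rule="both")
        assert sig.up == {"gA"}

    def test_missing_comparison_pair_named(self):
        tables = _tables({})
        dropped = [t for t in tables if not (t.focal == "TC10" and t.other == "PAC")]
        with pytest.raises(ValueError, match="TC10.*PAC"):
            specific_signature(dropped, 1.0)

    def test_noiseless_recovery_equals_truth(self):
        matrix, ann, meta, truth = generate_dataset(small_config())
        gm = group_means(matrix, meta)
        others = [g for g in gm.groups if not g.startswith("TC")]
        tables = pairwise_fold_tables(gm, ["TC5", "TC10"], others)
        sig = specific_signature(tables, 1.0, "both")
        assert sig.up == truth.up_genes
        assert sig.down == truth.down_genes

    def test_single_timepoint_planting_separates_rules(self):
        cfg = small_config(planted_timepoints=("5",))
        matrix, ann, meta, truth = generate_dataset(cfg)
        gm = group_means(matrix, meta)
        others = [g for g in gm.groups if not g.startswith("TC")]
        tables = pairwise_fold_tables(gm, ["TC5", "TC10"], others)
        either = specific_signature(tables, 1.0, "either")
        both = specific_signature(tables, 1.0, "both")
        assert either.up == truth.up_genes
        assert both.up == frozenset()

    def test_threshold_monotonicity_and_infinite_threshold(self):
        matrix, ann, meta, truth = generate_dataset(
            small_config(noise_sigma=0.3, effect_ratio=4.0))
        gm = group_means(matrix, meta)
        others = [g for g in gm.groups if not g.startswith("TC")]
        tables = pairwise_fold_tables(gm, ["TC5", "TC10"], others)
        s1 = specific_signature(tables, 1.0)
        s2 = specific_signature(tables, 2.0)
        sinf = specific_signature(tables, float("inf"))
        assert s2.up <= s1.up and s2.down <= s1.down
        assert sinf.up == frozenset() and sinf.down == frozenset()


class TestTopK:
    def test_direct_sort(self):
        t = FoldChangeTable("TC5", "MSC",
                            pd.Series({"A": 3.0, "B": 2.0, "C": -5.0}), 1.0)
        assert top_k_genes(t, 2, "up") == ["A", "B"]
        assert top_k_genes(t, 2, "down") == ["C"]

    def test_k_larger_than_available_no_padding(self):
        t = FoldChangeTable("TC5", "MSC", pd.Series({"A": 3.0, "B": -1.0}), 1.0)
        assert top_k_genes(t, 100, "up") == ["A"]

    def test_lexicographic_tie_break(self):
        t = FoldChangeTable("TC5", "MSC",
                            pd.Series({"Fhl2": 2.0, "Capn2": 2.0, "Qsox1": 0.5}), 1.0)
        assert top_k_genes(t, 2, "up") == ["Capn2", "Fhl2"]


class TestPearsonDissimilarity:
    def test_duplicated_column_distance_zero(self, rng):
        v = rng.random((10, 2))
        m = ExpressionMatrix(pd.DataFrame(
            np.column_stack([v[:, 0], v[:, 0], v[:, 1]]),
            index=[f"g{i}" for i in range(10)], columns=["a", "b", "c"]),
            level="gene")
        d = pearson_dissimilarity(m)
        assert d.at["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_negation_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = ExpressionMatrix(pd.DataFrame(
            {"a": x, "b": 10 - x}, index=[f"g{i}" for i in range(4)]),
            scale="log2", level="gene")
        d = pearson_dissimilarity(m)
        assert d.at["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_manual_correlation_oracle(self, rng):
        v = rng.random((20, 5))
        m = ExpressionMatrix(pd.DataFrame(
            v, index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(5)]), level="gene")
        d = pearson_dissimilarity(m)
        for i in range(5):
            for j in range(5):
                x, y = v[:, i], v[:, j]
                xc, yc = x - x.mean(), y - y.mean()
                r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
                assert d.iat[i, j] == pytest.approx(1 - r, abs=1e-10)

    def test_zero_variance_column_named(self):
        m = ExpressionMatrix(pd.DataFrame(
            {"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]},
            index=["g0", "g1", "g2"]), level="gene")
        with pytest.raises(ValueError, match="flat"):
            pearson_dissimilarity(m)


class TestHierarchicalCluster:
    def test_two_leaves_single_merge(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        dend = hierarchical_cluster(d)
        assert dend.merges == [(0, 1, 0.7)]

    def test_forced_merge_order_average_linkage(self):
        d = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        dend = hierarchical_cluster(d, "average")
        assert dend.merges[0][:2] == (0, 1) and dend.merges[0][2] == 1.0
        assert dend.merges[1][2] == 10.0

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_matches_scipy_linkage_oracle(self, method, rng):
        pts = rng.random((8, 3))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = pd.DataFrame(dm, index=list("abcdefgh"), columns=list("abcdefgh"))
        dend = hierarchical_cluster(d, method)
        ref = scipy_linkage(squareform(dm, checks=False), method=method)
        np.testing.assert_allclose(sorted(dend.heights()), sorted(ref[:, 2]),
                                   atol=1e-10)
        # same clades, not just the same heights
        ours = dend.clades()
        n = 8
        members = {i: frozenset([list("abcdefgh")[i]]) for i in range(n)}
        for k, (a, b, _, _) in enumerate(ref):
            members[n + k] = members[int(a)] | members[int(b)]
        assert set(members.values()) <= ours

    def test_merge_heights_nondecreasing_average_linkage(self, rng):
        pts = rng.random((10, 4))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(10)]
        d = pd.DataFrame(dm, index=labels, columns=labels)
        h = hierarchical_cluster(d, "average").heights()
        assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))

    def test_newick_exports_all_leaves(self):
        d = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        nwk = hierarchical_cluster(d).to_newick()
        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
        depths = tree.depths()
        leaf_depths = [depths[t] for t in tree.get_terminals()]
        assert max(leaf_depths) == pytest.approx(min(leaf_depths))  # ultrametric

    def test_fewer_than_two_leaves_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="2 leaves"):
            hierarchical_cluster(d)


def test_replicates_cluster_by_cell_type_before_cross_type_merges():
    """Strong between-type effects with weak noise: every sample group's
    replicates form a clade, and the two focal timepoints join each other
    before any other type."""
    cfg = small_config(effect_ratio=4.0, noise_sigma=0.1, seed=3)
    matrix, ann, meta, truth = generate_dataset(cfg)
    gm = group_means(matrix, meta)
    others = [g for g in gm.groups if not g.startswith("TC")]
    tables = pairwise_fold_tables(gm, ["TC5", "TC10"], others)
    union = set()
    for t in tables:
        union |= set(t.folds.index[(t.folds > 1) | (t.folds < -1)])
    d = pearson_dissimilarity(matrix.to_log2(pseudocount=1.0), sorted(union))
    dend = hierarchical_cluster(d, "average")
    clades = dend.clades()
    types = meta.table["cell_type"]
    for ct in sorted(types.unique()):
        assert frozenset(types.index[types == ct]) in clades, ct
    groups = meta.groups()
    focal = frozenset(groups.index[groups.isin(["TC5", "TC10"])])
    assert focal in clades
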