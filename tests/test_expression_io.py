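"""Parsing, validation, annotation filtering, probe collapse, chromosome cuts."""

import numpy as np
import pandas as pd
import pytest

from telosig.expression_io import (
    ExpressionMatrix,
    GeneAnnotation,
    ParseError,
    collapse_probes_to_genes,
    filter_to_annotated,
    read_expression_table,
    restrict_to_chromosome,
    write_expression_table,
)
from telosig.synthetic_data import generate_dataset

from conftest import small_config


def _ann(records):
    df = pd.DataFrame(records, columns=["probe_id", "symbol", "chromosome"])
    return GeneAnnotation(df.set_index("probe_id"))


def test_plain_tsv_parse(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("id\ts1\ts2\npA\t1\t2\npB\t3\t4\npC\t5\t6\n")
    m = read_expression_table(p)
    assert m.values.shape == (3, 2)
    assert list(m.values.columns) == ["s1", "s2"]
    assert m.values.at["pB", "s2"] == 4


def test_duplicate_probe_row_names_probe(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("id\ts1\npA\t1\npA\t2\n")
    with pytest.raises(ParseError, match="pA"):
        read_expression_table(p)


def test_negative_linear_value_rejected(tmp_path):
    p = tmp_path / "neg.tsv"
    p.write_text("id\ts1\npA\t-3\n")
    with pytest.raises(ParseError, match="negative"):
        read_expression_table(p)


def test_geo_series_matrix_round_trip(tmp_path):
    """A synthetic series-matrix fixture reads back to the in-memory table."""
    df = pd.DataFrame({"GSM1": [1.5, 2.0, 3.25], "GSM2": [0.5, 4.0, 9.0]},
                      index=pd.Index(["p1", "p2", "p3"], name="ID_REF"))
    lines = ["!Series_title\t\"synthetic fixture\"",
             "!Series_platform_id\t\"GPL0000\"",
             "!series_matrix_table_begin",
             "\t".join(['"ID_REF"', '"GSM1"', '"GSM2"'])]
    for rid, row in df.iterrows():
        lines.append("\t".join([f'"{rid}"'] + [str(v) for v in row]))
    lines += ["!series_matrix_table_end", "!Series_end\t\"x\""]
    p = tmp_path / "fixture_series_matrix.txt"
    p.write_text("\n".join(lines) + "\n")
    m = read_expression_table(p, dialect="geo_series_matrix")
    pd.testing.assert_frame_equal(m.values, df, check_names=False)


def test_geo_series_matrix_missing_markers(tmp_path):
    p = tmp_path / "broken.txt"
    p.write_text("!Series_title\t\"x\"\nID\tGSM1\np1\t2\n")
    with pytest.raises(ParseError, match="series_matrix_table"):
        read_expression_table(p, dialect="geo_series_matrix")


def test_filter_to_annotated_counts_and_idempotence():
    m = ExpressionMatrix(pd.DataFrame(
        np.arange(10).reshape(5, 2) + 1.0,
        index=[f"p{i}" for i in range(5)], columns=["s1", "s2"]))
    ann = _ann([("p0", "GA", "1"), ("p1", "", "1"), ("p2", "GB", "2"),
                ("p3", "", ""), ("p4", "GC", "3")])
    out = filter_to_annotated(m, ann)
    assert list(out.values.index) == ["p0", "p2", "p4"]
    again = filter_to_annotated(out, ann)
    pd.testing.assert_frame_equal(again.values, out.values)


def test_filter_all_annotated_is_identity():
    m = ExpressionMatrix(pd.DataFrame([[1.0], [2.0]], index=["a", "b"],
                                      columns=["s"]))
    ann = _ann([("a", "GA", "1"), ("b", "GB", "1")])
    pd.testing.assert_frame_equal(filter_to_annotated(m, ann).values, m.values)


def test_filter_known_annotated_fraction(tmp_path, rng):
    """1,000 probes with 800 annotated (independent scan of the written
    annotation file) leave exactly 800 rows."""
    probes = [f"p{i:04d}" for i in range(1000)]
    symbols = [f"G{i:04d}" if rng.random() < 0.8 else "" for i in range(1000)]
    ann_df = pd.DataFrame({"probe_id": probes, "symbol": symbols,
                           "chromosome": "1"}).set_index("probe_id")
    path = tmp_path / "ann.tsv"
    ann_df.to_csv(path, sep="\t")
    # independent scan: count non-empty symbol fields in the raw text
    expected = sum(1 for line in path.read_text().splitlines()[1:]
                   if line.split("\t")[1] != "")
    m = ExpressionMatrix(pd.DataFrame(rng.random((1000, 2)) + 0.1, index=probes,
                                      columns=["s1", "s2"]))
    out = filter_to_annotated(m, GeneAnnotation(ann_df))
    assert out.n_rows == expected


def test_collapse_mean_singleton_and_average():
    m = ExpressionMatrix(pd.DataFrame(
        {"s1": [2.0, 4.0, 7.0]}, index=["pa1", "pa2", "pb1"]))
    ann = _ann([("pa1", "GA", "1"), ("pa2", "GA", "1"), ("pb1", "GB", "1")])
    out = collapse_probes_to_genes(m, ann, method="mean")
    assert out.level == "gene"
    assert out.values.at["GA", "s1"] == 3.0
    assert out.values.at["GB", "s1"] == 7.0  # singleton copied unchanged


def test_collapse_median_polish_matches_iterative_oracle(rng):
    """6 probes / 2 genes: collapse agrees with an explicitly coded
    row-then-column median-sweep fit on each log2 probe block."""
    vals = rng.random((6, 4)) * 100 + 1
    probes = [f"g1_p{i}" for i in range(3)] + [f"g2_p{i}" for i in range(3)]
    m = ExpressionMatrix(pd.DataFrame(vals, index=probes,
                                      columns=list("abcd")), scale="log2")
    ann = _ann([(p, p.split("_")[0], "1") for p in probes])
    out = collapse_probes_to_genes(m, ann, method="median_polish")

    def oracle_polish(block):
        resid = block.copy()
        row_eff = np.zeros(resid.shape[0])
        col_eff = np.zeros(resid.shape[1])
        overall = 0.0
        for _ in range(100):
            deltas = []
            rmed = np.array([np.median(resid[i]) for i in range(resid.shape[0])])
            for i in range(resid.shape[0]):
                resid[i] -= rmed[i]
            row_eff += rmed
            t = np.median(col_eff); col_eff -= t; overall += t
            cmed = np.array([np.median(resid[:, j]) for j in range(resid.shape[1])])
            for j in range(resid.shape[1]):
                resid[:, j] -= cmed[j]
            col_eff += cmed
            t = np.median(row_eff); row_eff -= t; overall += t
            if max(np.abs(rmed).max(), np.abs(cmed).max()) < 1e-8:
                break
        return overall + col_eff

    for gene, rows in (("g1", slice(0, 3)), ("g2", slice(3, 6))):
        expected = oracle_polish(vals[rows].copy())
        np.testing.assert_allclose(out.values.loc[gene].to_numpy(), expected,
                                   atol=1e-8)


def test_collapse_mean_preserves_groupwise_totals(rng):
    vals = rng.random((9, 3)) + 0.5
    probes = [f"g{i % 3}_p{i}" for i in range(9)]
    m = ExpressionMatrix(pd.DataFrame(vals, index=probes, columns=list("xyz")))
    ann = _ann([(p, p.split("_")[0], "1") for p in probes])
    out = collapse_probes_to_genes(m, ann, method="mean")
    # direct computation: sum over genes of the mean of their probes
    for j, col in enumerate("xyz"):
        direct = sum(vals[[i for i, p in enumerate(probes)
                           if p.startswith(g)], j].mean() for g in ("g0", "g1", "g2"))
        assert out.values[col].sum() == pytest.approx(direct, rel=1e-12)


def test_restrict_to_chromosome_counts_and_subset():
    genes = [f"G{i}" for i in range(100)]
    ann = _ann([(g, g, "1" if i < 10 else "2") for i, g in enumerate(genes)])
    m = ExpressionMatrix(pd.DataFrame(np.ones((100, 2)), index=genes,
                                      columns=["s1", "s2"]), level="gene")
    out = restrict_to_chromosome(m, ann, "1")
    assert out.n_rows == 10
    assert set(out.values.index) <= set(m.values.index)


def test_restrict_unknown_chromosome_lists_available():
    ann = _ann([("G1", "G1", "1"), ("G2", "G2", "X")])
    m = ExpressionMatrix(pd.DataFrame([[1.0], [2.0]], index=["G1", "G2"],
                                      columns=["s"]), level="gene")
    with pytest.raises(ValueError, match="available"):
        restrict_to_chromosome(m, ann, "7")


def test_restrict_present_label_zero_genes_gives_empty():
    ann = _ann([("G1", "G1", "1"), ("G2", "", "2")])
    m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["G1"], columns=["s"]),
                         level="gene")
    out = restrict_to_chromosome(m, ann, "2")
    assert out.n_rows == 0


def test_restrict_matches_generator_focal_count():
    cfg = small_config()
    matrix, ann, meta, truth = generate_dataset(cfg)
    out = restrict_to_chromosome(matrix, ann, cfg.focal_chromosome)
    assert out.n_rows == cfg.n_focal_chrom_genes


def test_write_read_round_trip(tmp_path, tiny_dataset):
    matrix = tiny_dataset[0]
    p = tmp_path / "out.tsv"
    write_expression_table(matrix, p)
    back = read_expression_table(p, level="gene")
    pd.testing.assert_frame_equal(back.values, matrix.values, check_names=False)
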