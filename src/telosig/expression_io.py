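"""Reading, validation, filtering and probe→gene collapse of expression matrices.

The pipeline's central container is :class:`ExpressionMatrix`: a genes/probes ×
samples table of abundances carrying two flags — the measurement *scale*
(``linear`` intensities ≥ 0, or real-valued ``log2``) and the row *level*
(``probe`` or ``gene``). Two sidecar tables accompany it: a
:class:`GeneAnnotation` mapping probe ids to official gene symbols and
chromosome labels, and :class:`SampleMetadata` mapping sample ids to cell type,
timepoint and source dataset.

Supported on-disk dialects are plain TSV (header row of sample ids, first
column the row id) and the GEO series-matrix text format (the tab-separated
block between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``,
with ``!``-prefixed header/footer lines ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["linear", "log2"]
Level = Literal["probe", "gene"]

ANNOTATION_COLUMNS = ("probe_id", "symbol", "chromosome")
METADATA_COLUMNS = ("sample_id", "cell_type", "timepoint", "dataset")


class ParseError(ValueError):
    """A table failed structural validation; message carries the offending line."""


@dataclass
class ExpressionMatrix:
    """Genes/probes × samples abundance table.

    Parameters
    ----------
    values
        DataFrame with unique row ids (probes or symbols) and unique column
        ids (sample ids). Linear-scale values must be non-negative; no
        missing values are permitted.
    scale
        ``"linear"`` or ``"log2"``.
    level
        ``"probe"`` or ``"gene"``.
    """

    values: pd.DataFrame
    scale: Scale = "linear"
    level: Level = "probe"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ParseError(f"duplicate row id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        if v.isna().any().any():
            bad = v.columns[v.isna().any()][0]
            raise ParseError(f"missing values in sample {bad!r}")
        if self.scale == "linear" and (v.to_numpy() < 0).any():
            row = v.index[(v < 0).any(axis=1)][0]
            raise ParseError(f"negative linear intensity in row {row!r}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + pseudocount), scale="log2",
                                level=self.level)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values), scale="linear", level=self.level)

    def subset_rows(self, rows: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(rows)])


@dataclass
class GeneAnnotation:
    """Probe id → (official symbol or None, chromosome label or None).

    Stored as a DataFrame indexed by probe id with columns ``symbol`` and
    ``chromosome``; empty strings are normalized to missing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ParseError(f"duplicate annotation record for probe {dup!r}")
        for col in ("symbol", "chromosome"):
            if col not in t.columns:
                raise ParseError(f"annotation table lacks column {col!r}")
        with pd.option_context("future.no_silent_downcasting", True):
            self.table = t.replace("", np.nan)

    def symbol_of(self, probe: str) -> str | None:
        s = self.table.at[probe, "symbol"]
        return None if pd.isna(s) else str(s)

    def annotated_probes(self) -> pd.Index:
        """Probes carrying a non-empty official symbol."""
        return self.table.index[self.table["symbol"].notna()]

    def chromosomes(self) -> set[str]:
        return set(self.table["chromosome"].dropna().astype(str))

    def symbols_on_chromosome(self, chromosome: str) -> set[str]:
        t = self.table
        mask = t["chromosome"].astype("string") == str(chromosome)
        return set(t.loc[mask, "symbol"].dropna().astype(str))


@dataclass
class SampleMetadata:
    """Sample id → (cell type, timepoint or None, source dataset).

    ``group`` labels concatenate cell type and timepoint (``TC`` at timepoint
    ``5`` → ``TC5``); samples without a timepoint use the bare cell type.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ParseError(f"duplicate metadata record for sample {dup!r}")
        for col in ("cell_type", "timepoint", "dataset"):
            if col not in t.columns:
                raise ParseError(f"metadata table lacks column {col!r}")
        with pd.option_context("future.no_silent_downcasting", True):
            self.table = t.replace("", np.nan)

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = matrix.values.columns.difference(self.table.index)
        if len(missing):
            raise ParseError(f"samples without metadata: {list(missing)}")

    def groups(self) -> pd.Series:
        """Sample id → group label (cell type + timepoint)."""
        t = self.table
        tp = t["timepoint"]
        labels = t["cell_type"].astype(str).where(
            tp.isna(), t["cell_type"].astype(str) + tp.astype("string").fillna(""))
        return labels.rename("group")

    def datasets(self) -> pd.Series:
        return self.table["dataset"].astype(str).rename("dataset")

    def samples_in_dataset(self, dataset: str) -> list[str]:
        return list(self.table.index[self.table["dataset"].astype(str) == str(dataset)])


def _read_plain_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    """Parse the table block of a GEO series-matrix file.

    Lines beginning with ``!`` outside the block are metadata and skipped;
    values and ids may be double-quoted.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ParseError(f"{path}: missing series_matrix_table_begin/end markers")
    block = lines[start + 1:end]
    if not block:
        raise ParseError(f"{path}: empty series-matrix table (line {start + 1})")
    rows = [[f.strip('"') for f in l.split("\t")] for l in block if l.strip()]
    header = rows[0]
    body = rows[1:]
    for off, r in enumerate(body):
        if len(r) != len(header):
            raise ParseError(
                f"{path}: line {start + 2 + off + 1}: expected {len(header)} fields, "
                f"got {len(r)}")
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    return df


def read_expression_table(path: str | Path,
                          dialect: Literal["plain_tsv", "geo_series_matrix"] = "plain_tsv",
                          scale: Scale = "linear",
                          level: Level = "probe") -> ExpressionMatrix:
    """Read an expression table and validate it.

    Raises :class:`ParseError` for malformed tables, duplicate row/sample ids
    or negative linear intensities; the message names the offending id.
    """
    path = Path(path)
    if dialect == "plain_tsv":
        df = _read_plain_tsv(path)
    elif dialect == "geo_series_matrix":
        df = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExpressionMatrix(df, scale=scale, level=level)


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:3]) != list(ANNOTATION_COLUMNS):
        raise ParseError(
            f"annotation must have columns {ANNOTATION_COLUMNS}, got {list(df.columns)}")
    return GeneAnnotation(df.set_index("probe_id"))


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:4]) != list(METADATA_COLUMNS):
        raise ParseError(
            f"metadata must have columns {METADATA_COLUMNS}, got {list(df.columns)}")
    return SampleMetadata(df.set_index("sample_id"))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="id")


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.fillna("").to_csv(path, sep="\t", index_label="probe_id")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.fillna("").to_csv(path, sep="\t", index_label="sample_id")


def filter_to_annotated(matrix: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Drop probe rows whose annotation lacks an official symbol.

    The first filter of the analysis: probes without a symbol cannot enter any
    gene-level comparison. Row order is preserved; an empty result is allowed
    (logged, not an error).
    """
    if matrix.level != "probe":
        raise ValueError("filter_to_annotated expects a probe-level matrix")
    annotated = ann.annotated_probes()
    keep = matrix.values.index[matrix.values.index.isin(annotated)]
    if len(keep) == 0:
        logger.warning("filter_to_annotated: no annotated probes remain")
    logger.info("filter_to_annotated: %d/%d probes retained", len(keep), matrix.n_rows)
    return replace(matrix, values=matrix.values.loc[keep])


def collapse_probes_to_genes(matrix: ExpressionMatrix, ann: GeneAnnotation,
                             method: Literal["mean", "median_polish"] = "mean"
                             ) -> ExpressionMatrix:
    """Collapse a many-probes-per-gene matrix to one row per official symbol.

    ``mean`` averages probe rows per symbol on the input scale.
    ``median_polish`` summarizes each symbol's probe block on log2 scale with
    the robust additive fit of :func:`telosig.normalization.median_polish_summarize`
    and converts back to the input scale. Output rows follow the first
    occurrence order of each symbol.
    """
    if matrix.level != "probe":
        raise ValueError("collapse_probes_to_genes expects a probe-level matrix")
    symbols = pd.Series(
        [ann.symbol_of(p) for p in matrix.values.index], index=matrix.values.index)
    if symbols.isna().any():
        bad = symbols.index[symbols.isna()][0]
        raise ValueError(f"unannotated probe {bad!r}: run filter_to_annotated first")
    if method == "mean":
        collapsed = matrix.values.groupby(symbols, sort=False).mean()
    elif method == "median_polish":
        from .normalization import median_polish_summarize
        log2m = matrix.to_log2(pseudocount=1.0 if matrix.scale == "linear" else 0.0)
        rows = {}
        for sym, block in log2m.values.groupby(symbols, sort=False):
            rows[sym] = median_polish_summarize(block)
        collapsed = pd.DataFrame(rows).T
        collapsed.columns = matrix.values.columns
        if matrix.scale == "linear":
            collapsed = np.exp2(collapsed) - 1.0
            collapsed = collapsed.clip(lower=0.0)
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed, scale=matrix.scale, level="gene")


def restrict_to_chromosome(matrix: ExpressionMatrix, ann: GeneAnnotation,
                           chromosome: str) -> ExpressionMatrix:
    """Keep only the gene rows annotated to ``chromosome`` (order preserved).

    Chromosome labels are opaque strings; an unknown label raises with the
    available labels listed. A present label with zero matching rows yields an
    empty matrix with a warning.
    """
    if matrix.level != "gene":
        raise ValueError("restrict_to_chromosome expects a gene-level matrix")
    available = ann.chromosomes()
    if str(chromosome) not in available:
        raise ValueError(
            f"chromosome {chromosome!r} absent from annotation; "
            f"available: {sorted(available)}")
    wanted = ann.symbols_on_chromosome(chromosome)
    keep = matrix.values.index[matrix.values.index.isin(wanted)]
    if len(keep) == 0:
        logger.warning("restrict_to_chromosome: no genes on chromosome %s", chromosome)
    logger.info("restrict_to_chromosome(%s): %d/%d genes retained",
                chromosome, len(keep), matrix.n_rows)
    return replace(matrix, values=matrix.values.loc[keep])
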