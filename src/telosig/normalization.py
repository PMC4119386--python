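"""Quantile normalization, median-polish summarization, and housekeeping scaling.

Three harmonization steps used before any differential comparison:

* :func:`quantile_normalize` forces every sample column to share one empirical
  distribution (the row-wise mean of the column-sorted input) — the
  distribution-matching step of RMA-style preprocessing.
* :func:`median_polish_summarize` fits the robust additive model
  ``value ≈ overall + probe effect + sample effect`` by iterated median
  sweeps — RMA's probe-summarization step.
* :func:`housekeeping_scale` removes per-sample multiplicative (batch/platform)
  factors using a designated housekeeping gene set: with B the full matrix and
  H its housekeeping rows, the per-sample housekeeping mean Y_j is computed,
  C is the grand mean of Y over a set of reference samples whose scale is held
  fixed, the scale factor Z_j is 1 for reference samples and Y_j / C otherwise,
  and the rescaled matrix is E_ij = B_ij / Z_j. After scaling, every
  non-reference sample's housekeeping mean equals C exactly, and within-sample
  gene ratios are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata

MEDIAN_POLISH_TOL = 1e-8
MEDIAN_POLISH_MAX_ITER = 100


@dataclass
class HousekeepingSpec:
    """Housekeeping gene symbols and the reference samples whose scale is fixed."""

    housekeeping_symbols: list[str]
    reference_samples: list[str]

    def validate(self, matrix: ExpressionMatrix,
                 meta: SampleMetadata | None = None) -> None:
        if not self.housekeeping_symbols:
            raise ValueError("housekeeping symbol set is empty")
        if not self.reference_samples:
            raise ValueError("reference sample set is empty")
        for sym in self.housekeeping_symbols:
            if sym not in matrix.values.index:
                raise ValueError(f"housekeeping symbol {sym!r} absent from matrix")
        known = set(matrix.values.columns)
        if meta is not None:
            known &= set(meta.table.index)
        for s in self.reference_samples:
            if s not in known:
                raise ValueError(f"reference sample {s!r} absent from matrix/metadata")


@dataclass
class ScalingReport:
    """Audit record of housekeeping scaling: per-sample Y and Z, reference mean C."""

    table: pd.DataFrame  # columns: Y, Z, is_reference; index: sample id
    reference_mean: float

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all sample columns to the same value multiset.

    The shared multiset is the row-wise mean of the column-sorted input.
    Within a column, the k-th smallest value maps to the k-th target value;
    tied values receive the mean of the target values their ranks span, which
    makes the operation deterministic and idempotent.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    v = matrix.values.to_numpy(dtype=float)
    order = np.argsort(v, axis=0, kind="stable")
    target = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        col = v[:, j]
        ranked = np.empty(n)
        ranked[order[:, j]] = target
        # average target values over each tie block
        sorted_col = col[order[:, j]]
        block_start = 0
        for i in range(1, n + 1):
            if i == n or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    ranked[order[block_start:i, j]] = target[block_start:i].mean()
                block_start = i
        out[:, j] = ranked
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, scale=matrix.scale, level=matrix.level)


def median_polish_summarize(block: pd.DataFrame,
                            tol: float = MEDIAN_POLISH_TOL,
                            max_iter: int = MEDIAN_POLISH_MAX_ITER) -> pd.Series:
    """Summarize one gene's log2 probe block into a per-sample gene row.

    Fits ``value ≈ overall + probe + sample`` by Tukey median polish: each
    iteration sweeps probe (row) medians into the probe effects, then sample
    (column) medians into the sample effects, re-centering each effect vector
    by its median into the overall term. Iteration stops when the largest
    absolute median removed in a full sweep drops below ``tol`` or after
    ``max_iter`` sweeps. Returns ``overall + sample effect`` per sample.
    """
    vals = np.asarray(block, dtype=float)
    if vals.ndim != 2 or vals.size == 0:
        raise ValueError("median polish needs a non-empty 2-D probe block")
    if not np.isfinite(vals).all():
        raise ValueError("median polish requires finite inputs")
    cols = block.columns
    if vals.shape[0] == 1:
        return pd.Series(vals[0], index=cols)
    resid = vals.copy()
    row_eff = np.zeros(vals.shape[0])
    col_eff = np.zeros(vals.shape[1])
    overall = 0.0
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        ce_med = np.median(col_eff)
        col_eff -= ce_med
        overall += ce_med

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        re_med = np.median(row_eff)
        row_eff -= re_med
        overall += re_med

        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return pd.Series(overall + col_eff, index=cols)


def housekeeping_scale(matrix: ExpressionMatrix, spec: HousekeepingSpec,
                       meta: SampleMetadata | None = None
                       ) -> tuple[ExpressionMatrix, ScalingReport]:
    """Rescale samples so housekeeping means agree with the reference samples.

    Computes Y_j (housekeeping mean of sample j), C (mean of Y over reference
    samples), Z_j (1 for references, Y_j / C otherwise) and E = B / Z.
    Reference columns pass through unchanged.

    Raises if the matrix is not on linear scale, if a housekeeping symbol is
    missing (named in the error), or if any Y_j is zero.
    """
    if matrix.scale != "linear":
        raise ValueError("housekeeping scaling operates on linear intensities")
    spec.validate(matrix, meta)
    hk = matrix.values.loc[spec.housekeeping_symbols]
    y = hk.mean(axis=0)
    if (y == 0).any():
        bad = y.index[y == 0][0]
        raise ValueError(f"housekeeping mean is zero for sample {bad!r}; cannot scale")
    ref = pd.Index(spec.reference_samples)
    c = float(y.loc[ref].mean())
    z = y / c
    z.loc[ref] = 1.0
    scaled = matrix.values / z
    report = ScalingReport(
        table=pd.DataFrame({
            "Y": y, "Z": z,
            "is_reference": matrix.values.columns.isin(ref),
        }),
        reference_mean=c,
    )
    out = ExpressionMatrix(scaled, scale="linear", level=matrix.level)
    return out, report
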