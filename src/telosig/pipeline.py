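"""End-to-end orchestration: simulate/ingest → normalize → folds → signature →
cluster → enrich → export, from a single configuration.

The default stage order is: ingest (or simulate), probe filtering and collapse
(when the input is probe-level), quantile normalization within each source
dataset, housekeeping scaling across datasets, restriction to the focal
chromosome, per-group means, pairwise fold tables, threshold count grid,
specific signature, sample clustering over the union of differential genes,
optional gene-set enrichment, co-expression network, and exports. Every
ambiguous analysis choice (fold formula variant, timepoint rule, top-k,
linkage, thresholds) is a named configuration key. Identical configuration and
seed yield byte-identical outputs; the run manifest records the stage order,
output paths, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_THRESHOLDS,
    group_means,
    pairwise_fold_tables,
    threshold_counts,
)
from .enrichment_network import (
    coexpression_network,
    export_string_query,
    hypergeometric_enrichment,
    read_gmt,
    write_network,
)
from .expression_io import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    collapse_probes_to_genes,
    filter_to_annotated,
    read_annotation,
    read_expression_table,
    read_metadata,
    restrict_to_chromosome,
    write_expression_table,
)
from .normalization import HousekeepingSpec, housekeeping_scale, quantile_normalize
from .signature_cluster import (
    hierarchical_cluster,
    pearson_dissimilarity,
    specific_signature,
    top_k_genes,
    write_newick,
)
from .synthetic_data import SyntheticConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "ingest", "probe_filter", "collapse", "quantile_normalize",
    "housekeeping_scale", "restrict_chromosome", "group_means", "fold_tables",
    "threshold_counts", "signature", "cluster", "enrichment", "network", "export",
)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    # input: either a synthetic generator config or three table paths
    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    expression_dialect: str = "plain_tsv"
    expression_scale: str = "linear"
    expression_level: str = "gene"

    focal_cell_type: str = "TC"
    focal_timepoints: tuple[str, ...] = ("5", "10")
    other_cell_types: tuple[str, ...] | None = None  # None: all non-focal types
    chromosome: str = "1"

    housekeeping_symbols: tuple[str, ...] | None = None  # None: from truth (synthetic)
    reference_dataset: str = "own"
    apply_quantile_normalization: bool = True
    apply_housekeeping_scaling: bool = True

    pseudocount: float = DEFAULT_PSEUDOCOUNT
    fold_formula: str = "symmetric"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    timepoint_rule: str = "both"
    top_k: int = 100
    collapse_method: str = "mean"
    linkage: str = "average"
    r_threshold: float = 0.8
    gene_sets_path: str | None = None

    outdir: str = "telosig_out"
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and not (
                self.expression_path and self.annotation_path and self.metadata_path):
            raise PipelineError(
                "config: provide either a synthetic section or all three input paths")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise PipelineError("config: thresholds must be strictly increasing")
        if self.other_cell_types is not None:
            if self.focal_cell_type in self.other_cell_types:
                raise PipelineError(
                    "config: focal and other cell-type sets must be disjoint")
        if self.timepoint_rule not in ("both", "either"):
            raise PipelineError(f"config: unknown timepoint rule {self.timepoint_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if syn is not None:
            syn = {k: _tuplify(v) for k, v in syn.items()}
            cfg.synthetic = SyntheticConfig(**syn)
            if "seed" not in syn:
                cfg.synthetic.seed = cfg.seed
        return cfg


def _tuplify(v: Any) -> Any:
    return tuple(v) if isinstance(v, list) else v


@dataclass
class RunManifest:
    """Record of one pipeline run: outputs, dimensions, seed, stage order."""

    outputs: dict[str, str]
    stage_order: list[str]
    stage_dims: dict[str, str]
    seed: int
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    dims: dict[str, str] = {}

    def record(stage: str, matrix: ExpressionMatrix) -> None:
        dims[stage] = f"{matrix.n_rows} x {matrix.n_samples}"
        logger.info("%s: %s", stage, dims[stage])

    # --- ingest -----------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        matrix, ann, meta, truth = _simulate(config)
        outputs.update(write_dataset(outdir / "synthetic", matrix, ann, meta, truth))
    else:
        matrix, ann, meta = _ingest(config)
    record("ingest", matrix)
    meta.check_covers(matrix)

    # --- probe handling ---------------------------------------------------
    if matrix.level == "probe":
        matrix = _run_filter(matrix, ann)
        record("probe_filter", matrix)
        matrix = _run_collapse(matrix, ann, config.collapse_method)
        record("collapse", matrix)

    # --- normalization ----------------------------------------------------
    if config.apply_quantile_normalization:
        matrix = _run_qn_within_datasets(matrix, meta)
        record("quantile_normalize", matrix)

    if config.apply_housekeeping_scaling:
        matrix, report = _run_housekeeping(matrix, meta, config, truth)
        report_path = outdir / "scaling_report.tsv"
        report.write(report_path)
        outputs["scaling_report"] = str(report_path)
        record("housekeeping_scale", matrix)

    full_matrix = matrix  # pre-restriction matrix kept for the network stage

    # --- chromosome restriction & folds ------------------------------------
    matrix = _run_restrict(matrix, ann, config.chromosome)
    record("restrict_chromosome", matrix)

    gm = _run_group_means(matrix, meta)
    focal_groups = [f"{config.focal_cell_type}{tp}" for tp in config.focal_timepoints]
    if config.other_cell_types is not None:
        other_groups = list(config.other_cell_types)
    else:
        other_groups = [g for g in gm.groups if g not in focal_groups]
    tables = _run_folds(gm, focal_groups, other_groups, config)

    counts = _run_counts(tables, config.thresholds)
    counts_path = outdir / "threshold_counts.tsv"
    counts.write(counts_path)
    outputs["threshold_counts"] = str(counts_path)

    signature = _run_signature(tables, config)
    sig_path = outdir / "signature.tsv"
    signature.write(sig_path)
    outputs["signature"] = str(sig_path)

    topk_path = outdir / "top_k.tsv"
    _write_topk(tables, config.top_k, topk_path)
    outputs["top_k"] = str(topk_path)

    # --- clustering over the union of differential genes -------------------
    t0 = min(config.thresholds)
    union: set[str] = set()
    for tb in tables:
        union |= set(tb.folds.index[tb.up_mask(t0) | tb.down_mask(t0)])
    if len(union) >= 2:
        dend = _run_cluster(matrix, sorted(union), config.linkage)
        newick_path = outdir / "dendrogram.nwk"
        write_newick(dend, newick_path)
        outputs["dendrogram"] = str(newick_path)
        dims["cluster"] = f"{len(union)} genes x {matrix.n_samples} samples"
    else:
        logger.warning("cluster: fewer than 2 differential genes; skipped")

    # --- enrichment & network ----------------------------------------------
    if config.gene_sets_path and signature.genes:
        gsc = read_gmt(config.gene_sets_path, universe=list(matrix.values.index))
        enr = _run_enrichment(signature, gsc)
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index_label="set")
        outputs["enrichment"] = str(enr_path)

    if len(signature.genes) >= 2:
        net = _run_network(full_matrix, sorted(signature.genes), config.r_threshold)
        edge_path = outdir / "coexpression_edges.tsv"
        graphml_path = outdir / "coexpression.graphml"
        write_network(net, edge_path, graphml_path)
        outputs["coexpression_edges"] = str(edge_path)
        outputs["coexpression_graphml"] = str(graphml_path)

    if signature.genes:
        string_path = outdir / "string_query.txt"
        export_string_query(signature, string_path)
        outputs["string_query"] = str(string_path)

    norm_path = outdir / "normalized_expression.tsv"
    write_expression_table(full_matrix, norm_path)
    outputs["normalized_expression"] = str(norm_path)

    manifest = RunManifest(outputs=outputs, stage_order=list(STAGE_ORDER),
                           stage_dims=dims, seed=config.seed)
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


# --- stage wrappers (error context) ---------------------------------------

@_stage("simulate")
def _simulate(config: PipelineConfig):
    return generate_dataset(config.synthetic)


@_stage("ingest")
def _ingest(config: PipelineConfig):
    matrix = read_expression_table(config.expression_path,
                                   dialect=config.expression_dialect,
                                   scale=config.expression_scale,
                                   level=config.expression_level)
    ann = read_annotation(config.annotation_path)
    meta = read_metadata(config.metadata_path)
    return matrix, ann, meta


@_stage("probe_filter")
def _run_filter(matrix, ann):
    return filter_to_annotated(matrix, ann)


@_stage("collapse")
def _run_collapse(matrix, ann, method):
    return collapse_probes_to_genes(matrix, ann, method=method)


@_stage("quantile_normalize")
def _run_qn_within_datasets(matrix: ExpressionMatrix, meta: SampleMetadata
                            ) -> ExpressionMatrix:
    """Quantile-normalize each source dataset's columns jointly."""
    datasets = meta.datasets().loc[matrix.values.columns]
    pieces = []
    for ds in dict.fromkeys(datasets):  # preserve column order of first appearance
        cols = list(datasets.index[datasets == ds])
        block = ExpressionMatrix(matrix.values[cols], scale=matrix.scale,
                                 level=matrix.level)
        if block.n_samples < 2:
            logger.warning("quantile_normalize: dataset %s has a single sample; "
                           "left unchanged", ds)
            pieces.append(block.values)
        else:
            pieces.append(quantile_normalize(block).values)
    merged = pd.concat(pieces, axis=1)[matrix.values.columns]
    return ExpressionMatrix(merged, scale=matrix.scale, level=matrix.level)


@_stage("housekeeping_scale")
def _run_housekeeping(matrix, meta, config: PipelineConfig, truth):
    if config.housekeeping_symbols is not None:
        hk = list(config.housekeeping_symbols)
    elif truth is not None:
        hk = sorted(truth.housekeeping_genes)
    else:
        raise ValueError("housekeeping_symbols must be set for non-synthetic input")
    refs = meta.samples_in_dataset(config.reference_dataset)
    spec = HousekeepingSpec(housekeeping_symbols=hk, reference_samples=refs)
    return housekeeping_scale(matrix, spec, meta)


@_stage("restrict_chromosome")
def _run_restrict(matrix, ann, chromosome):
    return restrict_to_chromosome(matrix, ann, chromosome)


@_stage("group_means")
def _run_group_means(matrix, meta):
    return group_means(matrix, meta)


@_stage("fold_tables")
def _run_folds(gm, focal_groups, other_groups, config: PipelineConfig):
    return pairwise_fold_tables(gm, focal_groups, other_groups,
                                pseudocount=config.pseudocount,
                                formula=config.fold_formula)


@_stage("threshold_counts")
def _run_counts(tables, thresholds):
    return threshold_counts(tables, thresholds)


@_stage("signature")
def _run_signature(tables, config: PipelineConfig):
    return specific_signature(tables, threshold=min(config.thresholds),
                              timepoint_rule=config.timepoint_rule)


@_stage("cluster")
def _run_cluster(matrix: ExpressionMatrix, genes, linkage):
    log2m = matrix.to_log2(pseudocount=1.0 if matrix.scale == "linear" else 0.0)
    d = pearson_dissimilarity(log2m, genes)
    return hierarchical_cluster(d, linkage=linkage)


@_stage("enrichment")
def _run_enrichment(signature, gsc):
    return hypergeometric_enrichment(signature, gsc)


@_stage("network")
def _run_network(matrix, genes, r_threshold):
    return coexpression_network(matrix, genes, r_threshold)


def _write_topk(tables, k, path) -> None:
    rows = []
    for tb in tables:
        for direction in ("up", "down"):
            for rank, sym in enumerate(top_k_genes(tb, k, direction), start=1):
                rows.append({"comparison": tb.label, "direction": direction,
                             "rank": rank, "symbol": sym})
    pd.DataFrame(rows, columns=["comparison", "direction", "rank", "symbol"]).to_csv(
        path, sep="\t", index=False)
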