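"""Synthetic multi-cell-type expression datasets with planted signatures.

The generator emulates the statistical structure of a merged microarray
collection spanning eight cell types: a focal cell type observed at two
culture timepoints (nine sample groups in total) plus seven comparison types,
with sample groups spread over several source datasets that differ by a
multiplicative batch scale. Against a log-normal baseline it plants:

* ``n_planted_up`` / ``n_planted_down`` focal-type-specific genes on the focal
  chromosome, up- or down-regulated by ``effect_ratio`` in both focal
  timepoints (or a configurable subset of them);
* ``n_marker_genes_per_type`` marker genes per non-focal cell type, also on
  the focal chromosome, up-regulated by ``effect_ratio`` in that type only, so
  that every cell type has a distinguishable focal-chromosome profile;
* ``n_housekeeping`` housekeeping genes on background chromosomes whose true
  mean is identical across all groups — the anchor for cross-dataset scaling.

Observed intensities are ``true mean × batch scale × 2^N(0, noise_sigma²)``,
reproducible from ``seed``. The ground truth needed by recovery tests is
returned as a :class:`PlantedTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    write_annotation,
    write_expression_table,
    write_metadata,
)

DEFAULT_CELL_TYPES = ("TC", "MSC", "Fb", "ATII", "ABC", "PAC", "T-BL", "T-LL")

# Source-dataset layout mirroring a merged collection: the focal platform
# carries the focal type and the two stromal types; three public series carry
# the epithelial and lymphocyte types.
DEFAULT_DATASET_OF_TYPE = {
    "TC": "own", "MSC": "own", "Fb": "own",
    "ATII": "GSE6846",
    "T-BL": "GSE27379", "T-LL": "GSE27379",
    "ABC": "GSE28651", "PAC": "GSE28651",
}


class ConfigError(ValueError):
    """A synthetic configuration violates one of its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the planted-signature generator.

    Defaults reproduce the scale of the study design this generator emulates:
    645 genes on the focal chromosome among 10,000 background genes, 14 planted
    up- and 39 planted down-regulated focal genes, eight cell types with the
    focal type sampled at timepoints 5 and 10 days, three replicates per
    sample group.
    """

    n_background_genes: int = 10_000
    n_focal_chrom_genes: int = 645
    focal_chromosome: str = "1"
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    focal_cell_type: str = "TC"
    focal_timepoints: tuple[str, ...] = ("5", "10")
    replicates_per_sample_group: int = 3
    n_housekeeping: int = 20
    n_planted_up: int = 14
    n_planted_down: int = 39
    n_marker_genes_per_type: int = 30
    effect_ratio: float = 3.0
    noise_sigma: float = 0.2
    batch_scales: dict[str, float] = field(default_factory=dict)
    dataset_of_type: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DATASET_OF_TYPE))
    # timepoints in which planted effects are active; restricting to one
    # timepoint exercises the both/either intersection rule downstream
    planted_timepoints: tuple[str, ...] = ("5", "10")
    probes_per_gene: int = 1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_up + self.n_planted_down > self.n_focal_chrom_genes:
            raise ConfigError(
                "invariant violated: n_planted_up + n_planted_down must be "
                "<= n_focal_chrom_genes")
        n_marker_total = self.n_marker_genes_per_type * (len(self.cell_types) - 1)
        if (self.n_planted_up + self.n_planted_down + n_marker_total
                > self.n_focal_chrom_genes):
            raise ConfigError(
                "invariant violated: planted + per-type marker genes exceed "
                "n_focal_chrom_genes")
        if self.focal_cell_type not in self.cell_types:
            raise ConfigError("invariant violated: focal cell type must be one of "
                              "cell_types (exactly one focal type)")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigError("invariant violated: cell_types must be unique")
        if len(self.focal_timepoints) != 2:
            raise ConfigError("invariant violated: the focal type contributes exactly "
                              "two timepoint sample groups")
        if not set(self.planted_timepoints) <= set(self.focal_timepoints):
            raise ConfigError("invariant violated: planted_timepoints must be a subset "
                              "of focal_timepoints")
        if self.effect_ratio <= 1:
            raise ConfigError("invariant violated: effect_ratio must be > 1")
        if self.noise_sigma < 0:
            raise ConfigError("invariant violated: noise_sigma must be >= 0")
        if any(s <= 0 for s in self.batch_scales.values()):
            raise ConfigError("invariant violated: batch scales must be > 0")
        if self.n_housekeeping < 1 or self.n_housekeeping > self.n_background_genes:
            raise ConfigError("invariant violated: n_housekeeping must be in "
                              "[1, n_background_genes]")
        for ct in self.cell_types:
            if ct not in self.dataset_of_type:
                raise ConfigError(f"invariant violated: cell type {ct!r} has no "
                                  "dataset assignment")
        if self.replicates_per_sample_group < 1 or self.probes_per_gene < 1:
            raise ConfigError("invariant violated: replicates_per_sample_group and "
                              "probes_per_gene must be >= 1")

    @property
    def group_labels(self) -> list[str]:
        labels = [f"{self.focal_cell_type}{tp}" for tp in self.focal_timepoints]
        labels += [ct for ct in self.cell_types if ct != self.focal_cell_type]
        return labels


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset, for recovery tests.

    ``group_means`` are the true per-group linear means *before* batch scaling
    and noise; ``batch`` maps each sample to its source dataset and scale.
    """

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    housekeeping_genes: frozenset[str]
    marker_genes: dict[str, frozenset[str]]
    group_means: pd.DataFrame
    batch: pd.DataFrame  # index: sample id; columns: dataset, scale

    def write(self, path: str | Path) -> None:
        payload = {
            "up_genes": sorted(self.up_genes),
            "down_genes": sorted(self.down_genes),
            "housekeeping_genes": sorted(self.housekeeping_genes),
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "batch": {s: {"dataset": r["dataset"], "scale": float(r["scale"])}
                      for s, r in self.batch.iterrows()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    focal = [f"C{config.focal_chromosome}g{i:04d}"
             for i in range(1, config.n_focal_chrom_genes + 1)]
    n_bg = config.n_background_genes
    hk = [f"Hk{i:03d}" for i in range(1, config.n_housekeeping + 1)]
    bg = hk + [f"Bg{i:05d}" for i in range(1, n_bg - config.n_housekeeping + 1)]
    return focal, bg


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[ExpressionMatrix, GeneAnnotation, SampleMetadata,
                                PlantedTruth]:
    """Generate one synthetic expression dataset with its sidecars and truth.

    Planted up genes have focal-group true mean = ``effect_ratio`` × the
    other-group mean in every planted timepoint; planted down genes the
    reciprocal; housekeeping genes share one mean across all groups before
    batch scaling. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    focal_genes, bg_genes = _gene_names(config)
    genes = focal_genes + bg_genes

    # deterministic partition of focal-chromosome genes into planted and markers
    up = focal_genes[:config.n_planted_up]
    down = focal_genes[config.n_planted_up:config.n_planted_up + config.n_planted_down]
    cursor = config.n_planted_up + config.n_planted_down
    markers: dict[str, frozenset[str]] = {}
    for ct in config.cell_types:
        if ct == config.focal_cell_type:
            continue
        markers[ct] = frozenset(
            focal_genes[cursor:cursor + config.n_marker_genes_per_type])
        cursor += config.n_marker_genes_per_type
    hk = bg_genes[:config.n_housekeeping]

    groups = config.group_labels
    baseline = np.exp2(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                  size=len(genes)))
    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(groups))), index=genes, columns=groups)

    focal_groups_planted = [f"{config.focal_cell_type}{tp}"
                            for tp in config.planted_timepoints]
    means.loc[up, focal_groups_planted] *= config.effect_ratio
    means.loc[down, focal_groups_planted] /= config.effect_ratio
    for ct, mset in markers.items():
        means.loc[sorted(mset), ct] *= config.effect_ratio

    # samples: group x replicate, batch scale per source dataset
    group_info = [(f"{config.focal_cell_type}{tp}", config.focal_cell_type, tp)
                  for tp in config.focal_timepoints]
    group_info += [(ct, ct, "") for ct in config.cell_types
                   if ct != config.focal_cell_type]

    sample_ids, meta_rows, batch_rows = [], [], []
    for g, ct, tp in group_info:
        ds = config.dataset_of_type[ct]
        scale = config.batch_scales.get(ds, 1.0)
        for r in range(1, config.replicates_per_sample_group + 1):
            sid = f"{g}_r{r}"
            sample_ids.append(sid)
            meta_rows.append({"cell_type": ct, "timepoint": tp, "dataset": ds})
            batch_rows.append({"dataset": ds, "scale": scale})

    noise = np.exp2(rng.normal(0.0, config.noise_sigma,
                               size=(len(genes), len(sample_ids))))
    cols = {}
    for k, sid in enumerate(sample_ids):
        g = sid.rsplit("_r", 1)[0]
        scale = batch_rows[k]["scale"]
        cols[sid] = means[g].to_numpy() * scale * noise[:, k]
    values = pd.DataFrame(cols, index=genes)

    ann_rows = []
    n_bg_chroms = 18  # background genes scattered over chromosomes 2..19
    for i, g in enumerate(genes):
        if g in set(focal_genes):
            chrom = config.focal_chromosome
        else:
            chrom = str(2 + (i % n_bg_chroms))
        ann_rows.append({"probe_id": g, "symbol": g, "chromosome": chrom})
    ann_df = pd.DataFrame(ann_rows).set_index("probe_id")

    level = "gene"
    if config.probes_per_gene > 1:
        # optional k-probes-per-gene expansion with fixed per-probe affinity
        affinity = np.exp2(rng.normal(0.0, 0.25,
                                      size=(len(genes), config.probes_per_gene)))
        probe_rows, probe_ann = [], []
        for i, g in enumerate(genes):
            for p in range(config.probes_per_gene):
                probe_rows.append(values.iloc[i] * affinity[i, p])
                probe_ann.append({"probe_id": f"{g}_at{p + 1}",
                                  "symbol": g,
                                  "chromosome": ann_df.at[g, "chromosome"]})
        values = pd.DataFrame(probe_rows,
                              index=[r["probe_id"] for r in probe_ann])
        ann_df = pd.DataFrame(probe_ann).set_index("probe_id")
        level = "probe"

    matrix = ExpressionMatrix(values, scale="linear", level=level)
    ann = GeneAnnotation(ann_df)
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=pd.Index(sample_ids,
                                                                 name="sample_id")))
    truth = PlantedTruth(
        up_genes=frozenset(up),
        down_genes=frozenset(down),
        housekeeping_genes=frozenset(hk),
        marker_genes=markers,
        group_means=means,
        batch=pd.DataFrame(batch_rows, index=pd.Index(sample_ids, name="sample_id")),
    )
    return matrix, ann, meta, truth


def write_dataset(outdir: str | Path, matrix: ExpressionMatrix, ann: GeneAnnotation,
                  meta: SampleMetadata, truth: PlantedTruth) -> dict[str, str]:
    """Write the matrix, annotation, metadata and truth files; return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_expression_table(matrix, paths["expression"])
    write_annotation(ann, paths["annotation"])
    write_metadata(meta, paths["metadata"])
    truth.write(paths["truth"])
    return paths
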