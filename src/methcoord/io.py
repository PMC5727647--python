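"""File formats, run configuration and the pipeline orchestrator.

All tabular files are tab-separated UTF-8 with "." decimals and "NA" for
missing values — the dialect of the Xena-style matrices the analysis was
designed around.  Expression: genes in rows, samples in columns, first
column the gene id.  Ct tables: samples in rows, genes in columns.  Gene
identifiers are opaque strings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    ClinicalRecord,
    CtTable,
    ExpressionMatrix,
    MethcoordError,
    ValidationError,
    clinical_to_frame,
    frame_to_clinical,
)
from .clinical import StratifiedCorrelationAnalysis
from .differential import (
    CoordinationClusterer,
    edge_connectivity,
    paired_pair_comparison,
    top_divergent_pairs,
)
from .panel import build_panel
from .qpcr import delta_ct_normalize, normalize_to_reference

logger = logging.getLogger(__name__)

NA = "NA"


def _read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA],
                       keep_default_na=False)


def _write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True,
               index_label: str | None = None) -> None:
    # default float formatting is shortest-roundtrip, so writes are lossless
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", na_rep=NA, index=index, index_label=index_label)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample-metadata TSV.

    Raises a named error on duplicate gene ids, non-numeric cells and
    samples missing from the metadata.
    """
    raw = _read_tsv(path)
    try:
        data = raw.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [
            c for c in raw.columns
            if pd.to_numeric(raw[c], errors="coerce").isna().sum() > raw[c].isna().sum()
        ]
        raise ValidationError(
            f"non-numeric expression cells in column(s) {bad} of {path}"
        ) from exc
    meta = _read_tsv(metadata_path)
    return ExpressionMatrix(data.rename_axis(None), meta)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path) -> None:
    _write_tsv(expr.data, path, index_label="gene")
    _write_tsv(expr.sample_info, metadata_path, index_label="sample_id")


def read_ct(path: str | Path, reference_gene: str) -> CtTable:
    return CtTable(_read_tsv(path), reference_gene=reference_gene)


def write_ct(ct: CtTable, path: str | Path) -> None:
    _write_tsv(ct.data, path, index_label="sample_id")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    return frame_to_clinical(_read_tsv(path, index_col=None))


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    _write_tsv(clinical_to_frame(records), path, index=False)


def read_panel_genes(path: str | Path) -> list[str]:
    """Panel gene list: one identifier per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            genes.append(name)
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate gene identifiers in panel file {path}")
    return genes


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Collects every analysis constant in one auditable place; thresholds keep
    their standard defaults (r > 0.3 with alpha 0.05 for the positive-
    coordination call, |delta| > 0.15 for clinical flags, 3-year recurrence
    window, minimum stratum size 10).
    """

    expression: str | None = None
    metadata: str | None = None
    ct: str | None = None
    clinical: str | None = None
    panel_file: str | None = None
    out_dir: str = "methcoord_out"
    reference_gene: str | None = None
    input_scale: str | None = None
    r_threshold: float = 0.3
    alpha: float = 0.05
    delta_threshold: float = 0.15
    recurrence_years: float = 3.0
    min_group_n: int = 10
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    top_k: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not -1 <= self.r_threshold <= 1:
            raise ValidationError("r_threshold must lie in [-1, 1]")
        if not 0 <= self.delta_threshold <= 2:
            raise ValidationError("delta_threshold must lie in [0, 2]")
        if self.recurrence_years <= 0:
            raise ValidationError("recurrence_years must be positive")
        if self.min_group_n < 3:
            raise ValidationError("min_group_n must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class StageError(MethcoordError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunResult:
    """Bundle of a completed run's tables and output paths."""

    config: RunConfig
    panels: pd.DataFrame
    differential: pd.DataFrame | None = None
    edge_counts: pd.DataFrame | None = None
    clusters: pd.DataFrame | None = None
    top_pairs: pd.DataFrame | None = None
    clinical_differences: pd.DataFrame | None = None
    flag_tally: pd.DataFrame | None = None
    summary: dict[str, Any] = field(default_factory=dict)


def _panel_long_frame(panels) -> pd.DataFrame:
    frames = []
    for p in panels:
        f = p.pairs.copy()
        f.insert(0, "group", p.group)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def run_study(config: RunConfig) -> RunResult:
    """Execute the full pipeline per the run configuration.

    Stages: load (Ct normalization or declared re-normalization), per-group
    correlation panels, matched normal/tumor differential coordination (if
    both conditions are present), and clinical stratification (if clinical
    data are supplied).  Writes all output TSVs plus ``summary.json``; any
    stage error aborts the run after marking the summary incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "status": "incomplete",
    }

    def finish(stage: str, exc: Exception) -> StageError:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return StageError(stage, exc)

    # --- load ---------------------------------------------------------
    try:
        if config.ct:
            if not config.reference_gene:
                raise ValidationError("Ct input requires reference_gene")
            ct = read_ct(config.ct, config.reference_gene)
            meta = _read_tsv(config.metadata) if config.metadata else None
            expr = delta_ct_normalize(ct, config.reference_gene, sample_info=meta)
        elif config.expression and config.metadata:
            expr = read_expression(config.expression, config.metadata)
            if config.reference_gene and config.input_scale:
                expr = normalize_to_reference(
                    expr, config.reference_gene, input_scale=config.input_scale
                )
        else:
            raise ValidationError("config must supply either ct or expression+metadata")
        panel_genes = (
            read_panel_genes(config.panel_file) if config.panel_file else expr.genes
        )
        summary["stages"]["load"] = {
            "n_genes": len(expr.genes), "n_samples": expr.n_samples,
            "panel_genes": panel_genes,
        }
    except Exception as exc:  # noqa: BLE001 - aborts carry stage context
        raise finish("load", exc) from exc

    # --- per-group panels ---------------------------------------------
    try:
        groups = (
            expr.sample_info.groupby(["tissue", "condition"], sort=True)
            .size().items()
        )
        panels = []
        for (tissue, condition), n in groups:
            if n < 3:
                logger.warning("skipping group %s/%s with %d samples", tissue, condition, n)
                continue
            panels.append(
                build_panel(
                    expr, panel_genes, tissue=tissue, condition=condition,
                    r_threshold=config.r_threshold, alpha=config.alpha,
                )
            )
        if not panels:
            raise ValidationError("no group with >= 3 samples")
        panels_frame = _panel_long_frame(panels)
        _write_tsv(panels_frame, out / "panels.tsv", index=False)
        summary["stages"]["panels"] = {"n_groups": len(panels), "n_rows": len(panels_frame)}
    except Exception as exc:  # noqa: BLE001
        raise finish("panels", exc) from exc

    result = RunResult(config=config, panels=panels_frame, summary=summary)

    # --- differential coordination ------------------------------------
    try:
        normal = [p for p in panels if p.group.endswith("/normal")]
        tumor = [p for p in panels if p.group.endswith("/tumor")]
        matched = {p.group.split("/")[0] for p in normal} & {p.group.split("/")[0] for p in tumor}
        if len(matched) >= 2:
            normal = [p for p in normal if p.group.split("/")[0] in matched]
            tumor = [p for p in tumor if p.group.split("/")[0] in matched]
            diff = paired_pair_comparison(normal, tumor)
            edges = edge_connectivity(normal, tumor)
            profiles = pd.DataFrame(
                {p.group: p.r_vector().to_numpy() for p in normal + tumor},
                index=normal[0].r_vector().index,
            ).T
            clusterer = CoordinationClusterer(
                metric=config.cluster_metric, linkage=config.cluster_linkage
            ).fit(profiles)
            clusters = pd.DataFrame(
                {
                    "profile": clusterer.labels_in_,
                    "cluster": clusterer.labels_,
                    "leaf_position": [clusterer.leaf_order_.index(l) for l in clusterer.labels_in_],
                }
            )
            top = top_divergent_pairs(diff, k=min(config.top_k, len(diff)))
            _write_tsv(diff, out / "differential.tsv", index_label="pair")
            _write_tsv(edges, out / "edge_counts.tsv", index_label="pair")
            _write_tsv(clusters, out / "clusters.tsv", index=False)
            _write_tsv(top, out / "top_divergent.tsv", index_label="pair")
            result.differential, result.edge_counts = diff, edges
            result.clusters, result.top_pairs = clusters, top
            summary["stages"]["differential"] = {
                "n_tissues": len(matched), "n_pairs": len(diff),
            }
        else:
            summary["stages"]["differential"] = {"skipped": "need >= 2 matched tissues"}
    except Exception as exc:  # noqa: BLE001
        raise finish("differential", exc) from exc

    # --- clinical association -----------------------------------------
    try:
        if config.clinical:
            records = read_clinical(config.clinical)
            analysis = StratifiedCorrelationAnalysis(
                delta_threshold=config.delta_threshold,
                min_group_n=config.min_group_n,
                window_years=config.recurrence_years,
            ).fit(expr, records, panel_genes=panel_genes)
            _write_tsv(analysis.differences_, out / "clinical_differences.tsv", index=False)
            tally = analysis.tally_.per_characteristic.copy()
            tally["grand_total"] = analysis.tally_.grand_total
            _write_tsv(tally, out / "flag_tally.tsv", index_label="pair")
            result.clinical_differences = analysis.differences_
            result.flag_tally = tally
            summary["stages"]["clinical"] = {
                "n_rows": len(analysis.differences_),
                "n_flagged": int(analysis.differences_["flagged"].sum())
                if len(analysis.differences_) else 0,
                "skipped_cells": [list(c) for c in analysis.skipped_],
            }
        else:
            summary["stages"]["clinical"] = {"skipped": "no clinical table supplied"}
    except Exception as exc:  # noqa: BLE001
        raise finish("clinical", exc) from exc

    summary["status"] = "complete"
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    result.summary = summary
    return result
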