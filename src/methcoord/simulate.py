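"""Synthetic-study generator.

Emulates the statistical structure the downstream analysis assumes: a small
gene panel whose expression carries a specified per-group correlation matrix,
log-normal positive marginals (Gaussian copula: correlation is imposed on the
log scale and the draw is exponentiated), optional uncorrelated control
genes, matched normal/tumor groups with distinct coordination levels, and
clinical metadata tied to latent patient groups so the clinical stratifiers
can recover a planted effect.

All generation is a pure function of (config, seed): per-group random streams
are derived from the config seed and a CRC32 hash of the group label, so the
same config always yields byte-identical output regardless of generation
order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ClinicalRecord,
    CtTable,
    DEFAULT_CONTROL_GENES,
    DEFAULT_PANEL_GENES,
    ExpressionMatrix,
    ValidationError,
)

THREE_YEARS_DAYS = 1095  # 3 x 365, the recurrence-window convention

_PSD_TOL = 1e-8


def compound_symmetric(n_genes: int, rho: float) -> np.ndarray:
    """Correlation matrix with a common off-diagonal coefficient ``rho``."""
    if not -1.0 / (n_genes - 1) <= rho <= 1.0:
        raise ValidationError(f"rho={rho} is not a valid equicorrelation for {n_genes} genes")
    mat = np.full((n_genes, n_genes), float(rho))
    np.fill_diagonal(mat, 1.0)
    return mat


def block_correlation(n_panel: int, n_control: int, rho_panel: float) -> np.ndarray:
    """Panel genes equicorrelated at ``rho_panel``; controls independent of all."""
    total = n_panel + n_control
    mat = np.eye(total)
    mat[:n_panel, :n_panel] = compound_symmetric(n_panel, rho_panel)
    return mat


def _check_correlation_matrix(mat: np.ndarray, group: str, n_genes: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n_genes, n_genes):
        raise ValidationError(
            f"target correlation for group {group!r} has shape {mat.shape}, "
            f"expected ({n_genes}, {n_genes})"
        )
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError(f"target correlation for group {group!r} is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError(f"target correlation for group {group!r} lacks a unit diagonal")
    if np.min(np.linalg.eigvalsh(mat)) < -_PSD_TOL:
        raise ValidationError(
            f"target correlation for group {group!r} is not positive semi-definite"
        )
    return mat


@dataclass
class ClinicalEffect:
    """A planted clinical effect: two latent patient groups with their own
    panel correlation matrices.

    Group 1 maps onto the 'adverse' side of each stratifier (early
    recurrence/death, TNM III/IV, lymph-node positive); group 2 onto the
    other, so every stratifier recovers the latent partition.
    """

    group1_correlation: np.ndarray
    group2_correlation: np.ndarray
    group1_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.group1_fraction < 1.0:
            raise ValidationError("group1_fraction must lie strictly between 0 and 1")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic study.

    ``target_correlation`` maps ``(tissue, condition)`` to a symmetric,
    unit-diagonal, positive semi-definite correlation matrix over
    panel + control genes (in that order).  ``marginal_log_mean`` and
    ``marginal_log_sd`` give per-gene natural-log moments; the modest default
    sd keeps the log-scale correlation essentially intact after
    exponentiation.  ``output_scale='log'`` returns the Gaussian log-scale
    values instead of exponentiating.
    """

    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    control_genes: tuple[str, ...] = ()
    tissues: tuple[str, ...] = ("liver",)
    conditions: tuple[str, ...] = ("normal",)
    samples_per_group: int = 50
    target_correlation: Mapping[tuple[str, str], np.ndarray] = field(default_factory=dict)
    marginal_log_mean: Mapping[str, float] = field(default_factory=dict)
    marginal_log_sd: Mapping[str, float] = field(default_factory=dict)
    reference_gene: str = "ACTB"
    clinical_effect: ClinicalEffect | None = None
    output_scale: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        genes = self.all_genes
        if len(set(genes)) != len(genes):
            raise ValidationError("panel and control gene identifiers must be disjoint and unique")
        if self.samples_per_group < 3:
            raise ValidationError("samples_per_group must be >= 3")
        if self.output_scale not in ("linear", "log"):
            raise ValidationError("output_scale must be 'linear' or 'log'")
        for (tissue, condition), mat in self.target_correlation.items():
            _check_correlation_matrix(mat, f"{tissue}/{condition}", len(genes))

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(self.panel_genes) + tuple(self.control_genes)

    def log_moments(self) -> tuple[np.ndarray, np.ndarray]:
        mu = np.array([self.marginal_log_mean.get(g, 0.0) for g in self.all_genes])
        sd = np.array([self.marginal_log_sd.get(g, 0.25) for g in self.all_genes])
        if (sd <= 0).any():
            raise ValidationError("marginal_log_sd values must be positive")
        return mu, sd


def _group_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-group stream: config seed + CRC32 of the label path."""
    tag = zlib.crc32("|".join(labels).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


def _draw_group(
    config: SimulationConfig,
    corr: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene x sample draw with the given log-scale correlation."""
    mu, sd = config.log_moments()
    cov = corr * np.outer(sd, sd)
    log_vals = rng.multivariate_normal(mu, cov, size=n, method="svd").T
    if config.output_scale == "log":
        return log_vals
    return np.exp(log_vals)


def simulate_expression(
    config: SimulationConfig, tissue: str, condition: str
) -> ExpressionMatrix:
    """Simulate one (tissue, condition) group under its target correlation.

    Returns ``samples_per_group`` strictly positive samples (log-normal)
    unless ``output_scale='log'``.  Identical config + seed give identical
    output.
    """
    key = (tissue, condition)
    if key not in config.target_correlation:
        raise ValidationError(f"no target correlation configured for group {tissue}/{condition}")
    corr = _check_correlation_matrix(
        config.target_correlation[key], f"{tissue}/{condition}", len(config.all_genes)
    )
    rng = _group_rng(config.seed, "expression", tissue, condition)
    values = _draw_group(config, corr, config.samples_per_group, rng)
    sample_ids = [f"{tissue}_{condition}_s{i:04d}" for i in range(config.samples_per_group)]
    data = pd.DataFrame(values, index=list(config.all_genes), columns=sample_ids)
    info = pd.DataFrame(
        {
            "tissue": tissue,
            "condition": condition,
            "subject_id": [f"{tissue}_subj{i:04d}" for i in range(config.samples_per_group)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(data, info)


def simulate_study(config: SimulationConfig) -> ExpressionMatrix:
    """Simulate every configured (tissue, condition) group into one matrix."""
    parts = []
    infos = []
    for tissue in config.tissues:
        for condition in config.conditions:
            if (tissue, condition) not in config.target_correlation:
                continue
            em = simulate_expression(config, tissue, condition)
            parts.append(em.data)
            infos.append(em.sample_info)
    if not parts:
        raise ValidationError("config defines no (tissue, condition) group to simulate")
    return ExpressionMatrix(pd.concat(parts, axis=1), pd.concat(infos, axis=0))


def simulate_ct(
    expr: ExpressionMatrix, reference_gene: str, reference_ct: float = 20.0
) -> CtTable:
    """Invert 2^(-dCt) normalization: build a Ct table whose dCt
    normalization reproduces ``expr`` exactly.

    Ct(g, s) = reference_ct - log2(value(g, s)); the reference gene gets a
    constant Ct of ``reference_ct``.
    """
    vals = expr.data.to_numpy()
    if np.nanmin(vals) <= 0:
        raise ValidationError("simulate_ct requires strictly positive expression values")
    ct = reference_ct - np.log2(expr.data)
    table = ct.T  # samples in rows, genes in columns
    table[reference_gene] = reference_ct
    return CtTable(table, reference_gene=reference_gene)


def _stage_for_group(latent_group: int, rng: np.random.Generator) -> str:
    if latent_group == 1:
        return rng.choice(["III", "IV"])
    return rng.choice(["I", "II"])


def simulate_clinical(
    config: SimulationConfig, cancer_type: str, n_patients: int
) -> tuple[ExpressionMatrix, list[ClinicalRecord]]:
    """Simulate a patient cohort with a planted clinical effect.

    Patients are split into two latent groups drawing expression under the
    effect's two correlation matrices.  Clinical fields are assigned
    consistently with the latent group: group 1 recurs or dies within the
    3-year window, carries TNM stage III/IV and positive lymph nodes; group 2
    stays event-free past the window with stage I/II and negative nodes.
    """
    if config.clinical_effect is None:
        raise ValidationError("config has no clinical_effect specification")
    if n_patients < 6:
        raise ValidationError(
            "n_patients must be >= 6 to form two correlatable patient groups"
        )
    effect = config.clinical_effect
    genes = config.all_genes
    corr1 = _check_correlation_matrix(effect.group1_correlation, f"{cancer_type}/group1", len(genes))
    corr2 = _check_correlation_matrix(effect.group2_correlation, f"{cancer_type}/group2", len(genes))
    n1 = max(3, int(round(n_patients * effect.group1_fraction)))
    n1 = min(n1, n_patients - 3)
    n2 = n_patients - n1

    rng = _group_rng(config.seed, "clinical", cancer_type)
    x1 = _draw_group(config, corr1, n1, rng)
    x2 = _draw_group(config, corr2, n2, rng)
    values = np.concatenate([x1, x2], axis=1)
    latent = np.array([1] * n1 + [2] * n2)

    patient_ids = [f"{cancer_type}_p{i:04d}" for i in range(n_patients)]
    records: list[ClinicalRecord] = []
    for pid, grp in zip(patient_ids, latent):
        if grp == 1:
            recurred = rng.random() < 0.5
            t_event = float(rng.integers(30, THREE_YEARS_DAYS + 1))
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    cancer_type=cancer_type,
                    recurrence_event=recurred,
                    recurrence_time=t_event if recurred else t_event + 2000.0,
                    vital_event=not recurred,
                    vital_time=t_event if not recurred else t_event + 2000.0,
                    tnm_stage=str(_stage_for_group(1, rng)),
                    lymph_node_status="positive",
                )
            )
        else:
            follow_up = float(rng.integers(THREE_YEARS_DAYS + 1, THREE_YEARS_DAYS + 1500))
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    cancer_type=cancer_type,
                    recurrence_event=False,
                    recurrence_time=follow_up,
                    vital_event=False,
                    vital_time=follow_up,
                    tnm_stage=str(_stage_for_group(2, rng)),
                    lymph_node_status="negative",
                )
            )

    data = pd.DataFrame(values, index=list(genes), columns=patient_ids)
    info = pd.DataFrame(
        {
            "tissue": cancer_type,
            "condition": "tumor",
            "subject_id": patient_ids,
        },
        index=pd.Index(patient_ids, name="sample_id"),
    )
    return ExpressionMatrix(data, info), records


def matched_study_config(
    tissues: Sequence[str],
    normal_rho: float = 0.6,
    tumor_rho: float = 0.0,
    samples_per_group: int = 200,
    n_controls: int = 0,
    seed: int = 0,
    panel_genes: Sequence[str] = DEFAULT_PANEL_GENES,
) -> SimulationConfig:
    """Convenience constructor for a matched normal/tumor multi-tissue study
    with equicorrelated panels and independent controls."""
    controls = tuple(DEFAULT_CONTROL_GENES[:n_controls])
    g = len(panel_genes)
    targets = {}
    for tissue in tissues:
        targets[(tissue, "normal")] = block_correlation(g, n_controls, normal_rho)
        targets[(tissue, "tumor")] = block_correlation(g, n_controls, tumor_rho)
    return SimulationConfig(
        panel_genes=tuple(panel_genes),
        control_genes=controls,
        tissues=tuple(tissues),
        conditions=("normal", "tumor"),
        samples_per_group=samples_per_group,
        target_correlation=targets,
        seed=seed,
    )
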