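"""Core data containers shared across the pipeline.

The pipeline's tabular unit is a gene x sample expression matrix with
per-sample annotations (tissue, condition, subject).  Conditions follow the
matched normal/tumor design; ``"none"`` marks samples outside that contrast
(e.g. the multi-tissue normal survey).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "tumor", "none")

#: The seven-gene DNA methylation enzyme panel: writers (DNMTs), oxidizers
#: (TETs) and the excision glycosylase TDG.
DEFAULT_PANEL_GENES = ("DNMT1", "DNMT3A", "DNMT3B", "TET1", "TET2", "TET3", "TDG")

#: Tissue-restricted genes used as negative controls for panel coordination.
DEFAULT_CONTROL_GENES = ("ADH1A", "CYP4B1")


class MethcoordError(ValueError):
    """Base class for all named pipeline errors."""


class ValidationError(MethcoordError):
    pass


class UndefinedCorrelationError(MethcoordError):
    """Raised when a Pearson correlation is undefined (n < 3 or constant series)."""


class DegenerateTestError(MethcoordError):
    """Raised when a test statistic cannot be formed (e.g. constant non-zero
    paired differences)."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with per-sample annotations.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows, samples in columns; finite, typically non-negative
        abundances in arbitrary units.
    sample_info : pandas.DataFrame
        Indexed by sample id; must carry ``tissue`` and ``condition`` columns
        and may carry ``subject_id``.
    """

    data: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        missing = self.data.columns.difference(self.sample_info.index)
        if len(missing):
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing.tolist())}"
            )
        for col in ("tissue", "condition"):
            if col not in self.sample_info.columns:
                raise ValidationError(f"sample metadata lacks required column {col!r}")
        bad = set(self.sample_info["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            inf_mask = ~np.isfinite(self.data.to_numpy()) & ~self.data.isna().to_numpy()
        if inf_mask.any():
            raise ValidationError("expression values must be finite")
        # keep metadata aligned and ordered with the data columns
        self.sample_info = self.sample_info.loc[self.data.columns]

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select(self, tissue: str | None = None, condition: str | None = None) -> "ExpressionMatrix":
        """Subset samples by tissue and/or condition label."""
        mask = pd.Series(True, index=self.sample_info.index)
        if tissue is not None:
            mask &= self.sample_info["tissue"] == tissue
        if condition is not None:
            mask &= self.sample_info["condition"] == condition
        ids = self.sample_info.index[mask]
        return ExpressionMatrix(self.data[ids], self.sample_info.loc[ids].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.data.columns]
        return ExpressionMatrix(self.data[ids], self.sample_info.loc[ids].copy())

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples x genes orientation used by the estimator classes."""
        return self.data.T


@dataclass
class CtTable:
    """qPCR threshold-cycle table: samples in rows, genes in columns.

    Ct values must be finite and lie in the instrument range [0, 45]; the
    reference gene must be measured for every sample (missing target-gene Ct
    values are allowed and propagate as missing).
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.reference_gene not in self.data.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from Ct table"
            )
        vals = self.data.to_numpy()
        observed = ~np.isnan(vals)
        if not (np.isfinite(vals[observed]).all()):
            raise ValidationError("Ct values must be finite")
        if ((vals[observed] < 0) | (vals[observed] > 45)).any():
            raise ValidationError("Ct values must lie within [0, 45] cycles")

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.data.columns.tolist()


def canonical_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All C(G,2) unordered gene pairs in canonical (panel-index) order."""
    genes = list(genes)
    return [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]


def pair_label(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}-{gene_b}"


@dataclass
class CorrelationPanel:
    """All-pairs Pearson correlation panel for one sample group.

    ``pairs`` is a long-format frame with one row per unordered gene pair in
    canonical order: gene_a, gene_b, n, r, p, p_adj, significant_positive.
    """

    group: str
    genes: list[str]
    pairs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        g = len(self.genes)
        expected = g * (g - 1) // 2
        if len(self.pairs) != expected:
            raise ValidationError(
                f"panel for {self.group!r} has {len(self.pairs)} pairs, expected {expected}"
            )
        labels = [pair_label(a, b) for a, b in zip(self.pairs["gene_a"], self.pairs["gene_b"])]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate gene pairs in panel")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def r_vector(self) -> pd.Series:
        """Coordination profile: the C(G,2) correlations in canonical order."""
        idx = [pair_label(a, b) for a, b in zip(self.pairs["gene_a"], self.pairs["gene_b"])]
        return pd.Series(self.pairs["r"].to_numpy(), index=idx, name=self.group)


@dataclass
class CoordinationProfile:
    """The vector of a group's pairwise correlations, keyed by tissue/condition."""

    tissue: str
    condition: str
    r_vector: pd.Series

    def __post_init__(self) -> None:
        vals = self.r_vector.to_numpy(float)
        if ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValidationError("correlation values must lie in [-1, 1]")

    @property
    def label(self) -> str:
        return f"{self.tissue}_{self.condition}"


TNM_STAGES = ("I", "II", "III", "IV", "unknown")
LYMPH_STATUSES = ("positive", "negative", "unknown")


@dataclass
class ClinicalRecord:
    """One patient's clinical annotations for the three stratification rules."""

    patient_id: str
    cancer_type: str
    recurrence_event: bool
    recurrence_time: float  # days
    vital_event: bool
    vital_time: float  # days
    tnm_stage: str = "unknown"
    lymph_node_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.recurrence_time < 0 or self.vital_time < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: event times must be non-negative"
            )
        if self.tnm_stage not in TNM_STAGES:
            raise ValidationError(
                f"patient {self.patient_id!r}: invalid TNM stage {self.tnm_stage!r}"
            )
        if self.lymph_node_status not in LYMPH_STATUSES:
            raise ValidationError(
                f"patient {self.patient_id!r}: invalid lymph node status "
                f"{self.lymph_node_status!r}"
            )


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Serialize clinical records to the standard clinical table schema."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "recurrence_event": [int(r.recurrence_event) for r in records],
            "recurrence_time_days": [r.recurrence_time for r in records],
            "vital_event": [int(r.vital_event) for r in records],
            "vital_time_days": [r.vital_time for r in records],
            "tnm_stage": [r.tnm_stage for r in records],
            "lymph_node_status": [r.lymph_node_status for r in records],
        }
    )


def frame_to_clinical(frame: pd.DataFrame) -> list[ClinicalRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                cancer_type=str(row.cancer_type),
                recurrence_event=bool(int(row.recurrence_event)),
                recurrence_time=float(row.recurrence_time_days),
                vital_event=bool(int(row.vital_event)),
                vital_time=float(row.vital_time_days),
                tnm_stage=str(row.tnm_stage),
                lymph_node_status=str(row.lymph_node_status),
            )
        )
    return records
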