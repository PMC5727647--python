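"""Clinical stratification and correlation-difference flagging.

Patients of each cancer type are split into two groups by three rules:

* recurrence: death or recurrence within the 3-year window (1095 days,
  boundary inclusive) -> early group; everyone else -> non-early group,
* TNM stage: I/II -> group 1, III/IV -> group 2 (sub-stage suffixes such as
  "IIIA" normalize to their main stage; unknown labels are excluded),
* lymph nodes: positive -> group 1, negative -> group 2; unknown excluded.

For each gene pair the two groups' Pearson correlations are compared and the
pair is flagged when |r_group1 - r_group2| strictly exceeds the threshold
(default 0.15).  Flags are then tallied across cancer types per pair and
characteristic.  No p-value is attached to the difference by default; a
Fisher-z two-sample test is available as an explicit extension.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import (
    ClinicalRecord,
    ExpressionMatrix,
    ValidationError,
    canonical_pairs,
)
from .panel import CorrelationPanelEstimator

logger = logging.getLogger(__name__)

CHARACTERISTICS = ("recurrence", "tnm", "lymph_node")
DAYS_PER_YEAR = 365


@dataclass
class Stratification:
    """A two-group patient partition with its exclusions."""

    characteristic: str
    group1: list[str]
    group2: list[str]
    excluded: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValidationError(f"patients assigned to both groups: {sorted(overlap)}")


def stratify_recurrence(records: list[ClinicalRecord],
                        window_years: float = 3) -> Stratification:
    """Early group: death or recurrence within the window (inclusive)."""
    window_days = window_years * DAYS_PER_YEAR
    early, non_early = [], []
    for rec in records:
        is_early = (rec.vital_event and rec.vital_time <= window_days) or (
            rec.recurrence_event and rec.recurrence_time <= window_days
        )
        (early if is_early else non_early).append(rec.patient_id)
    return Stratification("recurrence", group1=early, group2=non_early, excluded=[])


_STAGE_RE = re.compile(r"^(IV|III|II|I)")


def normalize_stage(stage: str) -> str | None:
    """Normalize a TNM stage label to I/II/III/IV; None if unparseable."""
    cleaned = re.sub(r"^STAGE\s*", "", str(stage).strip().upper())
    m = _STAGE_RE.match(cleaned)
    return m.group(1) if m else None


def stratify_tnm(records: list[ClinicalRecord]) -> Stratification:
    """TNM stage I/II -> group 1; III/IV -> group 2; unknown excluded."""
    g1, g2, excluded = [], [], []
    for rec in records:
        stage = normalize_stage(rec.tnm_stage)
        if stage in ("I", "II"):
            g1.append(rec.patient_id)
        elif stage in ("III", "IV"):
            g2.append(rec.patient_id)
        else:
            excluded.append(rec.patient_id)
    if excluded:
        logger.warning("TNM stratifier excluded %d patient(s) with unknown stage", len(excluded))
    return Stratification("tnm", group1=g1, group2=g2, excluded=excluded)


def stratify_lymph(records: list[ClinicalRecord]) -> Stratification:
    """Lymph node positive -> group 1; negative -> group 2; unknown excluded."""
    g1, g2, excluded = [], [], []
    for rec in records:
        if rec.lymph_node_status == "positive":
            g1.append(rec.patient_id)
        elif rec.lymph_node_status == "negative":
            g2.append(rec.patient_id)
        else:
            excluded.append(rec.patient_id)
    if excluded:
        logger.warning("lymph-node stratifier excluded %d patient(s)", len(excluded))
    return Stratification("lymph_node", group1=g1, group2=g2, excluded=excluded)


STRATIFIERS = {
    "recurrence": stratify_recurrence,
    "tnm": stratify_tnm,
    "lymph_node": stratify_lymph,
}


@dataclass
class StratifiedDifference:
    """One gene pair's between-group correlation difference in one cancer."""

    gene_a: str
    gene_b: str
    cancer_type: str
    characteristic: str
    r_group1: float
    n_group1: int
    r_group2: float
    n_group2: int
    delta: float
    flagged: bool

    @property
    def pair(self) -> str:
        return f"{self.gene_a}-{self.gene_b}"


def correlation_difference(
    gene_a: str,
    gene_b: str,
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    cancer_type: str = "",
    characteristic: str = "",
    delta_threshold: float = 0.15,
) -> StratifiedDifference:
    """Build one StratifiedDifference; flagged iff |delta| > threshold (strict).

    The comparison tolerates float representation error so a difference that
    is exactly the threshold (e.g. 0.40 - 0.25) never flags.
    """
    delta = r1 - r2
    return StratifiedDifference(
        gene_a=gene_a,
        gene_b=gene_b,
        cancer_type=cancer_type,
        characteristic=characteristic,
        r_group1=float(r1),
        n_group1=int(n1),
        r_group2=float(r2),
        n_group2=int(n2),
        delta=float(delta),
        flagged=bool(abs(delta) - delta_threshold > 1e-12),
    )


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample Fisher-z comparison of independent correlations (extension)."""
    if n1 < 4 or n2 < 4:
        raise ValidationError("Fisher-z comparison needs n >= 4 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def stratified_differences(
    expr: ExpressionMatrix,
    groups: Stratification,
    panel_genes: list[str],
    cancer_type: str = "",
    delta_threshold: float = 0.15,
    min_group_n: int = 10,
) -> list[StratifiedDifference]:
    """Per-pair correlation difference between the two strata of one cancer.

    Each group gets its own correlation panel (standard panel rules); the
    cell is skipped (empty result, logged) when either group is smaller than
    ``min_group_n`` — Pearson r on fewer samples is too unstable to compare
    at the threshold's resolution.
    """
    sub1 = expr.subset_samples(groups.group1)
    sub2 = expr.subset_samples(groups.group2)
    if sub1.n_samples < min_group_n or sub2.n_samples < min_group_n:
        logger.warning(
            "skipping %s/%s: group sizes %d/%d below min_group_n=%d",
            cancer_type, groups.characteristic, sub1.n_samples, sub2.n_samples, min_group_n,
        )
        return []
    est1 = CorrelationPanelEstimator().fit(sub1.data.loc[panel_genes].T)
    est2 = CorrelationPanelEstimator().fit(sub2.data.loc[panel_genes].T)
    out = []
    for (a, b), row1, row2 in zip(
        canonical_pairs(panel_genes),
        est1.pairs_.itertuples(index=False),
        est2.pairs_.itertuples(index=False),
    ):
        out.append(
            correlation_difference(
                a, b, row1.r, row1.n, row2.r, row2.n,
                cancer_type=cancer_type,
                characteristic=groups.characteristic,
                delta_threshold=delta_threshold,
            )
        )
    return out


def differences_to_frame(differences: list[StratifiedDifference]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [d.gene_a for d in differences],
            "gene_b": [d.gene_b for d in differences],
            "pair": [d.pair for d in differences],
            "cancer_type": [d.cancer_type for d in differences],
            "characteristic": [d.characteristic for d in differences],
            "r_group1": [d.r_group1 for d in differences],
            "n_group1": [d.n_group1 for d in differences],
            "r_group2": [d.r_group2 for d in differences],
            "n_group2": [d.n_group2 for d in differences],
            "delta": [d.delta for d in differences],
            "flagged": [d.flagged for d in differences],
        }
    )


@dataclass
class FlagTally:
    """Flag counts per pair x characteristic, plus per-pair grand totals."""

    per_characteristic: pd.DataFrame  # pairs x characteristics, cancer-type counts
    grand_total: pd.Series  # per pair, summed over characteristics


def tally_flags(differences: list[StratifiedDifference]) -> FlagTally:
    """Count, per pair and characteristic, the distinct cancer types flagged."""
    frame = differences_to_frame(differences)
    if frame.empty:
        empty = pd.DataFrame(columns=list(CHARACTERISTICS))
        return FlagTally(per_characteristic=empty,
                         grand_total=pd.Series(dtype=int, name="grand_total"))
    flagged = frame[frame["flagged"]]
    counts = (
        flagged.groupby(["pair", "characteristic"])["cancer_type"].nunique().unstack(fill_value=0)
    )
    counts = counts.reindex(index=sorted(frame["pair"].unique()),
                            columns=list(CHARACTERISTICS), fill_value=0)
    grand = counts.sum(axis=1).rename("grand_total")
    return FlagTally(per_characteristic=counts, grand_total=grand)


class StratifiedCorrelationAnalysis(BaseEstimator):
    """Run all three clinical stratifications across every cancer type.

    Patient ids in the clinical records must match sample ids in the
    expression matrix.

    Attributes
    ----------
    differences_ : pandas.DataFrame
        One row per pair x cancer type x characteristic.
    tally_ : FlagTally
    skipped_ : list of (cancer_type, characteristic) cells skipped for size.
    """

    def __init__(self, delta_threshold: float = 0.15, min_group_n: int = 10,
                 window_years: float = 3):
        self.delta_threshold = delta_threshold
        self.min_group_n = min_group_n
        self.window_years = window_years

    def fit(self, expr: ExpressionMatrix, records: list[ClinicalRecord],
            panel_genes: list[str] | None = None):
        panel_genes = panel_genes or expr.genes
        all_diffs: list[StratifiedDifference] = []
        self.skipped_ = []
        cancers = sorted({r.cancer_type for r in records})
        for cancer in cancers:
            cohort = [r for r in records if r.cancer_type == cancer]
            in_expr = set(expr.samples)
            cohort = [r for r in cohort if r.patient_id in in_expr]
            for name, strat_fn in STRATIFIERS.items():
                if name == "recurrence":
                    groups = strat_fn(cohort, window_years=self.window_years)
                else:
                    groups = strat_fn(cohort)
                diffs = stratified_differences(
                    expr, groups, panel_genes,
                    cancer_type=cancer,
                    delta_threshold=self.delta_threshold,
                    min_group_n=self.min_group_n,
                )
                if not diffs:
                    self.skipped_.append((cancer, name))
                all_diffs.extend(diffs)
        self.raw_differences_ = all_diffs
        self.differences_ = differences_to_frame(all_diffs)
        self.tally_ = tally_flags(all_diffs)
        return self
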