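"""All-pairs Pearson correlation panels with BH-adjusted significance calls.

For a panel of G genes within one sample group (a tissue x condition cell),
every one of the C(G,2) unordered pairs gets a Pearson coefficient, a
two-sided p-value from the t-statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees
of freedom, and a Benjamini-Hochberg adjusted p-value; the BH family is
exactly the panel's pairs within that one group.  A pair is called
"significantly positive" when r exceeds the r-threshold (default 0.3) AND
its (adjusted, by default) p-value is below alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import (
    CorrelationPanel,
    ExpressionMatrix,
    UndefinedCorrelationError,
    ValidationError,
    canonical_pairs,
)


def pearson_pair(x: Sequence[float], y: Sequence[float],
                 label: str = "pair") -> tuple[float, float, int]:
    """Pearson r, two-sided p and n for one gene pair.

    Incomplete (x, y) observations are dropped first; n >= 3 complete pairs
    and two non-constant series are required — anything less is an error, not
    r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"{label}: series lengths differ ({x.size} vs {y.size})")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise UndefinedCorrelationError(
            f"{label}: only {n} complete observation pairs (need >= 3)"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"{label}: constant series, correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class CorrelationPanelEstimator(BaseEstimator):
    """Estimate the all-pairs correlation panel of one sample group.

    Parameters
    ----------
    r_threshold : float
        Minimum r for the "significantly positive" call (default 0.3).
    alpha : float
        Significance level applied to the (adjusted) p-value (default 0.05).
    use_adjusted : bool
        Whether the call uses BH-adjusted p-values (default) or raw ones.

    Attributes
    ----------
    genes_ : list of str
        Panel genes in input order.
    pairs_ : pandas.DataFrame
        One row per pair in canonical order: gene_a, gene_b, n, r, p, p_adj,
        significant_positive.
    """

    def __init__(self, r_threshold: float = 0.3, alpha: float = 0.05,
                 use_adjusted: bool = True):
        self.r_threshold = r_threshold
        self.alpha = alpha
        self.use_adjusted = use_adjusted

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a samples x genes frame (>= 3 samples)."""
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise ValidationError(
                f"group has {X.shape[0]} samples; at least 3 are required"
            )
        self.genes_ = X.columns.tolist()
        rows = []
        for a, b in canonical_pairs(self.genes_):
            r, p, n = pearson_pair(X[a], X[b], label=f"{a}-{b}")
            rows.append({"gene_a": a, "gene_b": b, "n": n, "r": r, "p": p})
        pairs = pd.DataFrame(rows)
        pairs["p_adj"] = bh_adjust(pairs["p"])
        crit = pairs["p_adj"] if self.use_adjusted else pairs["p"]
        pairs["significant_positive"] = (pairs["r"] > self.r_threshold) & (crit < self.alpha)
        self.pairs_ = pairs
        return self

    def to_panel(self, group: str = "group") -> CorrelationPanel:
        return CorrelationPanel(group=group, genes=list(self.genes_), pairs=self.pairs_.copy())


def build_panel(
    expr: ExpressionMatrix,
    panel_genes: Sequence[str],
    tissue: str | None = None,
    condition: str | None = None,
    r_threshold: float = 0.3,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> CorrelationPanel:
    """Build the correlation panel for one (tissue, condition) group.

    BH correction is applied across exactly this panel's pairs within this
    group.
    """
    absent = [g for g in panel_genes if g not in expr.data.index]
    if absent:
        raise ValidationError(f"panel genes absent from expression matrix: {absent}")
    sub = expr.select(tissue=tissue, condition=condition)
    label = "/".join(str(part) for part in (tissue, condition) if part is not None) or "all"
    if sub.n_samples < 3:
        raise ValidationError(
            f"group {label!r} has {sub.n_samples} samples; at least 3 are required"
        )
    est = CorrelationPanelEstimator(
        r_threshold=r_threshold, alpha=alpha, use_adjusted=use_adjusted
    )
    est.fit(sub.data.loc[list(panel_genes)].T)
    return est.to_panel(group=label)


@dataclass
class ControlContrast:
    """Per-class significance summary for panel-panel vs control-panel pairs."""

    panel_pair_count: int
    panel_significant: int
    control_pair_count: int
    control_significant: int

    @property
    def panel_fraction(self) -> float:
        return self.panel_significant / self.panel_pair_count

    @property
    def control_fraction(self) -> float:
        return self.control_significant / self.control_pair_count if self.control_pair_count else float("nan")


def control_gene_contrast(panel: CorrelationPanel,
                          control_genes: Sequence[str]) -> ControlContrast:
    """Contrast panel-panel pairs against control-panel pairs.

    Control genes are expected to be uncoordinated with the enzyme panel, so
    their pairs should rarely be called significantly positive.
    """
    controls = set(control_genes) & set(panel.genes)
    if not controls:
        raise ValidationError("panel contains none of the requested control genes")
    is_control = panel.pairs["gene_a"].isin(controls) | panel.pairs["gene_b"].isin(controls)
    ctrl = panel.pairs[is_control]
    core = panel.pairs[~is_control]
    return ControlContrast(
        panel_pair_count=len(core),
        panel_significant=int(core["significant_positive"].sum()),
        control_pair_count=len(ctrl),
        control_significant=int(ctrl["significant_positive"].sum()),
    )


#: Tissues excluded a priori because gametes carry atypical methylation profiles.
GERMLINE_TISSUES = ("testis", "ovary")


def retain_tissues(
    sample_counts: Mapping[str, int],
    min_samples: int = 15,
    excluded_tissues: Sequence[str] = GERMLINE_TISSUES,
) -> list[str]:
    """Apply the study's tissue-exclusion rules to a tissue -> n table.

    Tissues with fewer than ``min_samples`` samples are dropped, as are the
    a-priori exclusions (germline tissues by default).  Returns the retained
    tissue labels in input order.
    """
    if min_samples < 3:
        raise ValidationError("min_samples must be at least 3")
    dropped = {t.lower() for t in excluded_tissues}
    return [
        t for t, n in sample_counts.items()
        if n >= min_samples and t.lower() not in dropped
    ]
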