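"""qPCR Ct normalization and reference-gene normalization.

Relative expression is obtained from threshold cycles by the 2^(-dCt)
formula with dCt = Ct(gene) - Ct(reference), i.e.

    value(g, s) = 2 ** (Ct(reference, s) - Ct(g, s))

The sign convention is fixed here once: the exponent is Ct(reference) minus
Ct(gene), so a gene amplifying 5 cycles later than the reference has
relative expression 2^-5.  Missing target Ct values propagate as missing and
are never imputed; downstream correlation uses pairwise-complete pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CtTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

INPUT_SCALES = ("linear", "log2p1")


class DeltaCtNormalizer(TransformerMixin, BaseEstimator):
    """Transform a samples x genes Ct table into relative expression.

    Parameters
    ----------
    reference_gene : str
        Housekeeping gene (e.g. beta-actin); excluded from the output.
    """

    def __init__(self, reference_gene: str = "ACTB"):
        self.reference_gene = reference_gene

    def fit(self, X: pd.DataFrame, y=None):
        if self.reference_gene not in X.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from Ct table"
            )
        self.feature_names_in_ = np.asarray(X.columns)
        self.genes_out_ = [g for g in X.columns if g != self.reference_gene]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genes_out_"):
            self.fit(X)
        ref = X[self.reference_gene]
        missing_ref = ref.index[ref.isna()].tolist()
        if missing_ref:
            raise ValidationError(
                f"samples missing reference gene Ct: {missing_ref}"
            )
        out = 2.0 ** ref.to_numpy()[:, None] / 2.0 ** X[self.genes_out_]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.genes_out_)


class ReferenceNormalizer(TransformerMixin, BaseEstimator):
    """Divide each gene by the same sample's reference-gene value.

    ``input_scale`` must be declared by the caller — 'linear' values are
    divided directly; 'log2p1' (log2(x+1), the Xena-style encoding) values
    are first mapped back to linear via 2**x - 1.  Output is always linear.
    Samples with a zero linear reference value are dropped and logged; no
    pseudocount is applied.
    """

    def __init__(self, reference_gene: str = "ACTB", input_scale: str = "linear"):
        self.reference_gene = reference_gene
        self.input_scale = input_scale

    def fit(self, X: pd.DataFrame, y=None):
        if self.input_scale not in INPUT_SCALES:
            raise ValidationError(
                f"input_scale must be one of {INPUT_SCALES}, got {self.input_scale!r}"
            )
        if self.reference_gene not in X.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from expression table"
            )
        self.genes_out_ = [g for g in X.columns if g != self.reference_gene]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genes_out_"):
            self.fit(X)
        linear = X if self.input_scale == "linear" else 2.0 ** X - 1.0
        ref = linear[self.reference_gene]
        zero_ref = ref.index[(ref == 0) | ref.isna()].tolist()
        if zero_ref:
            logger.warning(
                "dropping %d sample(s) with zero/missing reference value: %s",
                len(zero_ref), zero_ref,
            )
        self.rejected_samples_ = zero_ref
        keep = linear.drop(index=zero_ref)
        return keep[self.genes_out_].div(keep[self.reference_gene], axis=0)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.genes_out_)


def delta_ct_normalize(ct: CtTable, reference_gene: str | None = None,
                       sample_info: pd.DataFrame | None = None) -> ExpressionMatrix:
    """2^(-dCt) normalization of a Ct table into an ExpressionMatrix.

    The reference gene is removed from the output panel.  A sample lacking
    the reference Ct is rejected with a named error; a missing target-gene Ct
    yields a missing value, never zero.
    """
    reference_gene = reference_gene or ct.reference_gene
    norm = DeltaCtNormalizer(reference_gene=reference_gene)
    expr = norm.fit(ct.data).transform(ct.data)
    if sample_info is None:
        sample_info = pd.DataFrame(
            {"tissue": "unknown", "condition": "none"},
            index=expr.index,
        )
    return ExpressionMatrix(expr.T, sample_info)


def normalize_to_reference(expr: ExpressionMatrix, reference_gene: str,
                           input_scale: str = "linear") -> ExpressionMatrix:
    """Re-normalize an expression matrix to a reference gene (linear ratio).

    See :class:`ReferenceNormalizer` for the scale contract.
    """
    norm = ReferenceNormalizer(reference_gene=reference_gene, input_scale=input_scale)
    out = norm.fit(expr.to_samples_by_genes()).transform(expr.to_samples_by_genes())
    return ExpressionMatrix(out.T, expr.sample_info.loc[out.index].copy())
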