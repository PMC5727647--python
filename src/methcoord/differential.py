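"""Normal-vs-tumor coordination comparison across matched tissues.

Given correlation panels for the same gene panel in N matched tissues under
two conditions, each gene pair contributes a length-N vector of normal
correlations and a length-N vector of tumor correlations.  Coordination loss
is summarized four ways:

* a two-sided paired t-test on the per-tissue differences (r values used
  as-is, mirroring common practice; a Fisher-z variant is available),
* an edge-count connectivity map (in how many tissues is the normal
  correlation strictly higher?),
* agglomerative clustering of the tissue x condition coordination profiles,
* a ranking of pairs by mean per-tissue difference ("most divergent").
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from .containers import (
    CoordinationProfile,
    CorrelationPanel,
    DegenerateTestError,
    ValidationError,
    pair_label,
)

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cutoff, tier in TIER_THRESHOLDS:
        if p < cutoff:
            return tier
    return "ns"


def _tissue_of(panel: CorrelationPanel) -> str:
    return panel.group.split("/")[0]


def _r_matrix(panels: list[CorrelationPanel]) -> pd.DataFrame:
    """Stack panels into a tissues x pairs correlation matrix."""
    rows = {}
    genes = panels[0].genes
    for p in panels:
        if p.genes != genes:
            raise ValidationError(
                f"gene panel mismatch: {p.group!r} has {p.genes}, expected {genes}"
            )
        rows[_tissue_of(p)] = p.r_vector().to_numpy()
    labels = [pair_label(a, b) for a, b in zip(panels[0].pairs["gene_a"], panels[0].pairs["gene_b"])]
    return pd.DataFrame(rows, index=labels).T


def _align(normal: pd.DataFrame, tumor: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    unmatched = set(normal.index).symmetric_difference(tumor.index)
    if unmatched:
        raise ValidationError(f"tissues without a matched counterpart: {sorted(unmatched)}")
    if list(normal.columns) != list(tumor.columns):
        raise ValidationError("gene-pair columns differ between conditions")
    return normal, tumor.loc[normal.index]


def paired_delta_t(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on a difference vector.

    An exactly-zero vector is the null identity (t=0, p=1); a constant
    non-zero vector has no variance to test against and is an error.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValidationError("paired test needs >= 2 matched tissues")
    if np.allclose(diffs, 0.0, atol=1e-15):
        return 0.0, 1.0
    sd = diffs.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(diffs.mean())):
        raise DegenerateTestError(
            "paired differences are constant and non-zero; t is undefined"
        )
    t = diffs.mean() / (sd / np.sqrt(diffs.size))
    p = 2.0 * stats.t.sf(abs(t), df=diffs.size - 1)
    return float(t), float(p)


class PairedCoordinationComparison(BaseEstimator):
    """Paired comparison of per-tissue correlations between two conditions.

    Parameters
    ----------
    fisher_z : bool
        Apply the Fisher z-transform arctanh(r) before testing (non-default
    extension; the default tests the correlations themselves).

    Attributes
    ----------
    tissues_ : list of str
    results_ : pandas.DataFrame
        Per pair: mean_delta (mean of r_normal - r_tumor), t_statistic, p,
        significance_tier, plus per-tissue r columns.
    edge_counts_ : pandas.Series
        Per pair, the number of tissues where r_normal > r_tumor (strict;
        ties count 0).
    """

    def __init__(self, fisher_z: bool = False):
        self.fisher_z = fisher_z

    def fit(self, r_normal: pd.DataFrame, r_tumor: pd.DataFrame):
        r_normal, r_tumor = _align(r_normal, r_tumor)
        self.tissues_ = r_normal.index.tolist()
        vals_n = r_normal.to_numpy(float)
        vals_t = r_tumor.to_numpy(float)
        test_n, test_t = (np.arctanh(vals_n), np.arctanh(vals_t)) if self.fisher_z else (vals_n, vals_t)
        rows = []
        for j, pair in enumerate(r_normal.columns):
            t_stat, p = paired_delta_t(test_n[:, j] - test_t[:, j])
            rows.append(
                {
                    "pair": pair,
                    "mean_delta": float(np.mean(vals_n[:, j] - vals_t[:, j])),
                    "t_statistic": t_stat,
                    "p": p,
                    "significance_tier": significance_tier(p),
                }
            )
        self.results_ = pd.DataFrame(rows).set_index("pair")
        self.edge_counts_ = pd.Series(
            (vals_n > vals_t).sum(axis=0), index=r_normal.columns, name="count"
        )
        self.n_tissues_ = len(self.tissues_)
        return self


def paired_pair_comparison(
    normal_panels: list[CorrelationPanel],
    tumor_panels: list[CorrelationPanel],
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Per-pair paired t comparison of matched normal/tumor panels.

    Returns a frame indexed by pair with per-tissue r columns
    (``r_normal:<tissue>``, ``r_tumor:<tissue>``), mean_delta, t_statistic,
    p and significance_tier.
    """
    rn = _r_matrix(normal_panels)
    rt = _r_matrix(tumor_panels)
    est = PairedCoordinationComparison(fisher_z=fisher_z).fit(rn, rt)
    out = est.results_.copy()
    rn, rt = _align(rn, rt)
    for tissue in est.tissues_:
        out[f"r_normal:{tissue}"] = rn.loc[tissue]
        out[f"r_tumor:{tissue}"] = rt.loc[tissue]
    return out


def edge_connectivity(
    normal_panels: list[CorrelationPanel],
    tumor_panels: list[CorrelationPanel],
) -> pd.DataFrame:
    """Edge-count map: per pair, tissues where r_normal strictly exceeds r_tumor."""
    rn, rt = _align(_r_matrix(normal_panels), _r_matrix(tumor_panels))
    counts = pd.Series(
        (rn.to_numpy(float) > rt.to_numpy(float)).sum(axis=0),
        index=rn.columns, name="count",
    )
    return pd.DataFrame({"count": counts, "total_tissues": len(rn.index)})


def connectivity_graph(edge_counts: pd.DataFrame) -> nx.Graph:
    """Build the gene connectivity graph; edge weight = tissue count."""
    g = nx.Graph()
    for pair, row in edge_counts.iterrows():
        a, b = str(pair).split("-", 1)
        g.add_edge(a, b, weight=int(row["count"]))
    return g


@dataclass
class ClusterResult:
    """Agglomerative clustering of coordination profiles."""

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")


class CoordinationClusterer(BaseEstimator):
    """Hierarchical clustering of coordination-profile rows.

    Metric and linkage default to Euclidean/average; leaf order follows the
    standard dendrogram convention, so results are deterministic for a fixed
    input order.
    """

    def __init__(self, metric: str = "euclidean", linkage: str = "average",
                 n_clusters: int = 2):
        self.metric = metric
        self.linkage = linkage
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValidationError("clustering needs at least 2 profiles")
        if X.isna().any().any():
            raise ValidationError("profiles contain missing values")
        self.labels_in_ = X.index.astype(str).tolist()
        dist = hierarchy.distance.pdist(X.to_numpy(float), metric=self.metric)
        self.linkage_ = hierarchy.linkage(dist, method=self.linkage)
        self.leaf_order_ = [self.labels_in_[i] for i in hierarchy.leaves_list(self.linkage_)]
        self.labels_ = hierarchy.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


def profiles_to_frame(profiles: list[CoordinationProfile]) -> pd.DataFrame:
    lengths = {len(p.r_vector) for p in profiles}
    if len(lengths) > 1:
        raise ValidationError(f"profile vector lengths differ: {sorted(lengths)}")
    return pd.DataFrame(
        {p.label: p.r_vector.to_numpy(float) for p in profiles},
        index=profiles[0].r_vector.index,
    ).T


def cluster_profiles(profiles: list[CoordinationProfile],
                     metric: str = "euclidean",
                     linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of tissue x condition coordination profiles."""
    frame = profiles_to_frame(profiles)
    est = CoordinationClusterer(metric=metric, linkage=linkage).fit(frame)
    return ClusterResult(labels=est.labels_in_, linkage=est.linkage_,
                         leaf_order=est.leaf_order_)


def top_divergent_pairs(results: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Rank pairs by descending mean_delta; ties broken by smaller p, then
    canonical pair order."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(results):
        raise ValidationError(f"k={k} exceeds the number of pairs ({len(results)})")
    ranked = results.assign(_ord=np.arange(len(results))).sort_values(
        by=["mean_delta", "p", "_ord"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_ord")
    return ranked.head(k)


def group_panel_comparison(panel_a: CorrelationPanel,
                           panel_b: CorrelationPanel) -> pd.DataFrame:
    """Pairwise delta table between two groups' panels (e.g. blood vs leukemia).

    Per pair: r_a, r_b, delta = r_a - r_b, and a sign_flip flag marking
    positive-to-negative (or the reverse) transitions.
    """
    if panel_a.genes != panel_b.genes:
        raise ValidationError(
            f"gene panels differ: {panel_a.genes} vs {panel_b.genes}"
        )
    ra = panel_a.r_vector()
    rb = panel_b.r_vector()
    out = pd.DataFrame({"r_a": ra, "r_b": rb})
    out["delta"] = out["r_a"] - out["r_b"]
    out["sign_flip"] = np.sign(out["r_a"]) * np.sign(out["r_b"]) < 0
    return out
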