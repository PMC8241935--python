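"""Molecular responder classification from a 23-gene expression signature.

Tumors are labeled molecular responders (mR) or nonresponders (mNR) by
hierarchically clustering samples on a z-scored gene signature and orienting
the two clusters by biology: the cluster with higher mean T-cell/IFN-γ gene
expression and lower cell-cycle gene expression is the responder cluster.
Labels therefore depend only on the category scores, never on arbitrary
cluster indices or sample order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._base import BaseEstimator

logger = logging.getLogger(__name__)

CATEGORIES = ("t_cell_ifng", "cell_cycle")


@dataclass
class SignatureResult:
    """Clustering + orientation outcome for a signature matrix."""

    sample_cluster: pd.Series          # sample -> cluster id (1 or 2)
    linkage_matrix: np.ndarray         # scipy linkage (merge heights)
    cluster_labels: dict[int, str]     # cluster id -> "mR" / "mNR"
    category_scores: pd.DataFrame      # cluster x category mean z-scores
    dropped_genes: list[str]

    @property
    def labels(self) -> pd.Series:
        return self.sample_cluster.map(self.cluster_labels)

    def to_dict(self) -> dict:
        return {
            "sample_cluster": self.sample_cluster.to_dict(),
            "labels": self.labels.to_dict(),
            "cluster_labels": {str(k): v for k, v in self.cluster_labels.items()},
            "category_scores": self.category_scores.to_dict(),
            "merge_heights": self.linkage_matrix[:, 2].tolist(),
            "dropped_genes": self.dropped_genes,
        }


def _zscore_genes(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    mean = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=1)
    constant = list(expr.columns[sd == 0])
    if constant:
        warnings.warn(f"dropping constant gene(s): {constant}")
    kept = expr.columns[sd > 0]
    return (expr[kept] - mean[kept]) / sd[kept], constant


def cluster_signature(
    expr: pd.DataFrame,
    genes: dict[str, str],
    k: int = 2,
    method: str = "ward",
    metric: str = "euclidean",
) -> SignatureResult:
    """Cluster samples on the z-scored signature genes.

    ``expr`` is a sample x gene matrix; ``genes`` maps each signature gene to
    its category (``t_cell_ifng`` or ``cell_cycle``). All signature genes
    must be present; constant genes are dropped with a warning. Clustering is
    agglomerative (Ward/Euclidean by default) cut at ``k`` clusters and is
    deterministic given the input order.
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise ValueError(f"signature gene(s) missing from matrix: {missing}")
    if len(expr) < max(3, k):
        if len(expr) == 2 and k == 2:
            pass  # trivial split: each sample its own cluster
        else:
            raise ValueError(f"need at least 3 samples, got {len(expr)}")
    bad = set(genes.values()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown gene categories: {sorted(bad)}")
    sub = expr[list(genes)].astype(float)
    z, dropped = _zscore_genes(sub)
    if z.shape[1] == 0:
        raise ValueError("no non-constant signature genes remain")
    Z = linkage(z.to_numpy(), method=method, metric=metric)
    assign = fcluster(Z, t=k, criterion="maxclust")
    sample_cluster = pd.Series(assign, index=expr.index, name="cluster")
    # per-cluster mean z by category
    scores = {}
    for cat in CATEGORIES:
        cat_genes = [g for g, c in genes.items() if c == cat and g in z.columns]
        if not cat_genes:
            raise ValueError(f"category {cat!r} has no (non-constant) genes")
        scores[cat] = z[cat_genes].mean(axis=1).groupby(sample_cluster).mean()
    category_scores = pd.DataFrame(scores)
    result = SignatureResult(
        sample_cluster=sample_cluster,
        linkage_matrix=Z,
        cluster_labels={},
        category_scores=category_scores,
        dropped_genes=dropped,
    )
    result.cluster_labels = label_clusters(result)
    logger.info("cluster_signature: %d samples -> clusters %s",
                len(expr), dict(sample_cluster.value_counts()))
    return result


def label_clusters(result: SignatureResult) -> dict[int, str]:
    """Orient clusters: higher (T-cell/IFN-γ − cell-cycle) score -> mR."""
    scores = result.category_scores
    orientation = scores["t_cell_ifng"] - scores["cell_cycle"]
    if orientation.nunique() < len(orientation):
        raise ValueError("orientation ambiguous: equal category scores")
    mr_cluster = int(orientation.idxmax())
    return {c: ("mR" if c == mr_cluster else "mNR") for c in scores.index}


class SignatureClusterer(BaseEstimator):
    """Estimator wrapper: fit clusters + orientation, predict mR/mNR labels.

    ``fit`` stores the full :class:`SignatureResult`; ``labels_`` holds the
    oriented per-sample labels. ``fit_predict`` returns them directly.
    """

    def __init__(
        self,
        genes: dict[str, str] | None = None,
        k: int = 2,
        method: str = "ward",
        metric: str = "euclidean",
    ):
        self.genes = genes
        self.k = k
        self.method = method
        self.metric = metric

    def fit(self, expr: pd.DataFrame, y=None) -> "SignatureClusterer":
        if self.genes is None:
            raise ValueError("genes mapping (gene -> category) is required")
        self.result_ = cluster_signature(
            expr, self.genes, k=self.k, method=self.method, metric=self.metric
        )
        self.labels_ = self.result_.labels
        return self

    def fit_predict(self, expr: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(expr).labels_
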