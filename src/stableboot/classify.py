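"""Marker-panel validation: hierarchical clustering, PCA, panel transfer.

A called marker panel is useful when the samples, restricted to the panel
genes alone, cluster back into their populations.  Clustering uses Ward
linkage on Euclidean distances (the ward.D2 convention: squared distances
inside the Ward criterion) over per-gene z-scored log expression by
default, and cluster labels are matched to true groups by
maximum-agreement assignment so misclassification can be counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .io_qc import ExpressionMatrix


@dataclass
class PanelEvaluation:
    """Outcome of clustering samples on a marker panel."""

    assignments: pd.Series          # cluster id per sample
    contingency: pd.DataFrame | None  # clusters x true groups (when labeled)
    misclassified: dict | None      # per-group misclassified counts
    total_misclassified: int | None
    panel_genes_found: list[str]
    panel_fraction_found: float
    linkage_method: str = "ward"
    transform_tag: str = "zscore_rows"

    def to_json_dict(self) -> dict:
        return {
            "linkage_method": self.linkage_method,
            "transform_tag": self.transform_tag,
            "panel_fraction_found": self.panel_fraction_found,
            "n_panel_genes_found": len(self.panel_genes_found),
            "assignments": {k: int(v) for k, v in self.assignments.items()},
            "contingency": (None if self.contingency is None
                            else self.contingency.to_dict()),
            "misclassified": self.misclassified,
            "total_misclassified": self.total_misclassified,
        }


def _match_clusters(assign: pd.Series, labels: pd.Series):
    """Match cluster ids to group labels maximizing agreement (Hungarian)."""
    cont = pd.crosstab(assign, labels)
    cost = -cont.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    mapping = {cont.index[r]: cont.columns[c] for r, c in zip(rows, cols)}
    mis = {}
    for grp in cont.columns:
        in_group = labels == grp
        matched_clusters = [c for c, g in mapping.items() if g == grp]
        correct = assign[in_group].isin(matched_clusters).sum()
        mis[str(grp)] = int(in_group.sum() - correct)
    return cont, mis


def hierarchical_classify(expr: ExpressionMatrix, panel: Sequence[str],
                          k: int = 2, labels: pd.Series | None = None,
                          zscore: bool = True) -> PanelEvaluation:
    """Cluster samples on the panel genes with Ward linkage, cut at ``k``.

    ``expr`` should hold log-scale expression (``log2p1``); rows (genes)
    are z-scored by default so every panel gene contributes on the same
    scale.  When true ``labels`` are supplied, clusters are matched to
    groups by maximal agreement and misclassified samples counted.
    """
    panel = list(dict.fromkeys(panel))
    if not panel:
        raise ValueError("panel is empty")
    found = [g for g in panel if g in expr.values.index]
    if len(found) < 2:
        raise ValueError(
            f"need >= 2 panel genes present in the matrix, found {len(found)}")
    if expr.values.shape[1] < k:
        raise ValueError(f"need at least k={k} samples")

    sub = ExpressionMatrix(expr.values.loc[found], expr.transform_tag)
    if zscore:
        sub = sub.zscore_rows()
    data = sub.values.to_numpy().T  # samples x genes

    if k == data.shape[0]:
        assign = pd.Series(range(1, k + 1), index=expr.values.columns)
    else:
        z = linkage(data, method="ward")
        assign = pd.Series(fcluster(z, t=k, criterion="maxclust"),
                           index=expr.values.columns)

    contingency = None
    mis = None
    total = None
    if labels is not None:
        labels = pd.Series(labels, index=expr.values.columns) \
            if not isinstance(labels, pd.Series) else labels.loc[expr.values.columns]
        contingency, mis = _match_clusters(assign, labels)
        total = int(sum(mis.values()))
    return PanelEvaluation(
        assignments=assign,
        contingency=contingency,
        misclassified=mis,
        total_misclassified=total,
        panel_genes_found=found,
        panel_fraction_found=len(found) / len(panel),
        transform_tag=sub.transform_tag,
    )


def pca_project(expr: ExpressionMatrix):
    """Project samples onto PC1/PC2 of gene-centered expression.

    Genes are mean-centered (no scaling); the sign of each component is
    fixed so that its largest-magnitude gene loading is positive, making
    coordinates reproducible across runs.  Returns ``(coords, variance)``
    where ``coords`` is a samples x [PC1, PC2] DataFrame and ``variance``
    the explained-variance fractions.
    """
    vals = expr.values
    if vals.shape[1] < 3:
        raise ValueError("PCA projection needs >= 3 samples")
    if vals.shape[0] < 2:
        raise ValueError("PCA projection needs >= 2 genes")
    data = vals.to_numpy().T  # samples x genes; PCA centers the gene columns
    if np.allclose(data.std(axis=0), 0):
        raise ValueError("constant expression matrix has no principal axes")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(data)
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
            pca.components_[j] = -load
    coords = pd.DataFrame(scores, index=vals.columns, columns=["PC1", "PC2"])
    variance = pd.Series(pca.explained_variance_ratio_, index=["PC1", "PC2"])
    return coords, variance


def evaluate_panel_transfer(expr_new: ExpressionMatrix, panel: Sequence[str],
                            labels: pd.Series, k: int = 2,
                            zscore: bool = True) -> PanelEvaluation:
    """Apply a marker panel called on one cohort to cluster a new cohort.

    This is the cross-cohort validation step: cluster the new samples on
    the panel genes found in the new matrix and count per-group
    misclassification against the known labels.  Panel genes missing from
    the new matrix are reported through ``panel_fraction_found``; fewer
    than two found genes is an error.
    """
    if labels is None:
        raise ValueError("panel transfer requires known labels")
    return hierarchical_classify(expr_new, panel, k=k, labels=labels,
                                 zscore=zscore)
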