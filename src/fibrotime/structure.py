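"""Sample-level diagnostics: all-vs-all Spearman correlation with a
hierarchical ordering, and PCA of log2-RPKM profiles.

These reproduce the two standard quality views of a multi-condition RNA-seq
experiment: a rank-correlation heatmap in which replicates should form tight
blocks and cell lines should separate, and a PCA in which the leading
components capture cell line and ageing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .normalize import ExpressionMatrix


@dataclasses.dataclass
class SampleCorrelation:
    sample_ids: list
    rho: pd.DataFrame  # symmetric, unit diagonal
    order: list  # dendrogram leaf order (average linkage on 1 - rho)


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # percentages, non-increasing, sums to 100


def sample_spearman(em: ExpressionMatrix) -> SampleCorrelation:
    """Spearman rank correlation between every pair of samples.

    Mid-ranks handle ties.  Samples are ordered by average-linkage
    hierarchical clustering of the distance 1 - rho.
    """
    values = em.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    constant = values.nunique(axis=0) <= 1
    if constant.any():
        bad = list(values.columns[constant])
        raise ValueError(f"constant expression column(s), correlation undefined: {bad}")
    rho, _ = spearmanr(values.to_numpy(), axis=0)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    rho_df = pd.DataFrame(rho, index=values.columns, columns=values.columns)
    dist = squareform(1.0 - rho, checks=False)
    order_idx = leaves_list(linkage(dist, method="average"))
    order = [values.columns[i] for i in order_idx]
    return SampleCorrelation(sample_ids=list(values.columns), rho=rho_df, order=order)


def pca_samples(em: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples on gene-centered, unscaled log2-RPKM values.

    Components are ordered by explained variance; the sign convention makes
    the largest-magnitude loading of each component positive, so results are
    deterministic.  ``variance_explained`` covers all computed components and
    sums to 100%.
    """
    if em.scale != "log2rpkm":
        raise ValueError("PCA expects a log2rpkm-scale matrix")
    X = em.values.to_numpy().T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    k = min(n_samples, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    var_pct = pca.explained_variance_ratio_ * 100.0
    if n_components is not None:
        scores = scores[:, :n_components]
    scores_df = pd.DataFrame(
        scores,
        index=em.values.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PcaResult(scores=scores_df, variance_explained=var_pct)
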