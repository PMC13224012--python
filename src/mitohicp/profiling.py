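"""Phenotypic profiling of image-level feature profiles.

Standardization, principal-component analysis with variance-explained and
per-family loading contributions, and hierarchical clustering with
correlation distance — the phenotype-discrimination stage that separates
treatment groups in PC space and orders them in clustered heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .manifest import FeatureManifest

__all__ = [
    "zscore_normalize",
    "PcaResult",
    "pca_embed",
    "rank_family_contributions",
    "cluster_heatmap",
]


def zscore_normalize(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise z-scoring (population SD); zero-variance columns are
    dropped and returned in the second element.  Requires >= 2 rows."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 rows to normalize")
    means = profiles.mean()
    sds = profiles.std(ddof=0)
    dropped = sds.index[(sds == 0) | sds.isna()].tolist()
    kept = [c for c in profiles.columns if c not in dropped]
    normalized = (profiles[kept] - means[kept]) / sds[kept]
    return normalized, dropped


@dataclass
class PcaResult:
    """PCA of normalized profiles.

    ``scores``: images x k; ``loadings``: features x k (unit eigenvectors
    of the sample covariance); ``variance_explained``: fraction per kept
    component; ``variance_explained_full``: all fractions (sums to 1);
    ``dropped_features``: zero-variance columns removed upstream.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    variance_explained_full: np.ndarray
    dropped_features: list[str]


def pca_embed(
    normalized: pd.DataFrame, k: int = 2, dropped_features: list[str] | None = None
) -> PcaResult:
    """PCA on z-scored profiles with a deterministic sign convention.

    Components are eigenvectors of the sample covariance matrix; each
    component's sign is fixed so that its largest-magnitude loading is
    positive.  ``k`` beyond the matrix rank is truncated with a warning.
    """
    if len(normalized) < 2 or normalized.shape[1] < 1:
        raise ValueError("need >= 2 rows and >= 1 column")
    X = normalized.to_numpy(dtype=float)
    max_k = min(X.shape[0] - 1, X.shape[1])
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; truncating", stacklevel=2)
        k = max_k
    pca = PCA(n_components=max_k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components

    for c in range(loadings.shape[1]):
        jmax = np.argmax(np.abs(loadings[:, c]))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores[:, :k], index=normalized.index, columns=comp_names),
        loadings=pd.DataFrame(
            loadings[:, :k], index=normalized.columns, columns=comp_names
        ),
        variance_explained=pca.explained_variance_ratio_[:k],
        variance_explained_full=pca.explained_variance_ratio_,
        dropped_features=list(dropped_features or []),
    )


def rank_family_contributions(
    result: PcaResult, manifest: FeatureManifest, components: tuple[str, ...] = ("PC1", "PC2")
) -> pd.DataFrame:
    """Feature-family contributions to the leading components.

    Per family: the sum of squared loadings over the requested components,
    normalized to sum to 1 across families; returned ranked descending.
    """
    fam = manifest.family_of()
    missing = [f for f in result.loadings.index if f not in fam]
    if missing:
        raise ValueError(f"features absent from manifest: {missing[:5]}")
    comps = [c for c in components if c in result.loadings.columns]
    sq = (result.loadings[comps] ** 2).sum(axis=1)
    contrib = sq.groupby(sq.index.map(fam)).sum()
    contrib = contrib / contrib.sum()
    out = contrib.sort_values(ascending=False).rename("contribution").reset_index()
    out.columns = ["family", "contribution"]
    return out


def cluster_heatmap(
    profiles: pd.DataFrame, metric: str = "correlation", method: str = "average"
) -> dict:
    """Agglomerative clustering of profile rows for heatmap display.

    Default distance is 1 - Pearson correlation with average linkage.
    Returns the scipy linkage matrix, the dendrogram leaf order, and the
    matrix re-ordered by it.  Constant rows are incompatible with
    correlation distance and raise with advice to use euclidean.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 rows to cluster")
    X = profiles.to_numpy(dtype=float)
    if metric == "correlation" and (X.std(axis=1) == 0).any():
        bad = profiles.index[X.std(axis=1) == 0].tolist()
        raise ValueError(
            f"constant rows {bad} have undefined correlation distance; "
            "use metric='euclidean'"
        )
    dists = pdist(X, metric=metric)
    # correlation distance can dip epsilon-negative for identical rows
    dists = np.clip(dists, 0.0, None)
    Z = hierarchy.linkage(dists, method=method)
    order = hierarchy.leaves_list(Z)
    return {
        "linkage": Z,
        "order": order,
        "row_labels": [profiles.index[i] for i in order],
        "matrix": profiles.iloc[order],
    }
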