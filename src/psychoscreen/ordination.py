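"""PCA, MANOVA on PC scores, Mahalanobis group distances and group clustering.

The ordination step asks whether community composition (or the mood panel)
differs between subjects and between genders: PCA compresses the normalized
matrix, a MANOVA on the retained scores tests group separation via Wilks'
lambda, and the Mahalanobis distances between group means (under the pooled
within-group covariance) drive an average-linkage dendrogram of groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x k
    loadings: pd.DataFrame  # features x k
    explained_variance_fraction: np.ndarray  # length k
    mean_: np.ndarray


@dataclass
class ManovaResult:
    wilks_lambda: float
    dimension_d: int
    p_value: float  # Rao's F transformation (exact for d <= 2 or <= 3 groups)
    chi2_p_value: float  # Bartlett's chi-square approximation
    f_stat: float
    df1: float
    df2: float
    group_mean_distances: pd.DataFrame  # groups x groups Mahalanobis
    linkage: np.ndarray  # scipy linkage matrix over groups (sorted labels)
    group_labels: list[str]


def pca(matrix: pd.DataFrame | np.ndarray, k: int) -> PCAResult:
    """PCA by SVD of the column-centered matrix; scores are the projections
    on the top-k right singular vectors."""
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        sample_index = matrix.index
        feature_index = matrix.columns
    else:
        values = np.asarray(matrix, dtype=float)
        sample_index = pd.RangeIndex(values.shape[0])
        feature_index = pd.RangeIndex(values.shape[1])
    n, p = values.shape
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k={k} must lie in [1, min(n-1, p)={min(n - 1, p)}]")
    mean = values.mean(axis=0)
    centered = values - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s ** 2).sum())
    if total_var == 0.0:
        raise ValueError("matrix has zero total variance")
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    evf = (s[:k] ** 2) / total_var
    return PCAResult(
        scores=pd.DataFrame(scores, index=sample_index,
                            columns=[f"PC{i+1}" for i in range(k)]),
        loadings=pd.DataFrame(loadings, index=feature_index,
                              columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance_fraction=evf,
        mean_=mean,
    )


def _sscp(x: np.ndarray) -> np.ndarray:
    d = x - x.mean(axis=0)
    return d.T @ d


def mahalanobis_distance(mean_i: np.ndarray, mean_j: np.ndarray,
                         pooled_cov: np.ndarray) -> float:
    diff = np.asarray(mean_i) - np.asarray(mean_j)
    return float(np.sqrt(diff @ np.linalg.solve(pooled_cov, diff)))


def manova_groups(scores: pd.DataFrame | np.ndarray,
                  labels: Sequence) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda = det(W) / det(W + B).

    The p-value uses Rao's F transformation of lambda, which is exact when
    the score dimension is <= 2 or there are <= 3 groups (it reduces to the
    ordinary F test for d = 1, 2 groups); Bartlett's chi-square
    approximation is reported alongside. Group mean distances are
    Mahalanobis distances under the pooled within-group covariance, and the
    dendrogram is average linkage over that distance matrix with groups in
    lexicographic label order (the deterministic tie-break).
    """
    x = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels length must match number of samples")
    group_names = sorted(set(labels))
    g = len(group_names)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, d = x.shape
    groups = {name: x[labels == name] for name in group_names}
    for name, block in groups.items():
        if block.shape[0] < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    if d >= n - g + 1:
        raise ValueError(f"score dimension d={d} too large for n={n}, g={g} groups")

    w = sum(_sscp(block) for block in groups.values())
    b = _sscp(np.vstack([block.mean(axis=0, keepdims=True).repeat(block.shape[0], 0)
                         for block in groups.values()]))
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular within-group SSCP; use fewer PCA components (smaller k)")
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F transformation
    df1 = d * (g - 1)
    denom = d ** 2 + (g - 1) ** 2 - 5
    t = np.sqrt((d ** 2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    wfac = n - 1 - (d + g) / 2.0
    df2 = wfac * t - (df1 - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = float((1 - lam_t) / lam_t * df2 / df1)
    p_value = float(stats.f.sf(f_stat, df1, df2))

    chi2_stat = -wfac * np.log(lam)
    chi2_p = float(stats.chi2.sf(chi2_stat, df1))

    pooled = w / (n - g)
    dist = pd.DataFrame(0.0, index=group_names, columns=group_names)
    means = {name: block.mean(axis=0) for name, block in groups.items()}
    for i, gi in enumerate(group_names):
        for gj in group_names[i + 1:]:
            val = mahalanobis_distance(means[gi], means[gj], pooled)
            dist.loc[gi, gj] = dist.loc[gj, gi] = val
    link = hierarchy.linkage(squareform(dist.to_numpy(), checks=False),
                             method="average") if g > 1 else np.empty((0, 4))
    return ManovaResult(
        wilks_lambda=lam, dimension_d=d, p_value=p_value, chi2_p_value=chi2_p,
        f_stat=f_stat, df1=float(df1), df2=float(df2),
        group_mean_distances=dist, linkage=link, group_labels=group_names,
    )


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch
    lengths (half the merge height, as in a standard dendrogram)."""
    tree = hierarchy.to_tree(linkage, rd=False)

    def walk(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist
        length = max(parent_height - height, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        children = ",".join(walk(ch, height) for ch in (node.left, node.right))
        return f"({children}):{length:.10g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    children = ",".join(walk(ch, tree.dist) for ch in (tree.left, tree.right))
    return f"({children});"
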