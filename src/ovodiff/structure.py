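"""Sample-structure diagnostics: hierarchical clustering and PCA.

Samples are clustered with complete linkage on a distance matrix built
from the Pearson correlation between expression profiles (d = 1 - r), and
projected with centered, unscaled PCA.  The question the PCA answers here
is *which* principal component, if any, separates the two ovulation
treatments: for the proteome the treatment signal appears in a leading
component, for the transcriptome only in a minor one (or not at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pointbiserialr
from sklearn.decomposition import PCA as _SKPCA

from .datamodel import ExpressionMatrix


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    Node ids: leaf i (0 <= i < n) is node i; the k-th merge creates node
    n + k.  ``merges`` is the ordered list of (node_a, node_b, height).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        if any(h < 0 for _, _, h in self.merges):
            raise ValueError("merge heights must be non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def linkage_matrix(self) -> np.ndarray:
        """Scipy-format linkage matrix (for cutting / plotting)."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            rows.append([a, b, h, size])
        return np.asarray(rows, dtype=float)

    def cut(self, k: int) -> pd.Series:
        """Cluster labels from cutting the tree into k clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix(), t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix())
        return [self.leaves[i] for i in order]


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a sample-space PCA."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(np.diff(vf) > 1e-10):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-8:
            raise ValueError("variance fractions must sum to <= 1")
        self.variance_fraction = vf


def correlation_distance_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise sample distances d(a, b) = 1 - pearson(a, b).

    Computed on the expression values over all features; samples with a
    constant profile have undefined correlation and raise.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(
            "correlation distances require fully detected values; "
            "apply the constitutive filter / averaging first"
        )
    if np.any(vals.std(axis=0) == 0):
        const = [matrix.sample_ids[j] for j in np.flatnonzero(vals.std(axis=0) == 0)]
        raise ValueError(f"constant sample profiles have undefined correlation: {const}")
    r = np.corrcoef(vals, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Uses scipy's agglomerative implementation, whose merge order is
    deterministic for a given input ordering; ties are broken by the
    condensed-matrix position (documented tie-break).
    """
    d = distances.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains NaN/inf")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(list(distances.index), merges)


def order_features(matrix: ExpressionMatrix, metric: str = "euclidean") -> list[str]:
    """Heatmap row order: leaf order of a complete-linkage tree on
    feature-feature Euclidean distances.

    The leaf order of a dendrogram is only defined up to flips at internal
    nodes, so the traversal is canonicalized: at every node the subtree
    containing the lexicographically smallest feature id comes first.
    This makes the order a pure function of the tree, independent of the
    input row order (for distinct merge heights).
    """
    ids = matrix.feature_ids
    vals = matrix.values.to_numpy(dtype=float)
    n = len(ids)
    if n < 2:
        return list(ids)
    z = hierarchy.linkage(pdist(vals, metric=metric), method="complete")
    children = {n + k: (int(a), int(b)) for k, (a, b, _, _) in enumerate(z)}
    min_id: dict[int, str] = {i: ids[i] for i in range(n)}
    for node in range(n, n + len(children)):
        a, b = children[node]
        min_id[node] = min(min_id[a], min_id[b])
    order: list[str] = []
    stack = [n + len(children) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(ids[node])
            continue
        a, b = children[node]
        first, second = (a, b) if min_id[a] <= min_id[b] else (b, a)
        stack.extend([second, first])  # LIFO: 'first' is visited first
    return order


def pca(matrix: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """Centered, unscaled PCA with samples as observations.

    SVD of the feature-centered data; variance fractions are the
    normalized squared singular values.  All components up to the data's
    rank are retained unless ``n_components`` caps them.
    """
    x = matrix.values.to_numpy(dtype=float).T  # samples x features
    if not np.isfinite(x).all():
        raise ValueError("PCA requires fully detected values")
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if np.allclose(x, x.mean(axis=0), atol=1e-12):
        raise ValueError("all-constant matrix has no principal components")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(
            model.components_.T, index=matrix.feature_ids, columns=comp_names
        ),
        variance_fraction=model.explained_variance_ratio_,
    )


def treatment_separation(
    pca_result: PCAResult, design: pd.DataFrame
) -> tuple[pd.DataFrame, int | None]:
    """Which principal components linearly separate the two treatments?

    A component "separates" iff some scalar threshold puts all
    superovulation scores strictly on one side of all natural-ovulation
    scores.  The point-biserial correlation between scores and the
    treatment indicator is reported alongside, since perfect separation
    is brittle at small sample counts.

    Returns (per-component report, index of the first separating
    component, 1-based, or None).
    """
    design = design.loc[pca_result.scores.index]
    is_sup = (design["treatment"] == "superovulation").to_numpy()
    if is_sup.all() or not is_sup.any():
        raise ValueError("both treatment groups must be present")
    rows = []
    first = None
    for i, comp in enumerate(pca_result.scores.columns):
        s = pca_result.scores[comp].to_numpy()
        a, b = s[is_sup], s[~is_sup]
        separates = bool(a.max() < b.min() or b.max() < a.min())
        if np.std(s) == 0:
            r = 0.0
        else:
            r = float(pointbiserialr(is_sup.astype(int), s)[0])
        rows.append(
            {
                "component": comp,
                "separates": separates,
                "point_biserial_r": r,
                "variance_fraction": float(pca_result.variance_fraction[i]),
            }
        )
        if separates and first is None:
            first = i + 1
    return pd.DataFrame(rows).set_index("component"), first
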