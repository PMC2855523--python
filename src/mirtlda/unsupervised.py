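"""Sample embedding (MDS/PCA) and Eisen-style hierarchical clustering.

With Euclidean distances, classical multidimensional scaling of the
sample profiles is equivalent to principal component analysis, so the
embedding is computed by SVD of the column-centered sample matrix after
each sample has been centered by its mean and standardized by its norm.
Clustering defaults to the Eisen convention: centered Pearson
correlation distance with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError

#: distance assigned against a constant (zero-variance) profile, the
#: maximum of the correlation-distance range [0, 2]
_MAX_CORR_DISTANCE = 2.0


@dataclass
class Embedding:
    """Principal-component scores of the samples."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x n_components
    explained_variance: np.ndarray  # fraction per component
    full_coordinates: np.ndarray  # samples x rank, for distance checks


@dataclass
class ClusterTree:
    """Agglomerative dendrogram for one axis of the data matrix."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merges, heights)
    leaf_order: list[int]
    axis: str
    flagged_constant: list[str]

    def ordered_ids(self) -> list[str]:
        return [self.ids[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch
        lengths derived from merge heights."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}
        names = {i: self.ids[i].replace(" ", "_") for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            names[node] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[node] = h
        return names[n + len(self.linkage) - 1] + ";"


def center_scale_samples(matrix: np.ndarray) -> np.ndarray:
    """Center each sample (row) by its mean and divide by its centered
    vector norm; output rows have zero mean and unit norm.  Idempotent up
    to the norm rescaling (a centered unit row maps to itself)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D samples x features matrix")
    finite = np.isfinite(X)
    if np.any(finite.sum(axis=1) < 2):
        raise ValidationError("every sample needs >= 2 observed values")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(finite, X, np.nan), axis=1, keepdims=True)
    centered = np.where(finite, X - means, 0.0)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("constant sample cannot be norm-standardized")
    return centered / norms


def mds_embed(
    scaled: np.ndarray, sample_ids=None, n_components: int = 3
) -> Embedding:
    """Top principal-component scores of the scaled sample matrix.

    Pairwise Euclidean distances in the full component space equal the
    input distances (classical MDS property).  Fewer samples than
    requested components truncates with a warning.
    """
    X = np.asarray(scaled, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValidationError("need >= 4 samples to embed")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, scores.shape[1])
    if k < n_components:
        import warnings

        warnings.warn(
            f"only {k} components available, requested {n_components}",
            stacklevel=2,
        )
    return Embedding(
        sample_ids=list(sample_ids),
        coordinates=scores[:, :k],
        explained_variance=explained[:k],
        full_coordinates=scores,
    )


def _correlation_distance(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Condensed centered-Pearson distance; constant rows flagged and
    assigned the maximal distance."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    Z = Xc / safe[:, None]
    corr = np.clip(Z @ Z.T, -1.0, 1.0)
    D = 1.0 - corr
    D[constant, :] = _MAX_CORR_DISTANCE
    D[:, constant] = _MAX_CORR_DISTANCE
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False), constant


def hierarchical_cluster(
    matrix: np.ndarray,
    ids=None,
    axis: str = "samples",
    metric: str = "correlation",
    linkage_method: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of rows (axis='assays'/'items') or
    columns (axis='samples') of an items x samples matrix.

    Defaults follow the Eisen heat-map convention (centered Pearson
    distance, average linkage); Euclidean distance is available via
    ``metric='euclidean'``.  Missing values are replaced by the row mean
    before distances are computed.  Leaf order is scipy's deterministic
    dendrogram order.
    """
    X = np.asarray(matrix, dtype=float)
    if axis == "samples":
        X = X.T
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 items to cluster")
    if ids is None:
        ids = [f"item{i}" for i in range(n)]
    if len(ids) != n:
        raise ValidationError("ids length mismatch")
    # impute row means into missing cells so distances stay defined
    finite = np.isfinite(X)
    if not finite.all():
        row_mean = np.where(
            finite.any(axis=1),
            np.nanmean(np.where(finite, X, np.nan), axis=1),
            0.0,
        )
        X = np.where(finite, X, row_mean[:, None])
    flagged: list[str] = []
    if metric == "correlation":
        condensed, constant = _correlation_distance(X)
        flagged = [ids[i] for i in np.flatnonzero(constant)]
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric="euclidean")
    else:
        raise ValidationError(f"unsupported metric {metric!r}")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterTree(
        ids=list(ids),
        linkage=Z,
        leaf_order=order,
        axis=axis,
        flagged_constant=flagged,
    )


def cut_clusters(tree: ClusterTree, k: int) -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram into k groups."""
    return hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
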