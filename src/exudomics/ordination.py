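"""From-scratch constrained and unconstrained ordination plus clustering.

PCA and (partial) RDA are implemented directly on the singular value
decomposition: RDA projects the centered response matrix onto the column
space of the predictors (via a rank-revealing least-squares fit) and
eigendecomposes the fitted values, so constrained eigenvalues measure
explained variance and conservation (constrained + unconstrained
[+ conditioned] = total) holds to machine precision.  DCA is correspondence
analysis with higher axes detrended by segments.  Hierarchical clustering
of presence/absence profiles uses Euclidean distance and complete linkage
(the cited functions' defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "OrdinationResult",
    "Dendrogram",
    "pca",
    "rda",
    "partial_rda",
    "dca",
    "hierarchical_cluster",
    "shannon_diversity",
    "one_hot",
]

_EIG_TOL = 1e-12


@dataclass(frozen=True)
class OrdinationResult:
    """Ordination axes with their variance bookkeeping.

    ``site_scores`` are samples x axes; ``axis_proportions`` are eigenvalues
    relative to the total variance of the (centered) response.  For
    constrained methods, ``constrained_proportion`` is the fraction of total
    variance in the constrained space and ``residual_eigenvalues`` describe
    the unconstrained axes; ``conditioned_proportion`` is the variance
    removed by the conditioning matrix in a partial analysis.
    """

    kind: str
    site_scores: pd.DataFrame
    eigenvalues: np.ndarray
    axis_proportions: np.ndarray
    total_variance: float
    constrained_proportion: float | None = None
    conditioned_proportion: float | None = None
    residual_eigenvalues: np.ndarray | None = None
    feature_loadings: pd.DataFrame | None = None


def _as_matrix(X) -> tuple[np.ndarray, pd.Index]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index
    X = np.asarray(X, dtype=float)
    return X, pd.RangeIndex(X.shape[0])


def one_hot(labels: Sequence) -> pd.DataFrame:
    """Full (untruncated) indicator coding of a categorical vector."""
    s = pd.Series(list(labels))
    return pd.get_dummies(s, dtype=float)


def _svd_axes(M: np.ndarray, n: int):
    """Economy SVD; returns (scores U*s, eigenvalues s^2/(n-1), V)."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > _EIG_TOL * max(eig[0], 1.0) if eig.size else slice(0)
    return (U * s)[:, keep], eig[keep], Vt[keep].T


def pca(X, center: bool = True, scale: bool = False) -> OrdinationResult:
    """Principal component analysis by SVD of the (centered) data matrix.

    Eigenvalue i equals s_i^2 / (n - 1); their sum equals the total variance
    of the matrix.  A constant matrix yields no axes and is not an error.
    """
    M, index = _as_matrix(X)
    n = M.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least two samples")
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    total = float((M**2).sum() / (n - 1))
    scores, eig, V = _svd_axes(M, n)
    props = eig / total if total > 0 else np.zeros_like(eig)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    loadings = None
    if isinstance(X, pd.DataFrame):
        loadings = pd.DataFrame(V, index=X.columns, columns=cols)
    return OrdinationResult(
        kind="PCA",
        site_scores=pd.DataFrame(scores, index=index, columns=cols),
        eigenvalues=eig,
        axis_proportions=props,
        total_variance=total,
        feature_loadings=loadings,
    )


def _projector_fit(
    X: np.ndarray, Y: np.ndarray, s_min: float | None = None
) -> np.ndarray:
    """Fitted values of Y projected onto span(X) via a rank-revealing SVD.

    ``s_min`` sets the absolute singular-value cutoff; by default it is
    relative to X's own largest singular value.  Passing the scale of an
    un-residualized predictor matrix suppresses numerically null columns
    left over after partialling out a conditioning matrix.
    """
    if not np.any(X):
        return np.zeros_like(Y)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s_min is None:
        s_min = s[0] * max(X.shape) * np.finfo(float).eps
    Q = U[:, s > s_min]
    return Q @ (Q.T @ Y)


def _prep_predictors(X, n: int) -> np.ndarray:
    M, _ = _as_matrix(X)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != n:
        raise ValueError("predictor rows must match response rows")
    return M - M.mean(axis=0)


def rda(Y, X) -> OrdinationResult:
    """Redundancy analysis: ordination of Y constrained to span(X).

    Y is centered internally; X may be numeric or dummy-coded (centered
    internally, rank handled by the least-squares solver).  Constrained axes
    are the principal axes of the fitted values; residual (unconstrained)
    axes are also computed so that constrained + unconstrained variance
    equals the total variance of centered Y.
    """
    Ym, index = _as_matrix(Y)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    Xc = _prep_predictors(X, n)
    rank = np.linalg.matrix_rank(Xc)
    if rank >= n - 1 and rank > 0:
        raise ValueError("saturated model: rank(X) leaves no residual "
                         "degrees of freedom")
    total = float((Yc**2).sum() / (n - 1))
    Yhat = _projector_fit(Xc, Yc)
    scores_c, eig_c, V = _svd_axes(Yhat, n)
    resid = Yc - Yhat
    _, eig_r, _ = _svd_axes(resid, n)
    constrained = float(eig_c.sum() / total) if total > 0 else 0.0
    cols = [f"RDA{i + 1}" for i in range(scores_c.shape[1])]
    # site scores: centered response projected on the constrained axes
    wa_scores = Yc @ V
    return OrdinationResult(
        kind="RDA",
        site_scores=pd.DataFrame(wa_scores, index=index, columns=cols),
        eigenvalues=eig_c,
        axis_proportions=(eig_c / total if total > 0
                          else np.zeros_like(eig_c)),
        total_variance=total,
        constrained_proportion=constrained,
        residual_eigenvalues=eig_r,
    )


def partial_rda(Y, X, Z) -> OrdinationResult:
    """RDA of Y on X after removing the conditioning matrix Z from both.

    The variance explained by Z alone is reported as
    ``conditioned_proportion``; conditioned + constrained + unconstrained
    variance equals the total variance of centered Y.
    """
    Ym, index = _as_matrix(Y)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    Xc = _prep_predictors(X, n)
    Zc = _prep_predictors(Z, n)
    total = float((Yc**2).sum() / (n - 1))
    Yz = _projector_fit(Zc, Yc)
    Yr = Yc - Yz
    Xr = Xc - _projector_fit(Zc, Xc)
    rank = np.linalg.matrix_rank(np.hstack([Zc, Xc]))
    if rank >= n - 1 and rank > 0:
        raise ValueError("saturated model: rank([Z X]) leaves no residual "
                         "degrees of freedom")
    conditioned = float((Yz**2).sum() / (n - 1))
    # cutoff on the scale of the original predictors, so directions that
    # are numerically annihilated by the conditioning cannot resurface
    x_scale = np.linalg.norm(Xc, 2) if np.any(Xc) else 1.0
    Yhat = _projector_fit(Xr, Yr, s_min=1e-9 * max(x_scale, 1.0))
    scores_c, eig_c, V = _svd_axes(Yhat, n)
    resid = Yr - Yhat
    _, eig_r, _ = _svd_axes(resid, n)
    cols = [f"RDA{i + 1}" for i in range(scores_c.shape[1])]
    return OrdinationResult(
        kind="partialRDA",
        site_scores=pd.DataFrame(Yr @ V, index=index, columns=cols),
        eigenvalues=eig_c,
        axis_proportions=(eig_c / total if total > 0
                          else np.zeros_like(eig_c)),
        total_variance=total,
        constrained_proportion=(float(eig_c.sum() / total)
                                if total > 0 else 0.0),
        conditioned_proportion=(conditioned / total if total > 0 else 0.0),
        residual_eigenvalues=eig_r,
    )


def _ca_decomposition(M: np.ndarray):
    """Correspondence analysis of a nonnegative matrix.

    Returns row scores (standard coordinates), eigenvalues, row weights.
    """
    grand = M.sum()
    P = M / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    eig = s**2
    keep = eig > 1e-10
    # standard row coordinates: chi-square metric scores
    rows = (U[:, keep] / np.sqrt(r)[:, None])
    return rows, eig[keep], r


def _detrend_by_segments(x, against, n_segments):
    """Subtract segment means of x computed along the 'against' axis."""
    edges = np.linspace(against.min(), against.max(), n_segments + 1)
    seg = np.clip(np.digitize(against, edges[1:-1]), 0, n_segments - 1)
    out = x.copy()
    for s in np.unique(seg):
        m = seg == s
        out[m] -= out[m].mean()
    return out


def dca(community, n_axes: int = 4, n_segments: int = 26,
        max_iter: int = 100, tol: float = 1e-10) -> OrdinationResult:
    """Detrended correspondence analysis (detrending by segments, no
    nonlinear rescaling).

    Axis 1 is the plain CA axis 1.  Each subsequent axis is extracted by
    reciprocal averaging, detrended against all previously extracted axes
    using ``n_segments`` equal-width segments per pass, and normalized under
    the row-weighted metric; its eigenvalue is the contraction factor of the
    converged iteration (within [0, 1] as for CA).
    """
    M, index = _as_matrix(community)
    if (M < 0).any():
        raise ValueError("community matrix must be nonnegative")
    row_ok = M.sum(axis=1) > 0
    col_ok = M.sum(axis=0) > 0
    if not row_ok.any():
        raise ValueError("community matrix is all zero")
    M = M[np.ix_(row_ok, col_ok)]
    index = index[row_ok]
    n = M.shape[0]
    rows_ca, eig_ca, r = _ca_decomposition(M)
    n_axes = min(n_axes, rows_ca.shape[1])
    rsum = M.sum(axis=1)
    csum = M.sum(axis=0)

    def wnorm(x):
        x = x - np.sum(r * x) / r.sum()
        norm = np.sqrt(np.sum(r * x**2))
        return (x / norm if norm > 0 else x), norm

    axes = []
    eigs = []
    for a in range(n_axes):
        if a == 0:
            axes.append(rows_ca[:, 0])
            eigs.append(eig_ca[0])
            continue
        x = rows_ca[:, a].copy()
        x, _ = wnorm(x)
        lam = 0.0
        for _ in range(max_iter):
            u = (M.T @ x) / csum
            x_new = (M @ u) / rsum
            for prev in axes:
                x_new = _detrend_by_segments(x_new, prev, n_segments)
            x_new, lam = wnorm(x_new)
            if np.sum(r * (x_new - x) ** 2) < tol or \
               np.sum(r * (x_new + x) ** 2) < tol:
                x = x_new
                break
            x = x_new
        axes.append(x)
        eigs.append(min(max(lam, 0.0), 1.0))
    scores = np.column_stack(axes) if axes else np.zeros((n, 0))
    eigs = np.asarray(eigs)
    total = float(eig_ca.sum())
    cols = [f"DCA{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        kind="DCA",
        site_scores=pd.DataFrame(scores, index=index, columns=cols),
        eigenvalues=eigs,
        axis_proportions=(eigs / total if total > 0
                          else np.zeros_like(eigs)),
        total_variance=total,
    )


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence (scipy linkage encoding) plus labels."""

    merges: np.ndarray  # (n-1, 4): cluster_a, cluster_b, height, size
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix."""
        from scipy.cluster.hierarchy import cophenet

        return cophenet(self.merges)

    def to_newick(self) -> str:
        """Newick export with branch lengths derived from merge heights."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.merges, list(self.labels))
        return str(tree).strip()


def hierarchical_cluster(
    pa, metric: str = "euclidean", linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of sample profiles.

    On a binary matrix the default Euclidean metric is the square root of
    the Hamming count.  Heights are non-decreasing under complete linkage.
    """
    from .preprocess import PresenceAbsenceMatrix

    values = pa.values if isinstance(pa, PresenceAbsenceMatrix) else pa
    if isinstance(values, pd.DataFrame):
        labels = tuple(str(i) for i in values.index)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        labels = tuple(str(i) for i in range(arr.shape[0]))
    if arr.shape[0] < 2:
        raise ValueError("clustering requires at least two samples")
    merges = hierarchy.linkage(pdist(arr, metric=metric), method=linkage)
    return Dendrogram(merges=merges, labels=labels)


def shannon_diversity(cover_vector) -> float:
    """Shannon diversity H = -sum p_i ln p_i of a nonnegative cover vector."""
    x = np.asarray(cover_vector, dtype=float)
    if (x < 0).any():
        raise ValueError("covers must be nonnegative")
    if x.sum() <= 0:
        raise ValueError("cover vector sums to zero")
    return float(stats.entropy(x))
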