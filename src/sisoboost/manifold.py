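"""Supervised isometric feature mapping.

The embedding pipeline is: label-aware pairwise dissimilarity ->
k-nearest-neighbour graph (with an optional Euclidean epsilon rule) ->
connectivity repair -> all-pairs shortest paths -> classical
multidimensional scaling.  The unsupervised variant runs the same pipeline
on raw Euclidean distances.  New points are projected with a Nystrom-style
out-of-sample extension through the stored eigensystem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import (
    connected_components,
    csgraph_from_dense,
    shortest_path,
)
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

# exp() overflows float64 a bit above 709; reject before poisoning shortest paths
_MAX_EXPONENT = 700.0


class DisconnectedGraphError(ValueError):
    """Raised when shortest paths are requested on a disconnected graph."""


@dataclass
class FeatureTable:
    """N samples x D features with optional binary labels.

    Parameters
    ----------
    ids
        Opaque per-sample identifiers, one per row.
    X
        Real-valued feature matrix, shape (N, D).  Must be finite.
    y
        Optional class labels in {0, 1}; 1 marks the positive class
        (hot spot).
    """

    ids: Sequence[str]
    X: np.ndarray
    y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {self.X.shape[0]} feature rows"
            )
        bad = ~np.isfinite(self.X)
        if bad.any():
            rows = np.unique(np.nonzero(bad)[0])
            raise ValueError(
                "non-finite feature values in rows "
                + ", ".join(str(self.ids[r]) for r in rows[:10])
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must match number of rows")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")
            self.y = self.y.astype(int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class SISOMAPParams:
    """Hyperparameters of the supervised embedding.

    ``alpha`` offsets between-class dissimilarities downward (must be <= 1
    so they stay non-negative), ``beta`` scales the squared-distance
    exponent ("auto" resolves to the mean squared pairwise Euclidean
    distance of the fit data), ``k`` is the neighbour count, ``epsilon``
    the optional Euclidean edge cutoff (0 disables it) and ``d`` the
    target dimension.
    """

    k: int = 7
    epsilon: float = 0.0
    alpha: float = 0.5
    beta: Union[float, str] = "auto"
    d: int = 3

    def __post_init__(self) -> None:
        if self.alpha > 1:
            raise ValueError("alpha must be <= 1")
        if self.beta != "auto":
            self.beta = float(self.beta)
            if self.beta <= 0:
                raise ValueError("beta must be positive or 'auto'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with a supervision flag."""

    D: np.ndarray
    supervised: bool


@dataclass
class NeighborhoodGraph:
    """Undirected weighted neighbourhood graph over N samples.

    ``weights`` holds edge weights, ``np.inf`` off-edge and 0 on the
    diagonal.  ``component_labels`` records connectivity *before* repair.
    """

    weights: np.ndarray
    component_labels: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    @property
    def edges(self) -> set:
        finite = np.isfinite(self.weights)
        i, j = np.nonzero(np.triu(finite, 1))  # upper triangle, no diagonal
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class GeodesicMatrix:
    D_G: np.ndarray


@dataclass
class Embedding:
    """Fitted embedding plus everything needed for out-of-sample mapping."""

    Y: np.ndarray                    # (N, d), columns by descending eigenvalue
    eigenvalues: np.ndarray          # retained, strictly positive
    eigenvectors: np.ndarray         # (N, d)
    tau_row_means: np.ndarray        # row means of squared geodesics
    tau_grand_mean: float
    params: SISOMAPParams
    train_X: np.ndarray = field(repr=False)
    beta_: float = 0.0               # resolved beta actually used
    geodesics_: Optional[np.ndarray] = field(default=None, repr=False)
    graph_: Optional[NeighborhoodGraph] = field(default=None, repr=False)
    supervised: bool = True


def resolve_beta(X: np.ndarray) -> float:
    """Mean squared pairwise Euclidean distance over all i<j pairs."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to resolve beta")
    mean_sq = float(np.mean(pdist(X, "sqeuclidean")))
    if mean_sq == 0.0:
        raise ValueError("all points identical; beta cannot be resolved")
    return mean_sq


def pairwise_dissimilarity(
    X: np.ndarray,
    y: Optional[np.ndarray],
    alpha: float,
    beta: float,
) -> DissimilarityMatrix:
    """Label-aware pairwise dissimilarity.

    Same-class pairs (and every pair when ``y`` is None) get
    ``sqrt(1 - exp(-d^2/beta))``; different-class pairs get
    ``exp(d^2/(2*beta)) - alpha``, the half-exponent form of
    ``sqrt(exp(d^2/beta)) - alpha``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if beta <= 0:
        raise ValueError("beta must be positive")
    bad = ~np.isfinite(X)
    if bad.any():
        rows = np.unique(np.nonzero(bad)[0])
        raise ValueError(f"non-finite feature values in rows {rows.tolist()}")

    d2 = squareform(pdist(X, "sqeuclidean"))
    same = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-d2 / beta)))
    if y is None:
        D = same
        supervised = False
    else:
        y = np.asarray(y)
        diff_mask = y[:, None] != y[None, :]
        if diff_mask.any():
            max_exp = float(d2[diff_mask].max()) / (2.0 * beta)
            if max_exp > _MAX_EXPONENT:
                raise ValueError(
                    "between-class exponent d^2/(2*beta) = "
                    f"{max_exp:.3g} exceeds float range; increase beta"
                )
        D = np.where(diff_mask, np.exp(d2 / (2.0 * beta)) - alpha, same)
        supervised = True
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D=D, supervised=supervised)


def build_neighborhood_graph(
    D: DissimilarityMatrix,
    X: np.ndarray,
    k: int,
    epsilon: float = 0.0,
) -> NeighborhoodGraph:
    """k-NN graph by dissimilarity, symmetrized by union, plus an optional
    Euclidean epsilon rule.

    Neighbour selection uses the dissimilarity matrix with ties broken by
    smaller sample index; the epsilon rule adds edge (i, j) whenever the
    raw Euclidean distance is below ``epsilon``.  Edge weights are always
    the dissimilarity.
    """
    Dm = D.D
    n = Dm.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(Dm[i], kind="stable")  # stable sort = index tie-break
        order = order[order != i][:k]
        adj[i, order] = True
    adj |= adj.T  # symmetric union

    if epsilon > 0:
        eucl = squareform(pdist(np.asarray(X, dtype=float)))
        near = eucl < epsilon
        np.fill_diagonal(near, False)
        adj |= near

    weights = np.where(adj, Dm, np.inf)
    np.fill_diagonal(weights, 0.0)
    _, labels = connected_components(adj, directed=False)
    return NeighborhoodGraph(weights=weights, component_labels=labels)


def repair_connectivity(
    G: NeighborhoodGraph, D: DissimilarityMatrix
) -> NeighborhoodGraph:
    """Connect a fragmented graph by iteratively adding the globally
    minimum-dissimilarity edge between two distinct components.

    Idempotent on connected graphs; never removes edges.
    """
    weights = G.weights.copy()
    labels = G.component_labels.copy()
    n_added = 0
    while labels.max() > 0:
        cross = labels[:, None] != labels[None, :]
        masked = np.where(cross, D.D, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        weights[i, j] = weights[j, i] = D.D[i, j]
        labels[labels == labels[j]] = labels[i]
        # relabel to compact 0..m-1
        _, labels = np.unique(labels, return_inverse=True)
        n_added += 1
    if n_added:
        warnings.warn(
            f"neighbourhood graph was disconnected; added {n_added} "
            "repair edge(s)",
            stacklevel=2,
        )
    return NeighborhoodGraph(weights=weights, component_labels=labels)


def shortest_paths(G: NeighborhoodGraph) -> GeodesicMatrix:
    """Exact all-pairs shortest paths over the neighbourhood graph."""
    if G.n_components > 1:
        raise DisconnectedGraphError(
            "graph has multiple components; run repair_connectivity first"
        )
    # null_value=inf keeps genuine zero-weight edges (duplicate points)
    sparse_graph = csgraph_from_dense(G.weights, null_value=np.inf)
    D_G = shortest_path(sparse_graph, method="auto", directed=False)
    return GeodesicMatrix(D_G=D_G)


def classical_mds(D_G: GeodesicMatrix, d: int) -> Embedding:
    """Classical (Torgerson) MDS on a geodesic distance matrix.

    Double-centres the squared distances (tau = -H S H / 2), keeps the top
    ``d`` strictly positive eigenpairs and scales eigenvectors by the
    square-rooted eigenvalues.  Each eigenvector's sign is fixed so its
    largest-magnitude entry is positive.
    """
    M = np.asarray(D_G.D_G, dtype=float)
    n = M.shape[0]
    if d >= n:
        raise ValueError(f"d must be < N ({n}), got {d}")
    S = M ** 2
    row_means = S.mean(axis=1)
    grand = float(S.mean())
    tau = -0.5 * (S - row_means[:, None] - row_means[None, :] + grand)

    evals, evecs = eigh(tau)  # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = max(abs(evals[0]), abs(evals[-1])) * 1e-12
    positive = evals > tol
    if not positive.any():
        raise ValueError("no positive eigenvalues; cannot embed")
    n_keep = min(d, int(positive.sum()))
    if n_keep < d:
        warnings.warn(
            f"only {n_keep} positive eigenvalue(s); reducing embedding "
            f"dimension from {d} to {n_keep}",
            stacklevel=2,
        )
    evals = evals[:n_keep]
    evecs = evecs[:, :n_keep]
    # deterministic sign: largest-magnitude component positive
    flip = evecs[np.argmax(np.abs(evecs), axis=0), np.arange(n_keep)] < 0
    evecs[:, flip] *= -1.0
    Y = evecs * np.sqrt(evals)[None, :]
    return Embedding(
        Y=Y,
        eigenvalues=evals,
        eigenvectors=evecs,
        tau_row_means=row_means,
        tau_grand_mean=grand,
        params=SISOMAPParams(d=d),
        train_X=np.empty((0, 0)),
    )


def _fit_pipeline(
    table: FeatureTable,
    params: SISOMAPParams,
    supervised: bool,
) -> Embedding:
    X = table.X
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to fit an embedding")
    if params.d > table.n_samples - 1:
        raise ValueError("d must be <= N - 1")
    beta = resolve_beta(X) if params.beta == "auto" else float(params.beta)
    if supervised:
        if table.y is None:
            raise ValueError("supervised fit requires labels")
        D = pairwise_dissimilarity(X, table.y, params.alpha, beta)
    else:
        # unsupervised special case: raw Euclidean edge weights
        D = DissimilarityMatrix(D=squareform(pdist(X)), supervised=False)
    G = build_neighborhood_graph(D, X, params.k, params.epsilon)
    G = repair_connectivity(G, D)
    geo = shortest_paths(G)
    emb = classical_mds(geo, params.d)
    emb.params = params
    emb.train_X = X.copy()
    emb.beta_ = beta
    emb.geodesics_ = geo.D_G
    emb.graph_ = G
    emb.supervised = supervised
    return emb


def sisomap_fit(table: FeatureTable, params: SISOMAPParams) -> Embedding:
    """Fit the supervised embedding on a labelled table."""
    return _fit_pipeline(table, params, supervised=True)


def isomap_fit(
    table: FeatureTable, k: int = 7, epsilon: float = 0.0, d: int = 2
) -> Embedding:
    """Unsupervised special case: same pipeline, labels ignored.

    Edge weights are the label-free dissimilarity, a strictly increasing
    transform of Euclidean distance, so the neighbourhood structure matches
    a plain Euclidean k-NN graph.
    """
    params = SISOMAPParams(k=k, epsilon=epsilon, d=d)
    return _fit_pipeline(table, params, supervised=False)


def sisomap_transform(model: Embedding, X_new: np.ndarray) -> np.ndarray:
    """Project new points into a fitted embedding.

    Per point: label-free dissimilarities to all training points, geodesics
    routed through the point's k nearest training points over the training
    graph, then the Nystrom projection
    ``y_j = sum_i u_j[i] * (row_mean_i - g_i^2) / (2 sqrt(lambda_j))``.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    train_X = model.train_X
    n_train = train_X.shape[0]
    d_out = model.Y.shape[1]
    if X_new.size == 0:
        return np.empty((0, d_out))
    if X_new.shape[1] != train_X.shape[1]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, model expects "
            f"{train_X.shape[1]}"
        )
    if model.geodesics_ is None:
        raise ValueError("model lacks training geodesics; refit required")

    diffs = X_new[:, None, :] - train_X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diffs, diffs)
    if model.supervised:
        dissim = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-d2 / model.beta_)))
    else:
        dissim = np.sqrt(d2)

    k = min(model.params.k, n_train)
    out = np.empty((X_new.shape[0], d_out))
    inv_sqrt = 1.0 / (2.0 * np.sqrt(model.eigenvalues))
    for m in range(X_new.shape[0]):
        order = np.argsort(dissim[m], kind="stable")[:k]
        if dissim[m, order[0]] <= 1e-12:
            # exact duplicate of a training point: reuse its geodesics so
            # label-free anchors cannot shortcut the supervised metric
            g = model.geodesics_[order[0], :]
        else:
            # geodesic to every training point through the anchor neighbours
            g = np.min(
                dissim[m, order][:, None] + model.geodesics_[order, :], axis=0
            )
        centered = model.tau_row_means - g ** 2
        out[m] = (model.eigenvectors.T @ centered) * inv_sqrt
    return out


def sisomap_fit_transductive(
    table: FeatureTable, X_new: np.ndarray, params: SISOMAPParams
) -> tuple[np.ndarray, np.ndarray]:
    """Transductive alternative: refit on train + test jointly.

    Pairs of labelled training points use the supervised dissimilarity;
    any pair touching a test point falls back to the label-free branch.
    Returns (train coordinates, test coordinates).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if table.y is None:
        raise ValueError("transductive fit requires training labels")
    if X_new.shape[1] != table.n_features:
        raise ValueError("feature count mismatch")
    X_all = np.vstack([table.X, X_new])
    n_train = table.n_samples
    beta = resolve_beta(X_all) if params.beta == "auto" else float(params.beta)

    d2 = squareform(pdist(X_all, "sqeuclidean"))
    same = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-d2 / beta)))
    D = same.copy()
    yb = table.y
    diff = yb[:, None] != yb[None, :]
    if diff.any():
        max_exp = float(d2[:n_train, :n_train][diff].max()) / (2.0 * beta)
        if max_exp > _MAX_EXPONENT:
            raise ValueError("between-class exponent overflows; increase beta")
    block = d2[:n_train, :n_train]
    D[:n_train, :n_train] = np.where(
        diff, np.exp(block / (2.0 * beta)) - params.alpha, same[:n_train, :n_train]
    )
    np.fill_diagonal(D, 0.0)
    Dm = DissimilarityMatrix(D=D, supervised=True)
    G = build_neighborhood_graph(Dm, X_all, params.k, params.epsilon)
    G = repair_connectivity(G, Dm)
    emb = classical_mds(shortest_paths(G), params.d)
    return emb.Y[:n_train], emb.Y[n_train:]
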