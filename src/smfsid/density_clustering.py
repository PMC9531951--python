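"""Block 4: density-peak clustering on the trace distance matrix.

Each trace gets a local density from its k-nearest-neighbour radius,

    rho_i = quality_i * (-log r_{k,i})

(the log of the k-NN radius is a monotone transform of the k-NN density
estimate, so density *ranks* — all that density-peak clustering uses — are
preserved without estimating the intrinsic dimension; the quality ratio
weighting favours clean traces as centers).  delta_i is the distance to the
nearest strictly-denser trace, gamma_i = rho_i * delta_i ranks center
candidates, and points are swept in descending gamma: a point becomes a
center iff it lies at least r_cut = 0.3 from every previously accepted
center.  Non-centers inherit the cluster of their nearest denser neighbour;
traces with no computed denser neighbour (outliers isolated by the Block-3
prefilter) stay unassigned (label -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .trace_distance import DistanceMatrix

DEFAULT_R_CUT = 0.3
UNASSIGNED = -1


def default_k(n: int) -> int:
    """Neighbour count for the density estimate: max(10, ceil(sqrt(n)))."""
    return max(10, int(np.ceil(np.sqrt(max(n, 1)))))


@dataclass
class Clustering:
    """Full density-peak clustering state."""

    ids: list[str]
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    centers: list[int]  # indices, in acceptance (descending-gamma) order
    labels: np.ndarray  # cluster index per trace, -1 for unassigned
    k: int
    r_cut: float
    flags: dict[str, list[str]] = field(default_factory=dict)

    @property
    def center_ids(self) -> list[str]:
        return [self.ids[i] for i in self.centers]

    def members(self, cluster: int) -> list[str]:
        return [self.ids[i] for i in np.flatnonzero(self.labels == cluster)]


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Indices sorted by descending rho, ties broken by ascending index."""
    return np.lexsort((np.arange(len(rho)), -rho))


def _strictly_denser(rho: np.ndarray, i: int, j: int) -> bool:
    """Whether j outranks i in density (rho ties broken by ascending id)."""
    return rho[j] > rho[i] or (rho[j] == rho[i] and j < i)


def knn_density(D: DistanceMatrix, k: int, quality: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Quality-weighted log-kNN density rho_i = quality_i * (-log r_{k,i}).

    Uses each trace's computed neighbours only; traces with fewer than k of
    them fall back to their farthest available neighbour (flagged).  A zero
    radius (duplicate traces) is replaced by 1e-3 times the smallest positive
    distance in the matrix (flagged).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(D)
    values = D.values
    finite = values[np.isfinite(values) & (values > 0)]
    eps = float(finite.min()) * 1e-3 if len(finite) else 1e-12
    rho = np.empty(n)
    flagged: list[str] = []
    for i in range(n):
        row = values[i].copy()
        row[i] = np.inf
        neigh = np.sort(row[np.isfinite(row)])
        if len(neigh) == 0:
            rho[i] = -np.inf
            flagged.append(D.ids[i])
            continue
        if len(neigh) < k:
            r_k = neigh[-1]
            flagged.append(D.ids[i])
        else:
            r_k = neigh[k - 1]
        if r_k <= 0:
            r_k = eps
            flagged.append(D.ids[i])
        rho[i] = quality[i] * (-np.log(r_k))
    return rho, flagged


def compute_delta(rho: np.ndarray, D: DistanceMatrix) -> np.ndarray:
    """delta_i = min distance to any strictly denser point.

    The global density maximum (first in the tie-broken density order) takes
    the maximum computed distance; points whose denser neighbours are all
    uncomputed keep +inf.
    """
    n = len(rho)
    values = D.values
    finite_vals = values[np.isfinite(values)]
    d_max = float(finite_vals.max()) if len(finite_vals) else 0.0
    order = _density_order(rho)
    delta = np.full(n, np.inf)
    for rank, i in enumerate(order):
        if rank == 0:
            delta[i] = d_max
            continue
        denser = order[:rank]
        dists = values[i, denser]
        m = dists.min() if len(dists) else np.inf
        delta[i] = m
    return delta


def select_centers(
    gamma: np.ndarray, D: DistanceMatrix, r_cut: float = DEFAULT_R_CUT
) -> list[int]:
    """Sweep points by descending gamma; accept as center iff at distance
    >= r_cut from every previously accepted center (uncomputed = inf)."""
    order = np.lexsort((np.arange(len(gamma)), -gamma))
    centers: list[int] = []
    for i in order:
        if np.isnan(gamma[i]) or gamma[i] == -np.inf:
            continue  # isolated points can never seed a cluster
        ok = all(D.values[i, c] >= r_cut for c in centers)
        if ok:
            centers.append(int(i))
    return centers


def assign_clusters(rho: np.ndarray, D: DistanceMatrix, centers: list[int]) -> np.ndarray:
    """Non-centers inherit the label of their nearest computed denser
    neighbour, processed in descending density so the chain is resolved."""
    n = len(rho)
    labels = np.full(n, UNASSIGNED, dtype=int)
    for lbl, c in enumerate(centers):
        labels[c] = lbl
    order = _density_order(rho)
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)
    for rank, i in enumerate(order):
        if labels[i] != UNASSIGNED:
            continue
        denser = order[:rank]
        if len(denser) == 0:
            continue
        dists = D.values[i, denser]
        finite = np.isfinite(dists)
        if not finite.any():
            continue  # isolated: stays unassigned
        j = denser[finite][int(np.argmin(dists[finite]))]
        labels[i] = labels[j]
    return labels


def cluster_traces(
    D: DistanceMatrix,
    quality: np.ndarray,
    k: int | None = None,
    r_cut: float = DEFAULT_R_CUT,
) -> Clustering:
    """Run the full density-peak clustering on a distance matrix."""
    n = len(D)
    if n == 0:
        return Clustering([], np.array([]), np.array([]), np.array([]), [], np.array([], dtype=int), 0, r_cut)
    k = k if k is not None else default_k(n)
    rho, flagged = knn_density(D, k, np.asarray(quality, dtype=float))
    delta = compute_delta(rho, D)
    with np.errstate(invalid="ignore"):
        gamma = rho * delta
    gamma = np.where(np.isnan(gamma), -np.inf, gamma)
    centers = select_centers(gamma, D, r_cut)
    labels = assign_clusters(rho, D, centers)
    return Clustering(
        ids=list(D.ids),
        rho=rho,
        delta=delta,
        gamma=gamma,
        centers=centers,
        labels=labels,
        k=k,
        r_cut=r_cut,
        flags={"knn_fallback": flagged},
    )


class DensityPeakClustering(BaseEstimator, ClusterMixin):
    """Density-peak clustering over a precomputed trace distance matrix.

    Parameters
    ----------
    k : neighbour count for the k-NN density (None -> max(10, ceil(sqrt(n)))).
    r_cut : minimum distance between cluster centers (0.3: the distance below
        which two traces count as the same unfolding pattern).

    Attributes (after ``fit``)
    --------------------------
    rho_, delta_, gamma_ : per-trace density, separation and center rank.
    centers_ : center indices in acceptance order.
    labels_ : per-trace cluster index (-1 = unassigned outlier).
    """

    def __init__(self, k: int | None = None, r_cut: float = DEFAULT_R_CUT):
        self.k = k
        self.r_cut = r_cut

    def fit(self, X, y=None, quality=None):
        """Fit on a DistanceMatrix or a square array (inf = not computed)."""
        if isinstance(X, DistanceMatrix):
            D = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("X must be a square distance matrix")
            D = DistanceMatrix(
                ids=[str(i) for i in range(len(X))],
                values=X,
                computed_mask=np.isfinite(X),
            )
        if quality is None:
            quality = np.ones(len(D))
        result = cluster_traces(D, quality, k=self.k, r_cut=self.r_cut)
        self.clustering_ = result
        self.rho_ = result.rho
        self.delta_ = result.delta
        self.gamma_ = result.gamma
        self.centers_ = result.centers
        self.labels_ = result.labels
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_
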