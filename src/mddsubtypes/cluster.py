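"""Clustering primitives: maximin-seeded Lloyd k-means and a Ward tree.

The subtype solution itself comes from k-means whose initial centers are
chosen by a farthest-point (maximin) sweep, so the seeds cover the full range
of the data instead of collapsing into one dense region.  Hierarchical Ward
clustering (the ward.D2 convention: Euclidean, not squared, distances fed to
the Lance-Williams update) supplies the nested partitions over which the
cluster-validity indices are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage


@dataclass
class ClusterSolution:
    """A fitted k-means partition in scaled feature space."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float
    seed: int | None = None
    n_iter: int = 0
    wss_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=float)
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be nonempty")


class WardTree:
    """Agglomerative Ward (ward.D2) merge tree with exact-k cuts."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("ward_tree needs a 2-D array with n >= 2 rows")
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite values in clustering data")
        self.n = data.shape[0]
        # scipy's "ward" on raw observations implements the ward.D2 criterion
        self._linkage = linkage(data, method="ward")

    @property
    def heights(self) -> np.ndarray:
        return self._linkage[:, 2]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self._linkage
        ]

    def cut(self, k: int) -> np.ndarray:
        """Labels for exactly ``k`` clusters (cut after n-k merges)."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} outside [1, {self.n}]")
        return cut_tree(self._linkage, n_clusters=k).ravel().astype(np.int64)


def ward_tree(data: np.ndarray) -> WardTree:
    """Build the Ward merge tree over Euclidean distances."""
    return WardTree(data)


def _min_dist_to_centers(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(data[:, None, :] - centers[None, :, :], axis=2)
    return d.min(axis=1)


def maximin_init(data: np.ndarray, k: int, seed: int | None = None,
                 refine_first: bool = False) -> np.ndarray:
    """Farthest-point initial centers.

    The first center is a data point drawn uniformly at random; each
    subsequent center is the data point maximizing its minimum Euclidean
    distance to the centers already chosen (ties broken toward the lowest
    subject index).  With ``refine_first`` the random first center is replaced
    by one assign/update pass — with a single center that is the data mean —
    before the maximin sweep, a variant that re-adjusts the seed toward the
    bulk of the data.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, n={n}]")
    rng = np.random.default_rng(seed)
    first = data[rng.integers(n)]
    if refine_first:
        first = data.mean(axis=0)
    centers = [first]
    while len(centers) < k:
        dmin = _min_dist_to_centers(data, np.asarray(centers))
        centers.append(data[int(np.argmax(dmin))])  # argmax -> lowest index tie-break
    return np.asarray(centers)


def _assign(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(data[:, None, :] - centers[None, :, :], axis=2)
    return d.argmin(axis=1)  # argmin breaks ties toward the lowest cluster index


def within_sum_of_squares(data: np.ndarray, labels: np.ndarray,
                          centroids: np.ndarray) -> float:
    return float(((data - centroids[labels]) ** 2).sum())


def kmeans(data: np.ndarray, k: int | None = None,
           init_centroids: np.ndarray | None = None, *,
           seed: int | None = None, max_iter: int = 100,
           tol: float = 1e-6, refine_first: bool = False) -> ClusterSolution:
    """Lloyd's algorithm from explicit or maximin initial centers.

    Iterates assign-to-nearest-centroid / recompute-means until the maximum
    centroid displacement falls below ``tol`` or ``max_iter`` is reached.  An
    emptied cluster is reseeded at the point farthest from its currently
    assigned centroid.  The within-cluster sum of squares is non-increasing
    across iterations.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in clustering data")
    if init_centroids is None:
        if k is None:
            raise ValueError("provide k or init_centroids")
        centers = maximin_init(data, k, seed=seed, refine_first=refine_first)
    else:
        centers = np.asarray(init_centroids, dtype=float).copy()
        if k is not None and centers.shape[0] != k:
            raise ValueError("k does not match init_centroids")
        k = centers.shape[0]
        if len({tuple(c) for c in centers}) != k:
            raise ValueError("initial centroids must be distinct")
    n_iter = 0
    labels = _assign(data, centers)
    wss_history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        new_centers = centers.copy()
        for j in range(k):
            members = data[labels == j]
            if members.shape[0] == 0:
                # reseed at the point farthest from its assigned centroid
                far = int(np.argmax(
                    np.linalg.norm(data - centers[labels], axis=1)
                ))
                new_centers[j] = data[far]
            else:
                new_centers[j] = members.mean(axis=0)
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        labels = _assign(data, centers)
        wss_history.append(within_sum_of_squares(data, labels, centers))
        if shift < tol:
            break
    # final means over the final assignment so the solution is consistent
    for j in range(k):
        members = data[labels == j]
        if members.shape[0]:
            centers[j] = members.mean(axis=0)
    wss = within_sum_of_squares(data, labels, centers)
    return ClusterSolution(
        k=k, labels=labels, centroids=centers, within_ss=wss,
        seed=seed, n_iter=n_iter, wss_history=tuple(wss_history),
    )
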