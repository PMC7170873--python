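"""Subsample-reassignment stability of a cluster solution.

The procedure: fix a training partition (70% of subjects by default); on each
replicate draw a subsample (100 subjects by default) from it, re-run k-means
on the subsample, train a linear discriminant analysis (LDA) classifier on the
subsample's cluster labels, assign every subject outside the subsample with
it, and compare the completed labeling with the reference solution via the
adjusted Rand index (ARI).  The cluster-to-cluster index — the mean Euclidean
distance between optimally matched replicate and reference centroids —
measures how far the cluster centers themselves drift.  Averages over many
replicates summarise how stable the subtype solution is under resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .cluster import ClusterSolution, kmeans


@dataclass
class StabilityConfig:
    """Resampling settings; defaults match the full-scale procedure."""

    n_reps: int = 10_000
    subsample_size: int = 100
    train_fraction: float = 0.70
    k: int = 3
    seed: int | None = None
    #: "full" = ARI over all subjects (unchosen training + holdout assigned
    #: by LDA); "holdout" = ARI over subsample + 30% holdout only.
    ari_scope: str = "full"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in (0, 1]")
        if self.ari_scope not in ("full", "holdout"):
            raise ValueError("ari_scope must be 'full' or 'holdout'")


@dataclass
class StabilityReport:
    adjusted_rand: np.ndarray
    cluster_to_cluster: np.ndarray
    mean_ari: float
    mean_c2c: float
    n_skipped: int
    config: StabilityConfig


@dataclass
class LdaModel:
    """Gaussian classifier with shared (pooled, ridged) covariance."""

    classes: np.ndarray
    means: np.ndarray
    covariance: np.ndarray
    priors: np.ndarray
    _cov_inv: np.ndarray = field(repr=False, default=None)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (max' - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max' = [sum_i C(a_i,2) + sum_j C(b_j,2)] / 2, from the contingency counts
    n_ij and margins a_i, b_j.  Degenerate margins (both partitions all
    singletons or a single cluster) make the denominator vanish; by
    convention 1.0 is returned when the labelings agree pairwise and 0.0
    otherwise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0.0:
        # both all-singletons or both one cluster: agreement is exact iff the
        # pair structure matches, which it does whenever denom vanishes with
        # sum_ij == expected
        return 1.0 if sum_ij == sum_a == sum_b else 0.0
    return float((sum_ij - expected) / denom)


def fit_lda(features: np.ndarray, labels, ridge: float | None = None
            ) -> LdaModel:
    """Pooled-covariance LDA with a ridge term for ill-conditioned subsamples.

    The default ridge is 1e-6 * trace(Sigma)/p (with an absolute 1e-8 floor so
    zero within-class scatter remains solvable), added to the diagonal of the
    pooled within-class covariance.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, yi = np.unique(y, return_inverse=True)
    n, p = x.shape
    counts = np.bincount(yi)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 members: {small.tolist()}")
    means = np.vstack([x[yi == c].mean(axis=0) for c in range(classes.size)])
    pooled = np.zeros((p, p))
    for c in range(classes.size):
        d = x[yi == c] - means[c]
        pooled += d.T @ d
    pooled /= n - classes.size
    if ridge is None:
        ridge = max(1e-6 * np.trace(pooled) / p, 1e-8)
    pooled = pooled + ridge * np.eye(p)
    priors = counts / n
    return LdaModel(
        classes=classes, means=means, covariance=pooled, priors=priors,
        _cov_inv=np.linalg.inv(pooled),
    )


def assign_lda(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Assign each row to the class maximizing the linear discriminant score.

    delta_c(x) = x' Sigma^-1 mu_c - mu_c' Sigma^-1 mu_c / 2 + ln pi_c; ties go
    to the lowest class index.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if x.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    a = model._cov_inv @ model.means.T                     # p x k
    scores = x @ a - 0.5 * np.einsum("kp,pk->k", model.means, a)
    scores = scores + np.log(model.priors)
    return model.classes[np.argmax(scores, axis=1)]


def cluster_to_cluster_distance(sol_a: ClusterSolution | np.ndarray,
                                sol_b: ClusterSolution | np.ndarray) -> float:
    """Mean distance between optimally matched centroids of two solutions."""
    ca = sol_a.centroids if isinstance(sol_a, ClusterSolution) else np.asarray(sol_a)
    cb = sol_b.centroids if isinstance(sol_b, ClusterSolution) else np.asarray(sol_b)
    if ca.shape != cb.shape:
        raise ValueError("solutions must have the same k and dimension")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    return float(d[rows, cols].mean())


def run_stability(data: np.ndarray, reference: ClusterSolution,
                  config: StabilityConfig) -> StabilityReport:
    """Subsample / re-cluster / LDA-reassign stability analysis.

    Replicates with an emptied or singleton cluster (LDA unfittable) are
    recorded, skipped, and excluded from the averages.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    n_train = int(np.floor(config.train_fraction * n))
    if config.subsample_size > n_train:
        raise ValueError(
            f"subsample_size {config.subsample_size} exceeds the training "
            f"partition size {n_train}"
        )
    if reference.k != config.k:
        raise ValueError("reference solution and config disagree on k")
    root = np.random.default_rng(config.seed)
    train_idx = root.choice(n, size=n_train, replace=False)
    seeds = np.random.SeedSequence(
        root.integers(2**31)
    ).spawn(config.n_reps)

    aris, c2cs = [], []
    n_skipped = 0
    ref_labels = reference.labels
    for rep in range(config.n_reps):
        rng = np.random.default_rng(seeds[rep])
        rep_seed = int(rng.integers(2**31))
        sub_idx = rng.choice(train_idx, size=config.subsample_size,
                             replace=False)
        sol = kmeans(data[sub_idx], config.k, seed=rep_seed)
        counts = np.bincount(sol.labels, minlength=config.k)
        if (counts < 2).any():
            n_skipped += 1
            continue
        model = fit_lda(data[sub_idx], sol.labels)
        completed = np.empty(n, dtype=np.int64)
        completed[sub_idx] = sol.labels
        rest = np.setdiff1d(np.arange(n), sub_idx, assume_unique=False)
        completed[rest] = assign_lda(model, data[rest])
        if config.ari_scope == "full":
            scope = np.arange(n)
        else:
            holdout = np.setdiff1d(np.arange(n), train_idx)
            scope = np.union1d(sub_idx, holdout)
        aris.append(adjusted_rand(completed[scope], ref_labels[scope]))
        c2cs.append(cluster_to_cluster_distance(sol, reference))
    aris = np.asarray(aris)
    c2cs = np.asarray(c2cs)
    return StabilityReport(
        adjusted_rand=aris,
        cluster_to_cluster=c2cs,
        mean_ari=float(aris.mean()) if aris.size else float("nan"),
        mean_c2c=float(c2cs.mean()) if c2cs.size else float("nan"),
        n_skipped=n_skipped,
        config=config,
    )
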