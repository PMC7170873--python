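"""Number-of-clusters selection: validity-index battery, vote, permutation null.

The number of subtypes k is not estimated by a single statistic but by a
majority vote: a battery of cluster-validity indices is evaluated on the
nested Ward partitions over a k range, each index nominates its best k under
its own decision rule, and the k with the most nominations wins (ties broken
toward the smaller, more parsimonious k).  The chosen k is then tested against
an empirical null in which each item column is independently permuted —
destroying the joint structure while preserving every marginal — and the
index (Scott or Friedman by default) is recomputed on re-clustered permuted
data.

Index definitions (T, W, B are scatter matrices about the grand mean, the
cluster means, and between cluster means respectively; p = dimension):

====================  ==========================================  ===========
index                 definition                                  best k rule
====================  ==========================================  ===========
calinski_harabasz     (tr B/(k-1)) / (tr W/(n-k))                 max
scott                 n * ln(det T / det W)                       max diff
friedman              tr(W^-1 B)                                  max diff
marriot               k^2 * det W                                 max 2nd diff
trace_w               tr W                                        max 2nd diff
rubin                 det T / det W                               min 2nd diff
ball                  tr W / k                                    max diff (decreasing)
hartigan              (tr W_k/tr W_{k+1} - 1)(n-k-1)              max diff (decreasing)
kl                    |DIFF_k| / |DIFF_{k+1}|,
                      DIFF_k = (k-1)^{2/p} trW_{k-1}
                               - k^{2/p} trW_k                    max
c_index               (S_w - S_min)/(S_max - S_min)               min
silhouette            mean silhouette width                       max
davies_bouldin        mean worst within/between ratio             min
====================  ==========================================  ===========

Non-finite index values (singular within-scatter on degenerate partitions)
are flagged; an index with fewer than two finite values over the k range
casts no vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .cluster import WardTree, kmeans, ward_tree

DEFAULT_BATTERY: tuple[str, ...] = (
    "calinski_harabasz", "scott", "friedman", "marriot", "trace_w",
    "rubin", "ball", "hartigan", "kl", "c_index", "silhouette",
    "davies_bouldin",
)

# larger index value = better-separated clustering (used by the permutation
# test to orient the tail)
LARGER_IS_BETTER: dict[str, bool] = {
    "calinski_harabasz": True, "scott": True, "friedman": True,
    "marriot": False, "trace_w": False, "rubin": True, "ball": False,
    "hartigan": True, "kl": True, "c_index": False, "silhouette": True,
    "davies_bouldin": False,
}

_DECISION_RULES: dict[str, str] = {
    "calinski_harabasz": "max", "silhouette": "max", "kl": "max",
    "davies_bouldin": "min", "c_index": "min",
    "scott": "max-difference", "friedman": "max-difference",
    "ball": "max-difference", "hartigan": "max-difference",
    "marriot": "max-second-difference", "trace_w": "max-second-difference",
    "rubin": "min-second-difference",
}


@dataclass
class IndexValue:
    index_name: str
    k: int
    value: float
    decision_rule: str
    degenerate: bool = False


@dataclass
class KSelectionReport:
    k_range: tuple[int, int]
    votes: dict[str, int]
    vote_counts: dict[int, int]
    chosen_k: int
    tie_broken: bool
    strict_majority: bool
    degenerate_indices: tuple[str, ...] = ()
    index_values: list[IndexValue] = field(default_factory=list)


@dataclass
class PermutationReport:
    index_name: str
    k: int
    observed: float
    null_values: np.ndarray
    p_value: float
    seed: int | None
    n_degenerate: int = 0


def scatter_matrices(data: np.ndarray, labels: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total, within-cluster and between-cluster scatter matrices.

    T is the scatter about the grand mean, W the pooled scatter about the
    cluster means, B the scatter of cluster means about the grand mean
    weighted by cluster size; T = W + B holds elementwise.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if np.issubdtype(labels.dtype, np.integer):
        present = set(labels.tolist())
        missing = set(range(int(labels.max()) + 1)) - present
        if missing:
            raise ValueError(f"clusters {sorted(missing)} are empty")
    grand = data.mean(axis=0)
    xc = data - grand
    t = xc.T @ xc
    w = np.zeros_like(t)
    b = np.zeros_like(t)
    for g in np.unique(labels):
        members = data[labels == g]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {g} is empty")
        mu = members.mean(axis=0)
        d = members - mu
        w += d.T @ d
        mc = mu - grand
        b += members.shape[0] * np.outer(mc, mc)
    return t, w, b


def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        return -np.inf
    return ld


def _c_index(dists_sorted: np.ndarray, cum: np.ndarray, data: np.ndarray,
             labels: np.ndarray) -> float:
    # S_w = sum of within-cluster pairwise distances over N_w pairs;
    # S_min/S_max = sums of the N_w smallest/largest distances overall.
    s_w = 0.0
    n_w = 0
    for g in np.unique(labels):
        members = data[labels == g]
        if members.shape[0] > 1:
            dg = pdist(members)
            s_w += dg.sum()
            n_w += dg.size
    if n_w == 0 or n_w >= dists_sorted.size:
        return np.nan
    s_min = cum[n_w - 1]
    s_max = cum[-1] - (cum[-1 - n_w] if n_w < cum.size else 0.0)
    denom = s_max - s_min
    if denom <= 0:
        # all candidate pair sums equal (e.g. duplicated points): the index is
        # 0 when S_w already attains the minimum, undefined otherwise
        return 0.0 if s_w <= s_min else np.nan
    return (s_w - s_min) / denom


class _IndexEngine:
    """Per-k scatter quantities for one dataset and one clusterer."""

    def __init__(self, data: np.ndarray, labels_by_k: dict[int, np.ndarray]):
        self.data = np.asarray(data, dtype=float)
        self.n, self.p = self.data.shape
        self.labels_by_k = {int(k): np.asarray(v) for k, v in labels_by_k.items()}
        grand = self.data.mean(axis=0)
        xc = self.data - grand
        self.t_mat = xc.T @ xc
        self.logdet_t = _logdet(self.t_mat)
        self.trace_t = float(np.trace(self.t_mat))
        self._cache: dict[int, dict] = {}
        self._pair = None

    def _pairwise(self):
        if self._pair is None:
            d = np.sort(pdist(self.data))
            self._pair = (d, np.cumsum(d))
        return self._pair

    def stats(self, k: int) -> dict:
        if k in self._cache:
            return self._cache[k]
        labels = self.labels_by_k[k]
        if k == 1:
            w = self.t_mat
            b = np.zeros_like(w)
        else:
            _, w, b = scatter_matrices(self.data, labels)
        out = {
            "labels": labels,
            "w": w,
            "b": b,
            "trace_w": float(np.trace(w)),
            "trace_b": float(np.trace(b)),
            "logdet_w": _logdet(w),
        }
        self._cache[k] = out
        return out

    # ---- index values -----------------------------------------------------
    def value(self, index_name: str, k: int) -> float:
        n, p = self.n, self.p
        st = self.stats(k)
        if index_name == "calinski_harabasz":
            if k < 2 or st["trace_w"] == 0.0:
                return np.nan if k < 2 else np.inf
            return (st["trace_b"] / (k - 1)) / (st["trace_w"] / (n - k))
        if index_name == "scott":
            if k < 1:
                return np.nan
            return n * (self.logdet_t - st["logdet_w"])
        if index_name == "friedman":
            w = st["w"]
            # singular within-scatter: fall back to pseudo-inverse but flag
            if np.linalg.matrix_rank(w) < p:
                return np.nan
            return float(np.trace(np.linalg.solve(w, st["b"])))
        if index_name == "marriot":
            det_w = 0.0 if st["logdet_w"] == -np.inf else np.exp(st["logdet_w"])
            return k * k * det_w
        if index_name == "trace_w":
            return st["trace_w"]
        if index_name == "rubin":
            return float(np.exp(self.logdet_t - st["logdet_w"]))
        if index_name == "ball":
            return st["trace_w"] / k
        if index_name == "hartigan":
            nxt = self.stats(k + 1) if k + 1 in self.labels_by_k else None
            if nxt is None or nxt["trace_w"] == 0.0:
                return np.nan
            return (st["trace_w"] / nxt["trace_w"] - 1.0) * (n - k - 1)
        if index_name == "kl":
            def diff(kk: int) -> float:
                if kk - 1 not in self.labels_by_k or kk not in self.labels_by_k:
                    return np.nan
                tw_prev = self.stats(kk - 1)["trace_w"]
                tw = self.stats(kk)["trace_w"]
                return (kk - 1) ** (2.0 / p) * tw_prev - kk ** (2.0 / p) * tw
            d_k, d_k1 = diff(k), diff(k + 1)
            if not np.isfinite(d_k) or not np.isfinite(d_k1) or d_k1 == 0.0:
                return np.nan
            return abs(d_k / d_k1)
        if index_name == "c_index":
            dists, cum = self._pairwise()
            return _c_index(dists, cum, self.data, st["labels"])
        if index_name == "silhouette":
            if k < 2 or k >= n:
                return np.nan
            return float(silhouette_score(self.data, st["labels"]))
        if index_name == "davies_bouldin":
            if k < 2:
                return np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                v = davies_bouldin_score(self.data, st["labels"])
            return float(v)
        raise KeyError(f"unknown validity index: {index_name}")


def _ward_labels_by_k(data: np.ndarray, ks) -> dict[int, np.ndarray]:
    tree = ward_tree(data)
    return {k: tree.cut(k) for k in ks}


def validity_index(data: np.ndarray, labels_by_k: dict[int, np.ndarray],
                   index_name: str) -> list[IndexValue]:
    """Evaluate one index over the supplied per-k partitions."""
    engine = _IndexEngine(data, labels_by_k)
    rule = _DECISION_RULES[index_name]
    out = []
    for k in sorted(labels_by_k):
        with np.errstate(over="ignore"):
            v = engine.value(index_name, k)
        out.append(IndexValue(index_name, k, float(v), rule,
                              degenerate=not np.isfinite(v)))
    return out


def _best_k(index_name: str, values: dict[int, float],
            k_lo: int, k_hi: int) -> int | None:
    """Apply an index's decision rule over [k_lo, k_hi]; None if degenerate."""
    rule = _DECISION_RULES[index_name]
    ks = [k for k in range(k_lo, k_hi + 1)
          if k in values and np.isfinite(values[k])]
    if len(ks) < 2:
        return None
    finite = [values[k] for k in ks]
    if max(finite) - min(finite) == 0.0:
        return None  # flat series carries no information
    # difference rules follow the series' natural direction: Scott/Friedman
    # increase with k, Ball/Hartigan decrease
    direction_up = index_name not in ("ball", "hartigan")

    def v(k):
        return values.get(k, np.nan)

    if rule == "max":
        return max(ks, key=lambda k: (v(k), -k))
    if rule == "min":
        return min(ks, key=lambda k: (v(k), k))
    crit: dict[int, float] = {}
    for k in ks:
        if rule == "max-difference":
            prev = v(k - 1)
            if not np.isfinite(prev):
                continue
            crit[k] = (v(k) - prev) if direction_up else (prev - v(k))
        else:  # second differences
            prev, nxt = v(k - 1), v(k + 1)
            if not (np.isfinite(prev) and np.isfinite(nxt)):
                continue
            s = prev - 2.0 * v(k) + nxt
            crit[k] = -s if rule == "min-second-difference" else s
    if len(crit) == 0:
        return None
    return max(sorted(crit), key=lambda k: (crit[k], -k))


def select_k(data: np.ndarray, k_range: tuple[int, int] = (2, 6),
             battery: tuple[str, ...] = DEFAULT_BATTERY,
             clusterer: str = "ward") -> KSelectionReport:
    """Majority vote over the validity-index battery on Ward partitions.

    Ties are broken toward the smaller k.  Indices whose values are
    non-finite over (nearly) the whole range are reported as degenerate and
    excluded from the vote.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
    if k_lo == k_hi:
        return KSelectionReport(
            k_range=(k_lo, k_hi), votes={}, vote_counts={k_lo: 0},
            chosen_k=k_lo, tie_broken=False, strict_majority=False,
        )
    ext = range(max(1, k_lo - 1), min(n, k_hi + 1) + 1)
    if clusterer == "ward":
        labels_by_k = _ward_labels_by_k(data, ext)
    elif clusterer == "kmeans":
        labels_by_k = {k: kmeans(data, k, seed=k).labels for k in ext}
    else:
        raise ValueError(f"unknown clusterer {clusterer!r}")

    engine = _IndexEngine(data, labels_by_k)
    votes: dict[str, int] = {}
    degenerate: list[str] = []
    all_values: list[IndexValue] = []
    for name in battery:
        vals: dict[int, float] = {}
        for k in ext:
            with np.errstate(over="ignore"):
                vals[k] = engine.value(name, k)
            if k_lo <= k <= k_hi:
                all_values.append(IndexValue(
                    name, k, float(vals[k]), _DECISION_RULES[name],
                    degenerate=not np.isfinite(vals[k]),
                ))
        best = _best_k(name, vals, k_lo, k_hi)
        if best is None:
            degenerate.append(name)
        else:
            votes[name] = best
    if not votes:
        raise ValueError("all validity indices degenerate on this data")
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == top)
    chosen = winners[0]
    return KSelectionReport(
        k_range=(k_lo, k_hi),
        votes=votes,
        vote_counts=dict(sorted(counts.items())),
        chosen_k=chosen,
        tie_broken=len(winners) > 1,
        strict_majority=top > sum(counts.values()) / 2.0,
        degenerate_indices=tuple(degenerate),
        index_values=all_values,
    )


def permutation_test_index(data: np.ndarray, k: int,
                           index_name: str = "scott", n_perm: int = 999,
                           seed: int | None = None,
                           clusterer: str = "ward") -> PermutationReport:
    """Permutation test of the chosen k's validity index.

    The null permutes every column of the scaled data independently, which
    destroys the joint (cluster) structure while preserving each item's
    marginal distribution; each permuted dataset is re-clustered with the same
    clusterer at the same k and the index recomputed.  The p-value uses the
    add-one convention p = (1 + #{null >= observed}) / (n_perm + 1) (tail
    oriented by the index's direction), so it is never exactly 0.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)

    def index_at(x: np.ndarray) -> float:
        if clusterer == "ward":
            labels = WardTree(x).cut(k)
        elif clusterer == "kmeans":
            labels = kmeans(x, k, seed=int(rng.integers(2**31))).labels
        else:
            raise ValueError(f"unknown clusterer {clusterer!r}")
        with np.errstate(over="ignore"):
            return _IndexEngine(x, {k: labels}).value(index_name, k)

    observed = index_at(data)
    if not np.isfinite(observed):
        raise ValueError(f"{index_name} degenerate on the observed data")
    null = np.empty(n_perm)
    n_degenerate = 0
    for i in range(n_perm):
        perm = np.column_stack([rng.permutation(col) for col in data.T])
        null[i] = index_at(perm)
        if not np.isfinite(null[i]):
            n_degenerate += 1
    if n_degenerate > 0.1 * n_perm:
        raise ValueError(
            f"{index_name} degenerate on {n_degenerate}/{n_perm} permutations"
        )
    finite = null[np.isfinite(null)]
    if LARGER_IS_BETTER[index_name]:
        extreme = int((finite >= observed).sum()) + n_degenerate
    else:
        extreme = int((finite <= observed).sum()) + n_degenerate
    p = (1.0 + extreme) / (n_perm + 1.0)
    return PermutationReport(
        index_name=index_name, k=k, observed=float(observed),
        null_values=null, p_value=float(p), seed=seed,
        n_degenerate=n_degenerate,
    )
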