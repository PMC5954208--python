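"""Equal-cardinality (balanced) k-means over walker variety profiles.

Plain k-means can return wildly unequal clusters; when each cluster feeds a
fixed-size training course every cluster must hold exactly n/k walkers. The
assignment step is therefore solved as a balanced transportation problem:
each centroid gets n/k slots and points are matched to slots at minimum
total squared distance (Hungarian assignment on the point-by-slot cost
matrix). Alternating that assignment with centroid updates keeps the
within-cluster sum of squares non-increasing, so the loop terminates; the
best of ``n_restarts`` seeded k-means++ initializations is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .bouts import VarietyProfile
from .io import Session

__all__ = [
    "ClusterAssignment",
    "profiles_to_matrix",
    "standardize_features",
    "balanced_kmeans",
    "cluster_to_groups",
]


@dataclass
class ClusterAssignment:
    """Result of a balanced k-means run.

    ``labels`` maps each walker id to a cluster index in {0..k-1}; every
    cluster holds exactly n/k members. ``objective`` is the within-cluster
    sum of squared distances to the centroids.
    """

    labels: dict[Hashable, int]
    centroids: np.ndarray
    objective: float
    n_iter: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def cluster_members(self) -> list[list[Hashable]]:
        groups: list[list[Hashable]] = [[] for _ in range(self.k)]
        for wid, lab in self.labels.items():
            groups[lab].append(wid)
        return groups


def profiles_to_matrix(
    profiles: Sequence[VarietyProfile],
) -> tuple[np.ndarray, list[str]]:
    """Stack complete variety profiles into an (n, 4) feature matrix.

    Raises if any profile has an undefined dimension — callers must decide
    how to handle incomplete walkers before clustering.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X = np.array([p.as_vector() for p in profiles], dtype=float)
    return X, [p.session_id for p in profiles]


def standardize_features(X: np.ndarray, method: str = "zscore"):
    """Column-scale a feature matrix for clustering or display.

    ``zscore`` centers each column and divides by its SD (the clustering
    default); ``minmax`` maps column extremes to 0 and 1 (the display
    convention). Returns ``(X_scaled, scaler)`` where the fitted scaler
    provides ``inverse_transform``. A zero-variance column is left centered
    at 0 (zscore) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if method == "zscore":
        scaler = StandardScaler()
    elif method == "minmax":
        scaler = MinMaxScaler()
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    Xs = scaler.fit_transform(X)
    if np.any(np.ptp(X, axis=0) == 0):
        cols = np.nonzero(np.ptp(X, axis=0) == 0)[0]
        warnings.warn(f"zero-variance feature column(s) {cols.tolist()}", stacklevel=2)
    return Xs, scaler


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ spreading: first center uniform, then each next
    center drawn with probability proportional to squared distance to the
    nearest chosen center."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with a chosen center
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _balanced_assignment(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign points to centroids at minimum total squared distance with
    exactly n/k points per centroid (Hungarian matching on centroid slots)."""
    n, k = X.shape[0], centroids.shape[0]
    cap = n // k
    # cost[i, j] = squared distance from point i to the centroid owning slot j
    d2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    cost = np.repeat(d2, cap, axis=1)
    rows, cols = linear_sum_assignment(cost)
    labels = np.empty(n, dtype=int)
    labels[rows] = cols // cap
    return labels


def balanced_kmeans(
    X: np.ndarray,
    k: int = 5,
    *,
    n_restarts: int = 32,
    seed: int = 0,
    max_iter: int = 100,
    ids: Sequence[Hashable] | None = None,
) -> ClusterAssignment:
    """Cluster n points into k groups of exactly n/k each.

    Alternates a balanced transportation assignment (capacity n/k per
    cluster, squared-distance cost) with centroid updates until the
    assignment stops changing; returns the best of ``n_restarts``
    k-means++ initializations by objective. Deterministic given ``seed``
    and invariant to the input row order: rows are canonicalized by
    lexicographic sort internally, so permuting the input (with its ids)
    yields the identical partition.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n points x d features)")
    n = X.shape[0]
    if k < 1 or n % k != 0:
        raise ValueError(
            f"n={n} must be divisible by k={k}; trim or pad the cohort first"
        )
    if ids is None:
        ids = list(range(n))
    elif len(ids) != n:
        raise ValueError("ids length must match number of rows")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")

    # canonical row order makes the run independent of input permutation
    order = np.lexsort(X.T[::-1])
    Xc = X[order]
    rng = np.random.default_rng(seed)

    best_labels: np.ndarray | None = None
    best_obj = np.inf
    best_iter = 0
    for _ in range(max(1, n_restarts)):
        centroids = _kmeanspp_init(Xc, k, rng)
        labels = None
        for it in range(1, max_iter + 1):
            new_labels = _balanced_assignment(Xc, centroids)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids = np.array(
                [Xc[labels == j].mean(axis=0) for j in range(k)]
            )
        obj = float(np.sum((Xc - centroids[labels]) ** 2))
        if obj < best_obj - 1e-12:
            best_obj, best_labels, best_iter = obj, labels, it

    # renumber clusters by first canonical member for determinism
    remap: dict[int, int] = {}
    for lab in best_labels:
        if lab not in remap:
            remap[lab] = len(remap)
    canon_labels = np.array([remap[lab] for lab in best_labels])
    centroids = np.array([Xc[canon_labels == j].mean(axis=0) for j in range(k)])

    labels_by_row = np.empty(n, dtype=int)
    labels_by_row[order] = canon_labels
    return ClusterAssignment(
        labels={wid: int(lab) for wid, lab in zip(ids, labels_by_row)},
        centroids=centroids,
        objective=best_obj,
        n_iter=best_iter,
    )


def cluster_to_groups(
    assignment: ClusterAssignment, sessions: Sequence[Session]
) -> list[list[Session]]:
    """Split sessions into the k equal-size groups of an assignment.

    Each group is ready to feed a course builder. Every session id must be
    labeled.
    """
    by_id = {s.session_id: s for s in sessions}
    missing = set(by_id) - set(assignment.labels)
    if missing:
        raise ValueError(f"sessions without cluster labels: {sorted(missing)}")
    groups: list[list[Session]] = [[] for _ in range(assignment.k)]
    for s in sessions:
        groups[assignment.labels[s.session_id]].append(s)
    return groups
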