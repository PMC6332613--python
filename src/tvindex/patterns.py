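"""Fixed-length featurization of TVI profiles and k-means pattern discovery.

Profiles have variable numbers of windows, so before clustering each one is
embedded on a fixed proportion grid: every present TVI value is placed at
the grid position nearest its window proportion, collisions are averaged,
and unfilled positions receive a fill value (zero by default, i.e. the
population-average TVI — missing windows are treated as uninformative).
Euclidean k-means (Lloyd's algorithm, best of several seeded random starts)
then groups the embedded profiles; with k = 3 the clusters are named
elevated / mixed / depressed by their member profiles' mean TVI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .tvi_core import TVIProfile, window_proportion

__all__ = [
    "FeaturizationParams",
    "ClusterModel",
    "CANONICAL_LABELS",
    "featurize_profile",
    "featurize_profiles",
    "cluster_profiles",
    "label_clusters",
    "sweep_k",
]

logger = logging.getLogger(__name__)

#: Canonical k=3 labels, ordered by descending cluster-mean TVI.
CANONICAL_LABELS = ("elevated", "mixed", "depressed")


@dataclass(frozen=True)
class FeaturizationParams:
    """Proportion-grid embedding parameters.

    grid_length
        Number of grid positions L (>= 2).
    missing_fill
        Value for unfilled positions: ``"zero"`` (population-average TVI)
        or ``"profile_mean"`` (the profile's own mean TVI, for sensitivity
        analysis).
    """

    grid_length: int = 20
    missing_fill: str = "zero"

    def __post_init__(self) -> None:
        if self.grid_length < 2:
            raise ValueError("grid_length must be >= 2")
        if self.missing_fill not in ("zero", "profile_mean"):
            raise ValueError(f"unknown missing_fill {self.missing_fill!r}")


@dataclass
class ClusterModel:
    """A fitted k-means model over featurized TVI profiles."""

    k: int
    params: FeaturizationParams
    centroids: np.ndarray
    assignments: dict[str, int]
    seed: int
    n_starts: int = 10
    max_iter: int = 100
    inertia: float = 0.0
    labels: dict[int, str] = field(default_factory=dict)

    def label_of(self, case_id: str) -> str:
        cluster = self.assignments[case_id]
        return self.labels.get(cluster, f"cluster_{cluster}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "n_starts": self.n_starts,
                "max_iter": self.max_iter,
                "inertia": self.inertia,
                "params": {
                    "grid_length": self.params.grid_length,
                    "missing_fill": self.params.missing_fill,
                },
                "centroids": self.centroids.tolist(),
                "labels": {str(i): lab for i, lab in self.labels.items()},
            },
            indent=2,
        )


def featurize_profile(
    profile: TVIProfile, params: FeaturizationParams | None = None
) -> np.ndarray:
    """Embed one profile's TVI sequence on the fixed proportion grid."""
    params = params or FeaturizationParams()
    L = params.grid_length
    present = [(w.index, w.tvi) for w in profile.windows if w.tvi is not None]
    if not present:
        raise ValueError(f"profile {profile.case_id} has no TVI values")
    sums = np.zeros(L)
    counts = np.zeros(L, dtype=int)
    W = profile.n_windows
    for index, tvi in present:
        pos = int(np.floor(window_proportion(index, W) * (L - 1) + 0.5))
        sums[pos] += tvi
        counts[pos] += 1
    if params.missing_fill == "zero":
        fill = 0.0
    else:
        fill = float(np.mean([tvi for _, tvi in present]))
    out = np.full(L, fill)
    filled = counts > 0
    out[filled] = sums[filled] / counts[filled]
    return out


def featurize_profiles(
    profiles: Mapping[str, TVIProfile], params: FeaturizationParams | None = None
) -> tuple[np.ndarray, list[str]]:
    """Featurize a cohort; returns ``(X, case_ids)`` in sorted case order."""
    params = params or FeaturizationParams()
    case_ids = sorted(profiles)
    X = np.vstack([featurize_profile(profiles[c], params) for c in case_ids])
    return X, case_ids


def cluster_profiles(
    X: np.ndarray,
    case_ids: Sequence[str],
    k: int = 3,
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    params: FeaturizationParams | None = None,
) -> ClusterModel:
    """Run seeded Lloyd k-means on featurized profiles, best of ``n_starts``.

    Raises if fewer than ``k`` distinct feature vectors exist.
    """
    X = np.asarray(X, float)
    if len(X) != len(case_ids):
        raise ValueError("X and case_ids length mismatch")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct vectors, got {n_distinct}")
    km = KMeans(
        n_clusters=k,
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    assignments = {str(c): int(a) for c, a in zip(case_ids, km.labels_)}
    return ClusterModel(
        k=k,
        params=params or FeaturizationParams(),
        centroids=km.cluster_centers_.copy(),
        assignments=assignments,
        seed=seed,
        n_starts=n_starts,
        max_iter=max_iter,
        inertia=float(km.inertia_),
    )


def _cluster_mean_tvi(
    model: ClusterModel, profiles: Mapping[str, TVIProfile]
) -> dict[int, float]:
    pooled: dict[int, list[np.ndarray]] = {i: [] for i in range(model.k)}
    for case_id, cluster in model.assignments.items():
        pooled[cluster].append(profiles[case_id].tvi_values)
    means = {}
    for cluster, chunks in pooled.items():
        if not chunks:
            raise ValueError(f"cluster {cluster} has no member profiles")
        values = np.concatenate(chunks)
        means[cluster] = float(np.mean(values))
    return means


def label_clusters(
    model: ClusterModel, profiles: Mapping[str, TVIProfile]
) -> ClusterModel:
    """Attach interpretable labels, ranked by cluster-mean TVI.

    For k = 3 the canonical names elevated / mixed / depressed are assigned
    to the clusters with highest / middle / lowest mean TVI over their
    member profiles' present TVI values. A tie in mean TVI is broken by
    cluster size (the larger cluster takes the more central label) and
    logged. For any other k, clusters are named ``cluster_0`` (highest mean
    TVI) through ``cluster_{k-1}`` (lowest).
    """
    means = _cluster_mean_tvi(model, profiles)
    sizes: dict[int, int] = {i: 0 for i in range(model.k)}
    for cluster in model.assignments.values():
        sizes[cluster] += 1
    mean_values = list(means.values())
    if len(set(mean_values)) < len(mean_values):
        logger.warning(
            "tied cluster mean TVI; breaking ties by cluster size (larger = more central)"
        )
        order = sorted(means, key=lambda c: (-means[c], sizes[c]))
    else:
        order = sorted(means, key=lambda c: -means[c])
    if model.k == 3:
        labels = {cluster: CANONICAL_LABELS[rank] for rank, cluster in enumerate(order)}
    else:
        labels = {cluster: f"cluster_{rank}" for rank, cluster in enumerate(order)}
    model.labels = labels
    return model


def sweep_k(
    X: np.ndarray,
    case_ids: Sequence[str],
    ks: Sequence[int] = (2, 3, 4, 5),
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    params: FeaturizationParams | None = None,
) -> dict[int, ClusterModel]:
    """Exploratory multi-k clustering; only k=3 receives canonical names."""
    return {
        k: cluster_profiles(X, case_ids, k, n_starts, max_iter, seed, params)
        for k in ks
    }
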