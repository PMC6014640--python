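"""1-D k-medoids clustering with ++ seeding for RS-peak classification.

The selected feature values of a window are partitioned into exactly three
clusters — maternal RS-peaks, fetal RS-peaks, and other waves / noise —
using k-medoids with squared-Euclidean dissimilarity, ++ initialization
(first medoid uniform over the data; each subsequent medoid sampled with
probability proportional to the squared distance to the nearest medoid
already chosen) and a configurable number of random restarts, keeping the
restart with the lowest total cost. The fetal cluster is then identified
as the one whose median lies strictly between the medians of the other
two: noise sits lowest, maternal RS-peaks highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

ROLE_NOISE = "noise"
ROLE_FETAL = "fetal"
ROLE_MATERNAL = "maternal"


@dataclass(frozen=True)
class ClusterConfig:
    """k is fixed at 3 by the method; 20 restarts is the standard setting."""

    k: int = 3
    replicates: int = 20
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k != 3:
            raise ValueError("the method classifies into exactly 3 clusters")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ClusterResult:
    """Labels, medoids, per-cluster medians and role assignment for one window."""

    labels: np.ndarray = field(repr=False)
    medoids: np.ndarray
    medians: np.ndarray
    total_cost: float
    roles: dict[int, str] | None = None

    def cluster_of(self, role: str) -> int:
        if self.roles is None:
            raise ValueError("roles not assigned yet")
        for idx, r in self.roles.items():
            if r == role:
                return idx
        raise KeyError(role)


def _pp_seed(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ seeding: distance-proportional sampling of initial medoids."""
    medoid_idx = [int(rng.integers(values.size))]
    d2 = (values - values[medoid_idx[0]]) ** 2
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a medoid
            candidates = np.setdiff1d(np.arange(values.size), medoid_idx)
            medoid_idx.append(int(rng.choice(candidates)))
        else:
            medoid_idx.append(int(rng.choice(values.size, p=d2 / total)))
        d2 = np.minimum(d2, (values - values[medoid_idx[-1]]) ** 2)
    return np.array(medoid_idx)


def _assign(values: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    return np.argmin((values[:, None] - medoids[None, :]) ** 2, axis=1)


def _best_medoid(members: np.ndarray) -> float:
    # with squared-Euclidean cost the in-cluster sum is minimized by the
    # member closest to the cluster mean (exact in 1-D)
    mean = members.mean()
    return float(members[np.argmin(np.abs(members - mean))])


def _one_replicate(
    values: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    medoids = values[_pp_seed(values, k, rng)].astype(float)
    labels = _assign(values, medoids)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = values[labels == c]
            if members.size:
                new_medoids[c] = _best_medoid(members)
        new_labels = _assign(values, new_medoids)
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        medoids, labels = new_medoids, new_labels
    cost = float(np.sum((values - medoids[labels]) ** 2))
    return labels, medoids, cost


def kmedoids_pp(values: np.ndarray, config: ClusterConfig = ClusterConfig()) -> ClusterResult:
    """Cluster 1-D feature values into 3 groups; best of ``replicates`` restarts.

    Deterministic for a given ``config.seed``: one seeded generator drives
    all restarts in sequence. Raises on fewer than 3 distinct values.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < config.k:
        raise ValueError("degenerate clustering input: need >= 3 distinct values")
    rng = np.random.default_rng(config.seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(config.replicates):
        labels, medoids, cost = _one_replicate(values, config.k, config.max_iter, rng)
        if best is None or cost < best[2]:
            best = (labels, medoids, cost)
    labels, medoids, cost = best
    medians = np.array([np.median(values[labels == c]) for c in range(config.k)])
    return ClusterResult(labels=labels, medoids=medoids, medians=medians, total_cost=cost)


def assign_roles(result: ClusterResult) -> ClusterResult:
    """Identify the fetal cluster as the one with the in-between median.

    Smallest median -> noise, largest -> maternal, middle -> fetal. Ties
    between medians are broken by the larger medoid taking the higher role
    (with a warning).
    """
    if np.any(~np.isfinite(result.medians)):
        raise ValueError("collapsed cluster: empty cluster has no median")
    order = np.lexsort((result.medoids, result.medians))  # medoid breaks median ties
    if np.unique(result.medians).size < result.medians.size:
        logger.warning("tied cluster medians %s; larger medoid takes the higher role", result.medians)
    roles = {
        int(order[0]): ROLE_NOISE,
        int(order[1]): ROLE_FETAL,
        int(order[2]): ROLE_MATERNAL,
    }
    return replace(result, roles=roles)


__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "kmedoids_pp",
    "assign_roles",
    "ROLE_NOISE",
    "ROLE_FETAL",
    "ROLE_MATERNAL",
]
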