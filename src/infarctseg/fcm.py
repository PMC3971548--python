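"""Fuzzy C-means clustering of candidate-voxel intensities.

The surviving voxel intensities (a 1-D feature space: normalized DWI
intensity only) are partitioned into K fuzzy clusters by the conventional
FCM algorithm, minimizing

    J = sum_k sum_i  u_ik^m * (x_k - c_i)^2

by alternating membership and center updates.  The per-cluster mean
intensities of the hard members drive the downstream cluster skimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FCMConfig", "FCMResult", "fcm_cluster", "cluster_means"]

logger = logging.getLogger(__name__)


@dataclass
class FCMConfig:
    """Settings for fuzzy C-means.

    ``n_clusters`` defaults to 50, the value the cluster-number calibration
    experiment selects.  ``fuzzifier_m`` is the conventional m = 2; ``tol``
    is the convergence tolerance on the maximum center shift.
    """

    n_clusters: int = 50
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzzifier_m <= 1:
            raise ValueError("fuzzifier_m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FCMResult:
    centers: np.ndarray           # (K,) final cluster centers
    memberships: np.ndarray       # (n, K) fuzzy membership degrees
    hard_assignment: np.ndarray   # (n,) argmax-membership cluster index
    cluster_means: np.ndarray     # (K,) mean intensity of hard members
    objective_trace: np.ndarray   # J per iteration, non-increasing
    n_iter: int = 0


def _memberships(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update: u_ik ∝ d_ik^(-2/(m-1)), rows sum to 1.

    A voxel coinciding exactly with one or more centers gets its membership
    split evenly over those centers (zero-distance degeneracy).
    """
    d2 = (values[:, None] - centers[None, :]) ** 2
    zero = d2 == 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = 0.0
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_cluster(
    values: np.ndarray,
    config: FCMConfig,
    initial_centers: np.ndarray | None = None,
) -> FCMResult:
    """Cluster 1-D intensities with conventional fuzzy C-means.

    Centers are initialized by drawing ``n_clusters`` distinct sample values
    with the configured seed (the stochastic element that makes repeated runs
    informative), unless ``initial_centers`` is given explicitly.  The
    iteration stops when the maximum center shift falls below ``config.tol``
    or after ``config.max_iter`` sweeps.  Deterministic given the seed.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    k = config.n_clusters
    if values.size < k:
        raise ValueError(
            f"{values.size} values cannot support {k} clusters; lower n_clusters"
        )
    m = config.fuzzifier_m
    if initial_centers is None:
        rng = np.random.default_rng(config.seed)
        # draw distinct values where possible: duplicate centers can never
        # separate afterwards (their updates stay identical)
        uniq = np.unique(values)
        pool = uniq if uniq.size >= k else values
        centers = rng.choice(pool, size=k, replace=False).astype(np.float64)
    else:
        centers = np.asarray(initial_centers, dtype=np.float64).copy()
        if centers.shape != (k,):
            raise ValueError(f"initial_centers must have shape ({k},)")

    trace = []
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        u = _memberships(values, centers, m)
        um = u**m
        d2 = (values[:, None] - centers[None, :]) ** 2
        trace.append(float((um * d2).sum()))
        denom = um.sum(axis=0)
        new_centers = np.where(
            denom > 0, (um * values[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), centers
        )
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < config.tol:
            break

    u = _memberships(values, centers, m)
    hard = np.argmax(u, axis=1)  # ties resolve to the lowest cluster index
    result = FCMResult(
        centers=centers,
        memberships=u,
        hard_assignment=hard,
        cluster_means=np.empty(k),
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
    )
    result.cluster_means = cluster_means(result, values)
    return result


def cluster_means(result: FCMResult, values: np.ndarray) -> np.ndarray:
    """Mean intensity of each cluster's hard members.

    A cluster with no hard members keeps its center as its recorded mean,
    with a warning.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size != result.hard_assignment.size:
        raise ValueError("values and clustering result have inconsistent lengths")
    k = result.centers.size
    sums = np.bincount(result.hard_assignment, weights=values, minlength=k)
    counts = np.bincount(result.hard_assignment, minlength=k)
    means = result.centers.copy()
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty]
    if (~nonempty).any():
        logger.warning(
            "%d empty cluster(s); recording their centers as means",
            int((~nonempty).sum()),
        )
    return means
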