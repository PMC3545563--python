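"""Baseline clusterers: K-means (Lloyd), mean-shift, and Fuzzy C-Means.

These are the parametric / fixed-K comparison methods the non-parametric
pipeline is evaluated against.  They are implemented directly from their
defining updates (assignment/centroid steps for K-means, kernel-weighted
mean iteration for mean-shift, inverse-distance membership and weighted
centroid for FCM) so that their behavior is fully determined by the stated
seeds and tolerances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HardClustering",
    "FuzzyClustering",
    "kmeans",
    "meanshift",
    "fcm",
    "silverman_bandwidth",
]


@dataclass
class HardClustering:
    labels: np.ndarray
    centers: np.ndarray
    iterations: int
    objective: float

    @property
    def k(self) -> int:
        return len(self.centers)


@dataclass
class FuzzyClustering:
    memberships: np.ndarray  # N x K, rows sum to 1
    centers: np.ndarray
    fuzzifier: float
    iterations: int
    objective: float

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _as_matrix(data) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(data, "X", data), dtype=float))


def _sq_dists(X, centers) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def kmeans(data, K: int, seed: int | None = None, max_iter: int = 300
           ) -> HardClustering:
    """Lloyd's algorithm: nearest-center assignment then mean update, until
    no assignment changes.  Initial centers are K distinct points chosen by
    the seeded generator; the objective is the within-cluster sum of squares.
    """
    X = _as_matrix(data)
    n = len(X)
    if not 1 <= K <= n:
        raise ValueError("K must satisfy 1 <= K <= N")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=K, replace=False)].copy()
    labels = np.full(n, -1)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, centers)
        new_labels = np.argmin(d2, axis=1)
        for k in range(K):
            mask = new_labels == k
            if mask.any():
                centers[k] = X[mask].mean(axis=0)
            else:  # re-seed an emptied cluster at the worst-fit point
                centers[k] = X[np.argmax(d2.min(axis=1))]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    obj = float(_sq_dists(X, centers)[np.arange(n), labels].sum())
    return HardClustering(labels, centers, it, obj)


def silverman_bandwidth(X) -> float:
    """Silverman's rule-of-thumb bandwidth on (standardized) features."""
    X = _as_matrix(X)
    n, d = X.shape
    sigma = float(np.mean(X.std(axis=0, ddof=1)))
    return sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def meanshift(data, bandwidth: float | None = None, tol: float = 1e-5,
              max_iter: int = 300) -> HardClustering:
    """Gaussian-kernel mean-shift mode seeking.

    Every point is iterated to its kernel-weighted mean until the shift is
    below ``tol``; converged positions closer than bandwidth/2 are merged
    into one mode, and labels follow mode membership.
    """
    X = _as_matrix(data)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(X)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    n = len(X)
    inv2h2 = 1.0 / (2.0 * bandwidth ** 2)
    pos = X.copy()
    active = np.ones(n, dtype=bool)
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        diff = pos[active, None, :] - X[None, :, :]
        w = np.exp(-np.einsum("mnd,mnd->mn", diff, diff) * inv2h2)
        new = (w @ X) / w.sum(axis=1, keepdims=True)
        shift = np.linalg.norm(new - pos[active], axis=1)
        pos[active] = new
        still = np.zeros(n, dtype=bool)
        still[np.flatnonzero(active)[shift >= tol]] = True
        active = still
    if active.any():
        warnings.warn("mean-shift did not converge for all points; "
                      "labeling by nearest mode")
    # merge modes within bandwidth/2
    modes: list[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    for i in range(n):
        for j, m in enumerate(modes):
            if np.linalg.norm(pos[i] - m) < bandwidth / 2.0:
                labels[i] = j
                break
        else:
            modes.append(pos[i].copy())
            labels[i] = len(modes) - 1
    centers = np.array([pos[labels == j].mean(axis=0) for j in range(len(modes))])
    d2 = _sq_dists(X, centers)
    obj = float(d2[np.arange(n), labels].sum())
    return HardClustering(labels, centers, it, obj)


def fcm(data, K: int, m: float = 2.0, seed: int | None = None,
        tol: float = 1e-6, max_iter: int = 300) -> FuzzyClustering:
    """Fuzzy C-Means with fuzzifier m > 1.

    Alternates the inverse-distance membership rule (exponent 2/(m-1)) with
    the membership-weighted centroid update Q_k = sum w_k(x) x / sum w_k(x)
    until center movement falls below ``tol``.  A point coinciding with a
    center receives full membership there.
    """
    X = _as_matrix(data)
    n = len(X)
    if K < 1 or K > n:
        raise ValueError("K must satisfy 1 <= K <= N")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=K, replace=False)].copy()
    expo = 2.0 / (m - 1.0)
    U = np.full((n, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, centers)
        zero = d2 <= 1e-300
        U = np.where(zero, 1.0, 0.0)
        free = ~zero.any(axis=1)
        if free.any():
            inv = d2[free] ** (-expo / 2.0)
            U[free] = inv / inv.sum(axis=1, keepdims=True)
        W = U ** m
        new_centers = (W.T @ X) / W.sum(axis=0)[:, None]
        move = float(np.linalg.norm(new_centers - centers, axis=1).max())
        centers = new_centers
        if move < tol:
            break
    d2 = _sq_dists(X, centers)
    obj = float(np.sum((U ** m) * d2))
    return FuzzyClustering(U, centers, m, it, obj)
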