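"""Seeded generators for motion-like sensor traces and feature-space mixtures.

The study's original recordings (chest-mounted tri-axial accelerometer at
45 Hz over standing / walking / running / turning / falling / stairs /
elevator) are not publicly deposited, so this module provides two seeded
stand-ins used throughout the test bed:

* raw-signal archetypes — gravity-aligned constant orientation plus a
  per-axis sinusoid at gait frequency plus Gaussian noise, with an
  orientation transient for a fall — concatenated into labeled traces; and
* feature-space mixtures — finite Gaussian mixtures, stick-breaking
  Dirichlet-process mixtures, and constructions with an exact, controllable
  pairwise Gaussian-KLD separation.

Archetype defaults are chosen so the feature-space ordering matches the
qualitative patterns of real gait data (stand << walk < run in SVA; a fall
produces a tilt-angle discontinuity); they are this package's own settings,
not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import invwishart

from .features import FeatureMatrix
from .igmm import NIWHyperparams
from .signals import G_MS2, SensorTrace

__all__ = [
    "MotionArchetype",
    "ARCHETYPES",
    "MixtureSpec",
    "gen_trace",
    "gen_finite_mixture",
    "gen_dp_mixture",
    "gen_separated_pair",
    "gen_separated_clusters",
    "dirichlet_logdensity",
]


@dataclass
class MotionArchetype:
    """Parameters of one synthetic motion's signal model.

    The acceleration is gravity projected onto the body axes (orientation
    given as the unit gravity direction in body coordinates) plus an
    axis-wise sinusoid of given amplitude/frequency plus white noise.
    ``tilt_drift`` rotates the orientation over the segment (rad, total) —
    used for falls and turns; ``spike`` adds a short impact transient.
    """

    name: str
    gravity_dir: tuple = (0.2, 0.1, 0.97)
    amplitude: tuple = (0.0, 0.0, 0.0)  # m/s^2 per axis
    freq_hz: float = 0.0
    noise_std: float = 0.05  # m/s^2
    tilt_drift: float = 0.0  # rad rotated about y over the segment
    spike: float = 0.0  # m/s^2 impact amplitude at mid-segment

    def __post_init__(self):
        g = np.asarray(self.gravity_dir, dtype=float)
        self.gravity_dir = g / np.linalg.norm(g)
        if self.freq_hz < 0 or self.noise_std < 0:
            raise ValueError("frequency and noise std must be non-negative")


#: default archetype library (walk/run amplitudes and cadences bracket
#: ordinary human gait; the fall rotates the trunk by ~80 degrees)
ARCHETYPES = {
    "stand": MotionArchetype("stand", amplitude=(0.02, 0.02, 0.02),
                             freq_hz=0.0, noise_std=0.05),
    "walk": MotionArchetype("walk", amplitude=(1.2, 0.8, 1.5),
                            freq_hz=1.8, noise_std=0.25),
    "run": MotionArchetype("run", amplitude=(3.5, 2.5, 4.5),
                           freq_hz=2.8, noise_std=0.6),
    "fall": MotionArchetype("fall", amplitude=(0.5, 0.3, 0.5),
                            freq_hz=0.5, noise_std=0.4,
                            tilt_drift=1.4, spike=25.0),
    "turn-left": MotionArchetype("turn-left", amplitude=(0.3, 0.3, 0.3),
                                 freq_hz=0.8, noise_std=0.15,
                                 tilt_drift=0.5),
    "turn-right": MotionArchetype("turn-right", amplitude=(0.3, 0.3, 0.3),
                                  freq_hz=0.8, noise_std=0.15,
                                  tilt_drift=-0.5),
}


def _rot_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def gen_trace(segments, rate_hz: float = 45.0, seed: int | None = None
              ) -> tuple[SensorTrace, np.ndarray]:
    """Concatenate archetype segments into one labeled trace.

    ``segments`` is a sequence of (archetype-or-name, duration_s) pairs.
    Returns the trace and the per-sample true motion labels.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    acc_parts, gyro_parts, labels = [], [], []
    for arch, duration in segments:
        if isinstance(arch, str):
            arch = ARCHETYPES[arch]
        n = int(round(duration * rate_hz))
        if n < 1:
            raise ValueError(f"segment {arch.name!r} has zero duration")
        tt = np.arange(n) / rate_hz
        frac = np.linspace(0.0, 1.0, n)
        grav = np.empty((n, 3))
        if arch.tilt_drift:
            for i, f in enumerate(frac):
                grav[i] = _rot_y(arch.tilt_drift * f) @ arch.gravity_dir
        else:
            grav[:] = arch.gravity_dir
        phase = rng.uniform(0, 2 * np.pi, size=3)
        osc = np.asarray(arch.amplitude) * np.sin(
            2 * np.pi * arch.freq_hz * tt[:, None] + phase)
        acc = G_MS2 * grav + osc + rng.normal(0, arch.noise_std, size=(n, 3))
        if arch.spike:
            mid = n // 2
            width = max(2, int(0.08 * rate_hz))
            pulse = arch.spike * np.exp(
                -0.5 * ((np.arange(n) - mid) / width) ** 2)
            acc[:, 2] += pulse
        acc_parts.append(acc)
        gyro_parts.append(
            np.degrees(arch.tilt_drift / duration) * np.ones(n)
            + rng.normal(0, 1.0, size=n))
        labels.extend([arch.name] * n)
    acc = np.vstack(acc_parts)
    gyro = np.concatenate(gyro_parts)
    t = np.arange(len(acc)) / rate_hz
    trace = SensorTrace(t, acc[:, 0], acc[:, 1], acc[:, 2], gyro, rate_hz)
    return trace, np.array(labels)


# ---------------------------------------------------------------------------
# feature-space mixtures

@dataclass
class MixtureSpec:
    """Explicit finite Gaussian mixture: K means, covariances, weights."""

    means: np.ndarray
    covs: np.ndarray
    weights: np.ndarray = None
    n: int = 300
    seed: int | None = None

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        k, d = self.means.shape
        covs = np.asarray(self.covs, dtype=float)
        if covs.ndim == 2:
            covs = np.repeat(covs[None], k, axis=0)
        if covs.shape != (k, d, d):
            raise ValueError("covs must be K x D x D (or one shared D x D)")
        for c in covs:
            np.linalg.cholesky(c)
        self.covs = covs
        if self.weights is None:
            self.weights = np.full(k, 1.0 / k)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != k or np.any(self.weights < 0):
            raise ValueError("weights must be K non-negative numbers")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")


def gen_finite_mixture(spec: MixtureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw labels ~ Multinomial(weights), points ~ N(mean_k, cov_k)."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.weights), size=spec.n, p=spec.weights)
    X = np.empty((spec.n, spec.means.shape[1]))
    for k in range(len(spec.weights)):
        mask = labels == k
        if mask.any():
            X[mask] = rng.multivariate_normal(
                spec.means[k], spec.covs[k], size=int(mask.sum()),
                method="cholesky")
    return FeatureMatrix(X), labels


def gen_dp_mixture(alpha: float, base: NIWHyperparams, n: int,
                   seed: int | None = None, max_truncation: int = 10000,
                   residual: float = 1e-8) -> tuple[FeatureMatrix, np.ndarray]:
    """Stick-breaking draw from a Dirichlet-process Gaussian mixture.

    Weights w_k = v_k prod_{j<k}(1 - v_j) with v ~ Beta(1, alpha) are
    generated until the residual stick mass falls below ``residual``; atoms
    (mu_k, Sigma_k) are drawn from the NIW base measure.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    weights, rest = [], 1.0
    while rest >= residual:
        if len(weights) >= max_truncation:
            raise ValueError("stick-breaking truncation insufficient")
        v = rng.beta(1.0, alpha)
        weights.append(v * rest)
        rest *= 1.0 - v
    w = np.array(weights)
    probs = np.append(w, rest)
    probs /= probs.sum()
    labels = rng.choice(len(probs), size=n, p=probs)
    # relabel to the occupied components only, keeping order of appearance
    occupied = np.unique(labels)
    remap = {int(o): i for i, o in enumerate(occupied)}
    labels = np.array([remap[int(l)] for l in labels])
    d = base.dim
    X = np.empty((n, d))
    for o in occupied:
        sigma = invwishart.rvs(df=base.nu0, scale=base.lambda0, random_state=rng)
        sigma = np.atleast_2d(sigma)
        mu = rng.multivariate_normal(base.mu0, sigma / base.kappa0)
        mask = labels == remap[int(o)]
        X[mask] = rng.multivariate_normal(mu, sigma, size=int(mask.sum()),
                                          method="cholesky")
    return FeatureMatrix(X), labels


def gen_separated_pair(kld_target: float, d: int = 3, n: int = 200,
                       seed: int | None = None, cov: np.ndarray | None = None
                       ) -> tuple[FeatureMatrix, np.ndarray]:
    """Two equal-covariance Gaussians at an exact KLD separation.

    For shared covariance S the KLD reduces to (1/2) delta^T S^-1 delta, so
    the mean offset along the first principal axis is solved in closed form;
    n/2 points are drawn from each component.
    """
    if kld_target < 0:
        raise ValueError("kld_target must be non-negative")
    if cov is None:
        cov = np.eye(d)
    cov = np.asarray(cov, dtype=float)
    chol = np.linalg.cholesky(cov)
    # delta = sqrt(2 k) * L e1  gives  delta^T S^-1 delta = 2 k exactly
    delta = np.sqrt(2.0 * kld_target) * chol[:, 0]
    means = np.vstack([np.zeros(d), delta])
    half = n // 2
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], [half, n - half])
    X = np.vstack([
        rng.multivariate_normal(means[0], cov, size=half, method="cholesky"),
        rng.multivariate_normal(means[1], cov, size=n - half, method="cholesky"),
    ])
    perm = rng.permutation(n)
    return FeatureMatrix(X[perm]), labels[perm]


# unit-distance mean configurations (min pairwise distance exactly 1)
def _unit_config(k: int, d: int = 3) -> np.ndarray:
    if d < 3 and k > d + 1:
        raise ValueError("need D >= 3 for more than D+1 components")
    if k == 2:
        pts = [[0, 0, 0], [1, 0, 0]]
    elif k == 3:
        pts = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
    elif k == 4:  # regular tetrahedron, edge 1
        pts = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
               [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]]
    elif k == 5:
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]]
    elif k == 6:
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1],
               [1, 1, 0]]
    else:
        raise ValueError("supported component counts: 2..6")
    pts = np.array(pts, dtype=float)
    return pts[:, :d] if d <= 3 else np.pad(pts, ((0, 0), (0, d - 3)))


def gen_separated_clusters(k: int, kld_min: float, n_per: int,
                           d: int = 3, seed: int | None = None
                           ) -> tuple[FeatureMatrix, np.ndarray]:
    """K unit-covariance Gaussian clusters whose minimum pairwise KLD equals
    ``kld_min`` exactly (means scaled from a unit-distance configuration)."""
    means = _unit_config(k, d) * np.sqrt(2.0 * kld_min)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n_per)
    X = np.vstack([
        rng.multivariate_normal(means[j], np.eye(d), size=n_per,
                                method="cholesky")
        for j in range(k)
    ])
    perm = rng.permutation(len(X))
    return FeatureMatrix(X[perm]), labels[perm]


def dirichlet_logdensity(x, alpha) -> float:
    """Log Dirichlet density on the open simplex with parameter vector alpha;
    the normalizer is the multinomial beta function B(alpha)."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if x.shape != a.shape:
        raise ValueError("x and alpha must have equal length")
    if np.any(a <= 0):
        raise ValueError("alpha components must be positive")
    if np.any(x <= 0) or not np.isclose(x.sum(), 1.0, atol=1e-9):
        raise ValueError("x must lie on the open probability simplex")
    log_b = float(gammaln(a).sum() - gammaln(a.sum()))
    return float(np.sum((a - 1.0) * np.log(x)) - log_b)
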