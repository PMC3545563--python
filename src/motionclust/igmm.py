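"""Infinite Gaussian mixture model with a collapsed Gibbs sampler.

The model is a Dirichlet-process mixture of multivariate Gaussians with a
conjugate Normal-Inverse-Wishart (NIW) base measure:

    partition  ~ CRP(alpha)
    (mu_k, Sigma_k) ~ NIW(mu0, kappa0, nu0, Lambda0)
    x_i | c_i = k   ~ N(mu_k, Sigma_k)

Component means, covariances and mixing weights are integrated out
analytically, so the sampler only resamples the label vector c.  The
conditional for one label mixes the Chinese-restaurant-process prior —
an existing cluster k is chosen with probability proportional to its
occupancy n_{k,-i}, a new cluster with probability proportional to alpha —
with the cluster's posterior-predictive density, which under NIW conjugacy
is a multivariate Student-t:

    x | cluster data ~ t_{nu_n - D + 1}( mu_n, Lambda_n (kappa_n+1) /
                                         (kappa_n (nu_n - D + 1)) )

with the usual conjugate updates
    mu_n     = (kappa0 mu0 + n xbar) / (kappa0 + n)
    kappa_n  = kappa0 + n,   nu_n = nu0 + n
    Lambda_n = Lambda0 + S + kappa0 n/(kappa0+n) (xbar-mu0)(xbar-mu0)^T

where S is the scatter about the cluster mean.  The concentration alpha
carries a Gamma(a, b) hyper-prior (shape-rate) and is resampled with the
Escobar-West auxiliary-variable step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, multigammaln

__all__ = [
    "NIWHyperparams",
    "ClusterStats",
    "GibbsState",
    "GibbsTrace",
    "crp_prior",
    "crp_finite_prior",
    "niw_posterior",
    "predictive_logdensity",
    "gibbs_sweep",
    "sample_alpha",
    "log_joint",
    "fit",
]

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# prior

@dataclass(frozen=True)
class NIWHyperparams:
    """Normal-Inverse-Wishart prior (mu0, kappa0, nu0, Lambda0) for D dims."""

    mu0: np.ndarray
    kappa0: float
    nu0: float
    lambda0: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu0", np.asarray(self.mu0, dtype=float))
        lam = np.asarray(self.lambda0, dtype=float)
        object.__setattr__(self, "lambda0", lam)
        d = self.mu0.shape[0]
        if lam.shape != (d, d):
            raise ValueError("lambda0 must be D x D")
        if not np.allclose(lam, lam.T):
            raise ValueError("lambda0 must be symmetric")
        try:
            np.linalg.cholesky(lam)
        except np.linalg.LinAlgError as e:
            raise ValueError("lambda0 must be positive-definite") from e
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.nu0 <= d - 1:
            raise ValueError("nu0 must exceed D - 1")

    @property
    def dim(self) -> int:
        return self.mu0.shape[0]

    @classmethod
    def default(cls, dim: int = 3, mu0=None, kappa0: float = 0.1,
                nu0: float = 4.0, lambda_diag: float = 0.3) -> "NIWHyperparams":
        """The reference hyper-parameter set on the standardized feature scale:
        kappa0 = 0.1, nu0 = 4, Lambda0 = diag(0.3), mu0 = 0 (the empirical
        mean after standardization)."""
        if mu0 is None:
            mu0 = np.zeros(dim)
        return cls(np.asarray(mu0, float), kappa0, nu0, lambda_diag * np.eye(dim))


# ---------------------------------------------------------------------------
# per-cluster sufficient statistics and posterior predictive

class ClusterStats:
    """Sufficient statistics of one cluster with cached NIW posterior.

    Maintains n, the data sum and the sum of outer products, supporting O(D^2)
    add/remove of single observations; the posterior hyper-parameters and the
    Cholesky factor of the Student-t predictive scale are cached and rebuilt
    lazily after any update.
    """

    __slots__ = ("prior", "n", "s", "ss", "_cache")

    def __init__(self, prior: NIWHyperparams, points: np.ndarray | None = None):
        self.prior = prior
        d = prior.dim
        self.n = 0
        self.s = np.zeros(d)
        self.ss = np.zeros((d, d))
        self._cache = None
        if points is not None:
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            if pts.size:
                if not np.all(np.isfinite(pts)):
                    raise ValueError("non-finite observation")
                self.n = len(pts)
                self.s = pts.sum(axis=0)
                self.ss = pts.T @ pts

    # -- sufficient-statistic updates -----------------------------------
    def add(self, x: np.ndarray) -> None:
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite observation")
        self.n += 1
        self.s += x
        self.ss += np.outer(x, x)
        self._cache = None

    def remove(self, x: np.ndarray) -> None:
        if self.n < 1:
            raise ValueError("cannot remove from an empty cluster")
        self.n -= 1
        self.s -= x
        self.ss -= np.outer(x, x)
        self._cache = None

    # -- posterior hyper-parameters (conjugate updates) ------------------
    @property
    def mean(self) -> np.ndarray:
        """Cluster sample mean; the prior mean when empty."""
        return self.s / self.n if self.n else self.prior.mu0.copy()

    @property
    def kappa_n(self) -> float:
        return self.prior.kappa0 + self.n

    @property
    def nu_n(self) -> float:
        return self.prior.nu0 + self.n

    @property
    def mu_n(self) -> np.ndarray:
        p = self.prior
        return (p.kappa0 * p.mu0 + self.s) / (p.kappa0 + self.n)

    @property
    def lambda_n(self) -> np.ndarray:
        p = self.prior
        if self.n == 0:
            return p.lambda0.copy()
        xbar = self.s / self.n
        scatter = self.ss - self.n * np.outer(xbar, xbar)
        dev = xbar - p.mu0
        shrink = p.kappa0 * self.n / (p.kappa0 + self.n)
        lam = p.lambda0 + scatter + shrink * np.outer(dev, dev)
        return 0.5 * (lam + lam.T)  # guard symmetry against rounding

    # -- predictive ------------------------------------------------------
    def _predictive_cache(self):
        if self._cache is None:
            d = self.prior.dim
            df = self.nu_n - d + 1.0
            if df <= 0:
                raise ValueError("predictive degrees of freedom must be positive")
            scale = self.lambda_n * ((self.kappa_n + 1.0) / (self.kappa_n * df))
            try:
                chol = np.linalg.cholesky(scale)
            except np.linalg.LinAlgError as e:
                raise ValueError("predictive scale not positive-definite") from e
            logdet_half = float(np.log(np.diag(chol)).sum())
            const = (gammaln(0.5 * (df + d)) - gammaln(0.5 * df)
                     - 0.5 * d * math.log(df * math.pi) - logdet_half)
            # keep the inverse factor: predictive evaluation is the sampler's
            # hot loop and a D x D matmul beats a triangular solve at D = 3
            self._cache = (self.mu_n, np.linalg.inv(chol), df, const)
        return self._cache

    def predictive_logpdf(self, x: np.ndarray) -> float:
        """Log posterior-predictive (multivariate Student-t) density at x."""
        mu, cinv, df, const = self._predictive_cache()
        d = self.prior.dim
        w = cinv @ (x - mu)
        m = float(w @ w)
        return const - 0.5 * (df + d) * math.log1p(m / df)

    # -- marginal likelihood --------------------------------------------
    def log_marginal(self) -> float:
        """Log marginal likelihood of the cluster's n observations under the
        NIW prior (ratio of posterior to prior normalizers)."""
        p = self.prior
        d = p.dim
        if self.n == 0:
            return 0.0
        sign0, logdet0 = np.linalg.slogdet(p.lambda0)
        signn, logdetn = np.linalg.slogdet(self.lambda_n)
        return (
            -0.5 * self.n * d * LOG_2PI
            + multigammaln(0.5 * self.nu_n, d) - multigammaln(0.5 * p.nu0, d)
            + 0.5 * p.nu0 * logdet0 - 0.5 * self.nu_n * logdetn
            + 0.5 * d * (math.log(p.kappa0) - math.log(self.kappa_n))
            + 0.5 * d * (self.nu_n - p.nu0) * math.log(2.0)
        )


def niw_posterior(prior: NIWHyperparams, observations) -> ClusterStats:
    """Batch conjugate update: ClusterStats for a set of observations."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        return ClusterStats(prior)
    return ClusterStats(prior, obs)


def predictive_logdensity(x, stats: ClusterStats) -> float:
    """Log density of the multivariate Student-t posterior predictive at x."""
    return stats.predictive_logpdf(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# CRP priors

def crp_prior(counts, alpha: float) -> np.ndarray:
    """Chinese-restaurant-process conditional over K existing clusters plus a
    new one, for the point currently being placed.

    ``counts`` are the occupancies n_{k,-i} of the represented clusters with
    the point removed; the probabilities are n_{k,-i}/(alpha + N - 1) for
    existing clusters and alpha/(alpha + N - 1) for a new cluster, where
    N - 1 = sum(counts).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("represented clusters must have counts >= 1")
    denom = alpha + counts.sum()
    return np.append(counts, alpha) / denom


def crp_finite_prior(counts, alpha: float, K: int) -> np.ndarray:
    """Finite-K symmetric-Dirichlet predictive (alpha/K + n_k)/(alpha + N).

    ``counts`` may be shorter than K; unrepresented clusters count 0.  As
    K grows this converges to the CRP conditional, which is the infinite
    limit used by the sampler.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(counts, dtype=float)
    if len(counts) > K:
        raise ValueError("K must cover all represented clusters")
    full = np.zeros(K)
    full[: len(counts)] = counts
    return (alpha / K + full) / (alpha + full.sum())


# ---------------------------------------------------------------------------
# sampler state

@dataclass
class GibbsState:
    """Mutable sampler state: labels, per-cluster stats, concentration."""

    assignments: np.ndarray
    clusters: list
    alpha: float
    rng: np.random.Generator
    sweep: int = 0

    @property
    def k_plus(self) -> int:
        return len(self.clusters)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.n for c in self.clusters])

    def check(self, n_total: int) -> None:
        assert sum(c.n for c in self.clusters) == n_total, "count mismatch"
        assert all(c.n >= 1 for c in self.clusters), "empty represented cluster"

    @classmethod
    def init(cls, X: np.ndarray, prior: NIWHyperparams, alpha: float,
             rng: np.random.Generator, mode: str = "sequential") -> "GibbsState":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        if mode == "single":
            assignments = np.zeros(n, dtype=int)
            clusters = [ClusterStats(prior, X)]
        elif mode == "per-point":
            assignments = np.arange(n, dtype=int)
            clusters = [ClusterStats(prior, X[i: i + 1]) for i in range(n)]
        elif mode == "sequential":
            # place each point by sampling its CRP-predictive conditional
            # given the points already placed — the prior-predictive
            # sequential allocation; starts the chain near high-probability
            # partitions, which single-site sampling then refines
            assignments = np.empty(n, dtype=int)
            clusters = []
            empty = ClusterStats(prior)
            log_alpha = math.log(alpha)
            for i in range(n):
                x = X[i]
                kk = len(clusters)
                logp = np.empty(kk + 1)
                for j in range(kk):
                    c = clusters[j]
                    logp[j] = math.log(c.n) + c.predictive_logpdf(x)
                logp[kk] = log_alpha + empty.predictive_logpdf(x)
                g = logp - np.log(-np.log(rng.random(kk + 1)))
                k = int(np.argmax(g))
                if k == kk:
                    clusters.append(ClusterStats(prior))
                clusters[k].add(x)
                assignments[i] = k
        else:
            raise ValueError(f"unknown init mode {mode!r}")
        return cls(assignments, clusters, alpha, rng)


def gibbs_sweep(state: GibbsState, X: np.ndarray, prior: NIWHyperparams,
                order: np.ndarray | None = None) -> GibbsState:
    """One full collapsed-Gibbs pass over all points.

    Each point is removed from its cluster (empty clusters deleted and labels
    compacted), the K+1 log-probabilities CRP-log-prior + Student-t
    log-predictive are formed, and the new label drawn by Gumbel-max from the
    state's seeded generator.  ``order`` selects the scan order (default:
    index order); :func:`fit` passes a fresh random permutation each sweep,
    which leaves the stationary distribution unchanged but mixes faster
    across partitions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    rng = state.rng
    empty = ClusterStats(prior)
    log_alpha = math.log(state.alpha)
    assign = state.assignments
    clusters = state.clusters
    if order is None:
        order = range(n)
    for i in order:
        x = X[i]
        k = assign[i]
        cl = clusters[k]
        cl.remove(x)
        if cl.n == 0:
            del clusters[k]
            assign[assign > k] -= 1
        kk = len(clusters)
        logp = np.empty(kk + 1)
        for j in range(kk):
            c = clusters[j]
            logp[j] = math.log(c.n) + c.predictive_logpdf(x)
        logp[kk] = log_alpha + empty.predictive_logpdf(x)
        # Gumbel-max categorical draw; ties broken by the noise itself
        g = logp - np.log(-np.log(rng.random(kk + 1)))
        knew = int(np.argmax(g))
        if knew == kk:
            clusters.append(ClusterStats(prior))
        clusters[knew].add(x)
        assign[i] = knew
    state.sweep += 1
    return state


def sample_alpha(state: GibbsState, prior_a: float = 3.0, prior_b: float = 2.0,
                 n_total: int | None = None, resample: bool = True) -> float:
    """Escobar-West auxiliary-variable update of the DP concentration.

    The Gamma(a, b) hyper-prior uses the shape-rate convention.  With
    ``resample=False`` the current alpha is returned unchanged.
    """
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("Gamma hyper-prior parameters must be positive")
    if not resample:
        return state.alpha
    n = int(n_total) if n_total is not None else int(sum(c.n for c in state.clusters))
    k = state.k_plus
    rng = state.rng
    eta = rng.beta(state.alpha + 1.0, n)
    rate = prior_b - math.log(eta)
    w = (prior_a + k - 1.0) / (prior_a + k - 1.0 + n * rate)
    shape = prior_a + k if rng.random() < w else prior_a + k - 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def log_joint(state: GibbsState, X: np.ndarray, prior: NIWHyperparams) -> float:
    """Log joint of partition and data: CRP partition log-probability
    (the exchangeable partition probability function) plus the sum of
    per-cluster NIW marginal log-likelihoods."""
    n = len(X)
    counts = state.counts
    a = state.alpha
    lp = (state.k_plus * math.log(a) + gammaln(a) - gammaln(a + n)
          + float(np.sum(gammaln(counts))))
    lm = sum(c.log_marginal() for c in state.clusters)
    return float(lp + lm)


# ---------------------------------------------------------------------------
# full fit

@dataclass
class GibbsTrace:
    """Per-sweep record of a chain plus the MAP-sweep summary."""

    assignments: list = field(default_factory=list)
    k_plus: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    log_joint: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.k_plus)

    @property
    def map_sweep(self) -> int:
        return int(np.argmax(self.log_joint))

    @property
    def map_assignments(self) -> np.ndarray:
        return self.assignments[self.map_sweep]

    @property
    def map_k(self) -> int:
        return self.k_plus[self.map_sweep]

    def summary(self, mode: str = "map"):
        """(K, labels) from the MAP sweep (default) or the last sweep."""
        i = self.map_sweep if mode == "map" else len(self) - 1
        return self.k_plus[i], self.assignments[i]

    def stabilization_sweep(self, window: int = 10, rel_tol: float = 0.01) -> int:
        """Convergence diagnostic: first sweep at which the ``window``-sweep
        running means of both the log joint and the occupied-cluster count
        change by less than ``rel_tol`` (relative).  Returns the chain length
        if the chain never stabilizes by this measure."""
        lj = np.asarray(self.log_joint, dtype=float)
        ks = np.asarray(self.k_plus, dtype=float)
        n = len(lj)

        def running_mean(x):
            return np.array([x[max(0, i - window + 1): i + 1].mean()
                             for i in range(n)])

        rlj, rk = running_mean(lj), running_mean(ks)
        for s in range(window, n):
            dlj = abs(rlj[s] - rlj[s - 1]) < rel_tol * abs(rlj[s - 1])
            dk = abs(rk[s] - rk[s - 1]) < rel_tol * max(rk[s - 1], 1.0)
            if dlj and dk:
                return s
        return n


def fit(data, prior: NIWHyperparams | None = None, sweeps: int = 100,
        alpha_init: float = 0.5, alpha_prior: tuple = (3.0, 2.0),
        alpha_fixed: bool = False, seed: int | None = None,
        init_mode: str = "sequential") -> GibbsTrace:
    """Run the collapsed Gibbs sampler and record the chain.

    ``data`` may be a FeatureMatrix or an (N, D) array.  Each sweep scans
    the points in a fresh random order.  Returns the per-sweep trace; the
    reported clustering is the sweep with the highest log joint (MAP sweep).
    """
    X = np.atleast_2d(np.asarray(getattr(data, "X", data), dtype=float))
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    d = X.shape[1]
    if prior is None:
        prior = NIWHyperparams.default(d)
    rng = np.random.default_rng(seed)
    state = GibbsState.init(X, prior, alpha_init, rng, mode=init_mode)
    trace = GibbsTrace()
    a, b = alpha_prior
    for _ in range(sweeps):
        gibbs_sweep(state, X, prior, order=rng.permutation(len(X)))
        state.alpha = sample_alpha(state, a, b, n_total=len(X),
                                   resample=not alpha_fixed)
        trace.assignments.append(state.assignments.copy())
        trace.k_plus.append(state.k_plus)
        trace.alpha.append(state.alpha)
        trace.log_joint.append(log_joint(state, X, prior))
    return trace
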