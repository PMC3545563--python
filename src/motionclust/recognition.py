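"""Cluster-to-motion mapping via Gaussian KL divergence, plus the metrics.

Discovered clusters are anonymous; to name them, each cluster's empirical
Gaussian is compared against a library of reference motion profiles
(per-motion mean and covariance in the same standardized feature space) and
assigned the profile with minimum KL divergence.  A cluster whose best KLD
exceeds a threshold tau is declared an unforeseen motion (``new-motion``) —
the behavior that lets the non-parametric pipeline flag, e.g., a fall that
occurs during walking without a fall profile ever having been supplied.

Three evaluation metrics are reported:

* Type 1 — percentage of trials in which the inferred number of motions
  equals the true number;
* Type 2 — percentage of points assigned to their correct motion (hit
  accuracy), under the optimal one-to-one cluster/motion matching when
  cluster names are absent;
* Type 3 — percentage of points assigned incorrectly (false alarm),
  complementary to Type 2 per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MotionProfile",
    "RecognitionResult",
    "kld_gaussian",
    "cluster_gaussian",
    "map_clusters",
    "type1_hit_rate",
    "type2_hit_accuracy",
    "per_class_accuracy",
    "MetricsReport",
    "evaluate",
]

NEW_MOTION = "new-motion"


@dataclass
class MotionProfile:
    """Reference Gaussian for one named motion in standardized feature space."""

    name: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("covariance must be D x D")
        np.linalg.cholesky(self.cov)  # SPD check


def save_profiles(profiles, path) -> None:
    payload = [
        {"name": p.name, "mean": p.mean.tolist(), "cov": p.cov.tolist()}
        for p in profiles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_profiles(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [MotionProfile(d["name"], np.array(d["mean"]), np.array(d["cov"]))
            for d in payload]


def kld_gaussian(mean1, cov1, mean2, cov2) -> float:
    """KL(N1 || N2) between multivariate Gaussians, closed form:

    1/2 [ tr(S2^-1 S1) + (m2-m1)^T S2^-1 (m2-m1) - D + ln(det S2 / det S1) ]
    """
    m1 = np.asarray(mean1, dtype=float)
    m2 = np.asarray(mean2, dtype=float)
    s1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    s2 = np.atleast_2d(np.asarray(cov2, dtype=float))
    d = m1.shape[0]
    try:
        c2 = np.linalg.cholesky(s2)
        c1 = np.linalg.cholesky(s1)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariances must be positive-definite") from e
    # tr(S2^-1 S1) via the Cholesky factors
    a = np.linalg.solve(c2, c1)
    trace_term = float(np.sum(a * a))
    w = np.linalg.solve(c2, m2 - m1)
    maha = float(w @ w)
    logdet = 2.0 * float(np.log(np.diag(c2)).sum() - np.log(np.diag(c1)).sum())
    return max(0.0, 0.5 * (trace_term + maha - d + logdet))


def cluster_gaussian(data, assignments, cluster_id: int,
                     eps: float = 1e-6) -> tuple:
    """Empirical (mean, covariance) of one cluster's feature vectors.

    Clusters too small for a full-rank covariance (fewer than D + 1 points,
    or degenerate) are regularized by adding eps * I.
    """
    X = np.atleast_2d(np.asarray(getattr(data, "X", data), dtype=float))
    mask = np.asarray(assignments) == cluster_id
    if not mask.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    pts = X[mask]
    mean = pts.mean(axis=0)
    d = X.shape[1]
    if len(pts) >= 2:
        cov = np.cov(pts, rowvar=False).reshape(d, d)
    else:
        cov = np.zeros((d, d))
    if len(pts) < d + 1 or np.linalg.eigvalsh(cov).min() <= eps:
        cov = cov + eps * np.eye(d)
    return mean, cov


@dataclass
class RecognitionResult:
    """Outcome of mapping clusters onto motion profiles."""

    cluster_to_motion: dict
    min_kld: dict
    kld_table: dict = field(default_factory=dict)

    def label_points(self, assignments) -> np.ndarray:
        """Per-point motion names inherited from each point's cluster."""
        return np.array([self.cluster_to_motion[int(c)] for c in assignments])

    @property
    def duplicates(self) -> list:
        """Motion names claimed by more than one cluster (many-to-one)."""
        names = [m for m in self.cluster_to_motion.values() if m != NEW_MOTION]
        return sorted({m for m in names if names.count(m) > 1})


def map_clusters(cluster_gaussians: dict, profiles, tau: float = 10.0
                 ) -> RecognitionResult:
    """Assign each cluster the profile of minimum KLD; above tau -> new-motion.

    ``cluster_gaussians`` maps cluster id -> (mean, cov).  Many clusters may
    map to the same motion; duplicates are reported, not forbidden.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one motion profile is required")
    mapping, min_kld, table = {}, {}, {}
    for cid, (mean, cov) in cluster_gaussians.items():
        klds = {p.name: kld_gaussian(mean, cov, p.mean, p.cov) for p in profiles}
        best = min(klds, key=klds.get)
        table[cid] = klds
        min_kld[cid] = klds[best]
        mapping[cid] = best if klds[best] <= tau else NEW_MOTION
    return RecognitionResult(mapping, min_kld, table)


# ---------------------------------------------------------------------------
# metrics

def type1_hit_rate(predicted_ks, true_k: int) -> float:
    """Percentage of trials whose inferred cluster count equals the truth."""
    ks = np.asarray(predicted_ks)
    if ks.size == 0:
        raise ValueError("no trials supplied")
    return 100.0 * float(np.mean(ks == true_k))


def _contingency(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(true, return_inverse=True)
    table = np.zeros((len(pu), len(tu)), dtype=int)
    np.add.at(table, (pi, ti), 1)
    return table, pu, tu


def type2_hit_accuracy(pred, true) -> float:
    """Percentage of points in their correct cluster under the optimal
    one-to-one cluster/class matching (Hungarian assignment)."""
    table, _, _ = _contingency(pred, true)
    r, c = linear_sum_assignment(-table)
    return 100.0 * table[r, c].sum() / len(np.asarray(pred))


def per_class_accuracy(pred_names, true_names) -> dict:
    """Per-motion hit accuracy and false alarm for *named* labels.

    hit_c = % of class-c points whose predicted name equals c;
    false_alarm_c = 100 - hit_c (the misassigned fraction of class c).
    """
    pred = np.asarray(pred_names)
    true = np.asarray(true_names)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    out = {}
    for cls in np.unique(true):
        mask = true == cls
        hit = 100.0 * float(np.mean(pred[mask] == cls))
        out[str(cls)] = {"hit": hit, "false_alarm": 100.0 - hit}
    return out


@dataclass
class MetricsReport:
    """The three evaluation metrics plus the per-motion breakdown."""

    type1_hit: float | None
    type2_hit: float
    type3_false_alarm: float
    per_motion: dict

    def to_dict(self) -> dict:
        return {
            "type1_hit": self.type1_hit,
            "type2_hit": self.type2_hit,
            "type3_false_alarm": self.type3_false_alarm,
            "per_motion": self.per_motion,
        }


def evaluate(pred, true, predicted_ks=None, true_k: int | None = None,
             named: bool | None = None) -> MetricsReport:
    """Compute the metric suite for one trial.

    With string (named) labels, correctness is name equality; with integer
    cluster ids, the optimal one-to-one matching is applied first.  Type 1
    is computed only when per-trial cluster counts are supplied.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if named is None:
        named = pred.dtype.kind in "UOS"
    if named:
        hit = 100.0 * float(np.mean(pred == true))
        per_motion = per_class_accuracy(pred, true)
    else:
        table, _, tu = _contingency(pred, true)
        r, c = linear_sum_assignment(-table)
        hit = 100.0 * table[r, c].sum() / len(pred)
        col_to_row = {cj: ri for ri, cj in zip(r, c)}
        per_motion = {}
        for j, cls in enumerate(tu):
            n_cls = table[:, j].sum()
            good = table[col_to_row[j], j] if j in col_to_row else 0
            h = 100.0 * good / n_cls
            per_motion[str(cls)] = {"hit": h, "false_alarm": 100.0 - h}
    t1 = None
    if predicted_ks is not None and true_k is not None:
        t1 = type1_hit_rate(predicted_ks, true_k)
    return MetricsReport(t1, hit, 100.0 - hit, per_motion)
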