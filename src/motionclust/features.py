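"""Motion features: the 3-D observation space (TAS, SVA, ACT) per window.

Each fixed-length window of the tri-axial acceleration signal is reduced to
three numbers chosen to separate static from dynamic motions:

* **TAS** — tilt-angle sum, the window sum of |phi| where phi is the tilt
  angle about x; large and stable for upright static postures, discontinuous
  across orientation changes such as a fall.
* **SVA** — sum over the three axes of the variance of the cumulative
  time-integral of acceleration; a variance-weighted signal-magnitude-area
  variant that orders static << walk < run.
* **ACT** — lag-1 autocorrelation coefficient of the window's tilt-angle
  series, capturing periodicity of gait.

The resulting N x 3 matrix is the observation set of the mixture model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .signals import SignalWindow, tilt_x

__all__ = ["FeatureMatrix", "tas", "sva", "act", "featurize"]

FEATURE_NAMES = ("tas", "sva", "act")


@dataclass
class FeatureMatrix:
    """N feature vectors plus the standardization actually applied.

    ``X`` holds the (possibly standardized) observations; ``shift`` and
    ``scale`` record the per-dimension transform ``X = (raw - shift)/scale``
    so raw values can always be recovered.
    """

    X: np.ndarray
    shift: np.ndarray = None
    scale: np.ndarray = None
    window_index: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, d = self.X.shape
        if n < 1:
            raise ValueError("FeatureMatrix needs at least one row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if self.shift is None:
            self.shift = np.zeros(d)
        if self.scale is None:
            self.scale = np.ones(d)
        self.shift = np.asarray(self.shift, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("standardization scales must be positive")
        if self.window_index is None:
            self.window_index = np.arange(n)

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_dim(self) -> int:
        return self.X.shape[1]

    def raw(self) -> np.ndarray:
        """Undo the recorded standardization."""
        return self.X * self.scale + self.shift

    @classmethod
    def from_array(cls, raw: np.ndarray, standardize: bool = True,
                   ddof: int = 1) -> "FeatureMatrix":
        """Wrap an (N, D) array, optionally standardizing each column."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if not standardize or len(raw) < 2:
            if standardize and len(raw) < 2:
                warnings.warn("standardization undefined for N=1; using identity")
            return cls(raw)
        shift = raw.mean(axis=0)
        scale = raw.std(axis=0, ddof=ddof)
        if np.any(scale <= 0):
            raise ValueError("zero-variance feature column; cannot standardize")
        return cls((raw - shift) / scale, shift, scale)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES)[: self.n_dim])
        df.insert(0, "window_index", self.window_index)
        df.to_csv(path, index=False)


def tas(win: SignalWindow) -> float:
    """Tilt-angle sum: sum over the window of |phi_i| (radians)."""
    phi = tilt_x(win.ax, win.ay, win.az)
    return float(np.sum(np.abs(phi)))


def sva(win: SignalWindow, ddof: int = 1) -> float:
    """Sum over axes of the variance of the cumulative acceleration integral.

    Each axis is integrated over the window with the trapezoid rule at
    dt = 1/rate_hz; the sample variance (denominator W-ddof) of the
    integrated series is summed over the three axes.
    """
    if len(win) < 2:
        raise ValueError("SVA needs at least 2 samples")
    dt = 1.0 / win.rate_hz
    acc = win.accel()
    integ = cumulative_trapezoid(acc, dx=dt, axis=0, initial=0.0)
    return float(np.sum(np.var(integ, axis=0, ddof=ddof)))


def act(win: SignalWindow) -> float:
    """Lag-1 autocorrelation coefficient of the window's tilt-angle series.

    Standardized with the window's own mean and variance and clamped to
    [-1, 1].  A zero-variance (constant-tilt) window returns 0 by
    convention, with a warning.
    """
    phi = tilt_x(win.ax, win.ay, win.az)
    phi = phi - phi.mean()
    denom = float(np.dot(phi, phi))
    if denom == 0.0:
        warnings.warn("zero-variance tilt series; ACT set to 0")
        return 0.0
    r1 = float(np.dot(phi[1:], phi[:-1])) / denom
    return float(np.clip(r1, -1.0, 1.0))


def featurize(windows, standardize: bool = True) -> FeatureMatrix:
    """Compute (TAS, SVA, ACT) for each window and assemble the matrix."""
    windows = list(windows)
    if not windows:
        raise ValueError("featurize needs at least one window")
    rows, idx = [], []
    for w in windows:
        try:
            rows.append([tas(w), sva(w), act(w)])
        except ValueError as e:
            raise ValueError(f"window {w.index}: {e}") from e
        idx.append(w.index)
    fm = FeatureMatrix.from_array(np.array(rows), standardize=standardize)
    fm.window_index = np.asarray(idx)
    return fm
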