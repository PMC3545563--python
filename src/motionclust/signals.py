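"""Raw sensor-trace handling: reading, denoising, windowing, tilt angles.

A trace is a tri-axial accelerometer recording (optionally with a single
gyroscope channel) sampled at a fixed rate; body-mounted sensors of this
kind report acceleration along the device's x/y/z axes in m/s^2.  The tilt
angle of the body relative to gravity is recovered from the acceleration
components alone and feeds the downstream feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "SensorTrace",
    "SignalWindow",
    "read_trace",
    "write_trace",
    "denoise",
    "window",
    "tilt_x",
    "tilt_y",
]

#: standard gravity, used when converting inputs recorded in g
G_MS2 = 9.81


@dataclass
class SensorTrace:
    """A validated multi-channel sensor recording.

    Attributes
    ----------
    t : ndarray
        Sample timestamps in seconds, strictly increasing.
    ax, ay, az : ndarray
        Acceleration per axis in m/s^2.
    gyro : ndarray or None
        Angular speed in deg/s (carried through, unused by the features).
    rate_hz : float
        Nominal sampling rate, > 0.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gyro: np.ndarray | None = None
    rate_hz: float = 45.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.t)
        if n < 1:
            raise ValueError("trace must contain at least one sample")
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from t")
        if self.gyro is not None and len(self.gyro) != n:
            raise ValueError("gyro channel length differs from t")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def accel(self) -> np.ndarray:
        """Return the (n, 3) acceleration matrix [ax, ay, az]."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class SignalWindow:
    """``W`` consecutive samples of a :class:`SensorTrace`."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate_hz: float
    index: int = 0
    gyro: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ax) < 2:
            raise ValueError("window must contain at least 2 samples")

    def __len__(self) -> int:
        return len(self.ax)

    def accel(self) -> np.ndarray:
        return np.column_stack([self.ax, self.ay, self.az])


def read_trace(
    path,
    rate_hz: float,
    *,
    delimiter: str = ",",
    has_time: bool = True,
    unit: str = "m/s2",
) -> SensorTrace:
    """Read a delimited-text trace with columns ``t, ax, ay, az[, gyro]``.

    Parameters
    ----------
    path : path-like
        Text file, optional header row, at least four numeric columns.
    rate_hz : float
        Sampling rate of the recording.
    has_time : bool
        If False the first column is ``ax`` and timestamps are synthesized
        from ``rate_hz`` starting at 0.
    unit : {"m/s2", "g"}
        Unit of the acceleration columns; ``"g"`` values are converted with
        g = 9.81 m/s^2.
    """
    df = pd.read_csv(path, sep=delimiter, header=None, comment="#",
                     skip_blank_lines=True)
    # tolerate a single header row of column names
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    needed = 4 if has_time else 3
    if df.shape[1] < needed:
        raise ValueError(
            f"expected at least {needed} columns, found {df.shape[1]}")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.where(~np.isfinite(vals[:, :needed]).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-numeric or missing values at rows {bad.tolist()}")
    if has_time:
        t, acc = vals[:, 0], vals[:, 1:4]
        gyro = vals[:, 4] if vals.shape[1] > 4 else None
    else:
        t = np.arange(len(vals)) / rate_hz
        acc = vals[:, 0:3]
        gyro = vals[:, 3] if vals.shape[1] > 3 else None
    if unit == "g":
        acc = acc * G_MS2
    elif unit != "m/s2":
        raise ValueError(f"unknown unit {unit!r}")
    return SensorTrace(t, acc[:, 0], acc[:, 1], acc[:, 2], gyro, rate_hz)


def write_trace(trace: SensorTrace, path, *, delimiter: str = ",") -> None:
    """Write a trace back to delimited text (inverse of :func:`read_trace`)."""
    cols = {"t": trace.t, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    if trace.gyro is not None:
        cols["gyro"] = trace.gyro
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, header=False)


def denoise(trace: SensorTrace, method: str = "median", width: int = 5) -> SensorTrace:
    """Outlier-removal filter applied per channel.

    ``method="median"`` runs a sliding median of odd ``width`` (edges
    nearest-extended); ``method="none"`` is the identity.
    """
    if method == "none":
        return trace
    if method != "median":
        raise ValueError(f"unknown denoise method {method!r}")
    if width < 1 or width % 2 == 0:
        raise ValueError("median width must be an odd integer >= 1")
    filt = lambda x: median_filter(x, size=width, mode="nearest")
    return SensorTrace(
        trace.t, filt(trace.ax), filt(trace.ay), filt(trace.az),
        None if trace.gyro is None else filt(trace.gyro), trace.rate_hz,
    )


def window(trace: SensorTrace, W: int = 512, overlap: int = 0) -> list[SignalWindow]:
    """Split a trace into fixed-length windows; a trailing partial window is dropped."""
    if W < 2:
        raise ValueError("window length W must be >= 2")
    if not 0 <= overlap < W:
        raise ValueError("overlap must satisfy 0 <= overlap < W")
    n = len(trace)
    if n < W:
        raise ValueError(f"trace of length {n} shorter than window W={W}")
    step = W - overlap
    out = []
    for idx, start in enumerate(range(0, n - W + 1, step)):
        sl = slice(start, start + W)
        out.append(
            SignalWindow(
                trace.t[sl], trace.ax[sl], trace.ay[sl], trace.az[sl],
                trace.rate_hz, index=idx,
                gyro=None if trace.gyro is None else trace.gyro[sl],
            )
        )
    return out


def _tilt(num: np.ndarray, o1: np.ndarray, o2: np.ndarray) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    if np.any((num == 0) & (o1 == 0) & (o2 == 0)):
        raise ValueError("tilt undefined for an all-zero acceleration sample")
    # arctan2(num, r) with r >= 0 equals arctan(num/r) in [-pi/2, pi/2] and
    # yields sign(num)*pi/2 when r == 0.
    return np.arctan2(num, np.hypot(o1, o2))


def tilt_x(ax, ay, az):
    """Tilt angle about the x axis, phi = arctan(ax / sqrt(ay^2 + az^2))."""
    return _tilt(ax, ay, az)


def tilt_y(ax, ay, az):
    """Tilt angle about the y axis, rho = arctan(ay / sqrt(ax^2 + az^2))."""
    return _tilt(ay, ax, az)
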