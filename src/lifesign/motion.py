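"""Accelerometer motion detection via a mean-absolute-deviation indicator.

For a buffer of N_acc three-axis samples the indicator is

    S = (1/N_acc) * sum_i ( |x_mean - x_i| + |y_mean - y_i| + |z_mean - z_i| )

i.e. the per-axis mean absolute deviation from the buffer mean, summed
over the three axes.  Subtracting the per-axis mean makes S immune to the
static gravity component and to sensor bias; motion is declared when S
*strictly exceeds* a threshold (contrast with the pulse detector, where
the threshold comparison accepts ties).

Device convention: N_acc = 8 triplets per 4 s observation window; streams
sampled faster are decimated to 8 triplets by uniform striding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError, InvalidInputError, InvalidParameterError
from .kde import fit_h1_calibration

__all__ = [
    "DEFAULT_N_ACC",
    "DEFAULT_WINDOW_S",
    "DEFAULT_MOTION_THRESHOLD",
    "AccelBuffer",
    "MotionDecision",
    "axis_means",
    "motion_indicator",
    "decide_motion",
    "calibrate_motion_threshold",
    "buffers_from_stream",
]

DEFAULT_N_ACC = 8
DEFAULT_WINDOW_S = 4.0

#: Shipped default threshold (sensor units, g).  Derived from the synthetic
#: calibration procedure: placed between the rest-state indicator population
#: (99th percentile ~ 0.03 g) and the walking population (minimum ~ 0.4 g).
DEFAULT_MOTION_THRESHOLD = 0.05


@dataclass(frozen=True)
class AccelBuffer:
    """N_acc three-axis accelerometer samples covering one observation window."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (self.x.size == self.y.size == self.z.size):
            raise InvalidInputError("axis buffers must have equal lengths")
        if self.x.size < 2:
            raise InvalidInputError("buffer needs at least 2 samples per axis")
        for arr in (self.x, self.y, self.z):
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError("buffer contains non-finite samples")

    @property
    def n_acc(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class MotionDecision:
    s: float
    moving: bool
    threshold: float


def axis_means(buf: AccelBuffer) -> tuple[float, float, float]:
    """Per-axis arithmetic means (x_mean, y_mean, z_mean)."""
    return float(buf.x.mean()), float(buf.y.mean()), float(buf.z.mean())


def motion_indicator(buf: AccelBuffer) -> float:
    """Summed per-axis mean absolute deviation; zero iff every axis is constant."""
    xm, ym, zm = axis_means(buf)
    dev = np.abs(buf.x - xm) + np.abs(buf.y - ym) + np.abs(buf.z - zm)
    return float(dev.mean())


def decide_motion(s: float, threshold: float = DEFAULT_MOTION_THRESHOLD) -> MotionDecision:
    """Moving iff the indicator strictly exceeds the threshold."""
    if threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    return MotionDecision(s=float(s), moving=bool(s > threshold), threshold=float(threshold))


def calibrate_motion_threshold(rest_s_values, quantile: float = 0.99) -> float:
    """KDE quantile of rest-state indicator values (false-alarm calibration)."""
    if not (0.0 < quantile < 1.0):
        raise InvalidParameterError(f"quantile must lie in (0, 1), got {quantile}")
    x = np.asarray(rest_s_values, dtype=float).ravel()
    if x.size < 10:
        raise CalibrationError(f"need >= 10 rest-state indicator values, got {x.size}")
    spec, _ = fit_h1_calibration(x, quantile)
    return spec.threshold


def buffers_from_stream(
    xyz,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    n_acc: int = DEFAULT_N_ACC,
) -> list[AccelBuffer]:
    """Split an (n, 3) accelerometer stream into decimated per-window buffers.

    Each complete ``window_s`` window is reduced to ``n_acc`` triplets by
    uniform striding; a trailing partial window is discarded.  Gyroscope /
    magnetometer columns beyond the first three are ignored.
    """
    arr = np.asarray(xyz, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise InvalidInputError("accelerometer stream must be (n, 3) or wider")
    if fs <= 0 or window_s <= 0 or n_acc < 2:
        raise InvalidParameterError("fs and window_s must be positive, n_acc >= 2")
    n_win = int(round(window_s * fs))
    if n_win < n_acc:
        raise InvalidParameterError(
            f"window of {n_win} samples cannot supply n_acc={n_acc} triplets"
        )
    stride = n_win // n_acc
    idx = np.arange(n_acc) * stride
    out = []
    for start in range(0, arr.shape[0] - n_win + 1, n_win):
        w = arr[start : start + n_win]
        out.append(
            AccelBuffer(x=w[idx, 0], y=w[idx, 1], z=w[idx, 2], window_s=window_s)
        )
    return out
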