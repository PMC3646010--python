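"""3-D flight kinematics from videogrammetry tracks.

Tracks arrive as timestamped xyz positions (nominally 60 frames/s).
Each coordinate is smoothed with a quintic smoothing spline, from which
flight vectors, bat->target vectors, approach angles and distances are
derived. A wand-calibration error check mirrors the standard accuracy
test for dynamic-wand 3-D reconstructions.

Coordinates are right-handed, meters, z-up; time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = [
    "RawTrack",
    "SmoothTrack",
    "WandRecord",
    "fit_smooth_track",
    "approach_angle",
    "wand_error",
    "MIN_SPEED_M_S",
]

#: Below this speed the flight direction is numerically meaningless and
#: the approach angle is reported as missing (NaN).
MIN_SPEED_M_S = 0.05

_MIN_SAMPLES = 6  # quintic spline needs at least k+1 = 6 points


@dataclass(frozen=True)
class RawTrack:
    """Raw digitized 3-D positions of one object over time."""

    times: np.ndarray
    positions: np.ndarray  # shape (n, 3), meters

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if t.shape[0] != p.shape[0]:
            raise ValueError("times and positions length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return self.times.shape[0]


class SmoothTrack:
    """Per-coordinate quintic smoothing-spline representation of a track.

    Evaluable position and first derivative at any time within the
    original sample range.
    """

    def __init__(self, splines, t_range) -> None:
        self._splines = splines
        self.t_start, self.t_end = t_range

    def _check(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        if np.any(t < self.t_start - 1e-12) or np.any(t > self.t_end + 1e-12):
            raise ValueError(
                f"time outside track range [{self.t_start}, {self.t_end}]"
            )
        return t

    def position(self, t) -> np.ndarray:
        t = self._check(t)
        out = np.stack([s(t) for s in self._splines], axis=-1)
        return out

    def velocity(self, t) -> np.ndarray:
        t = self._check(t)
        return np.stack([s.derivative(1)(t) for s in self._splines], axis=-1)

    def speed(self, t) -> float:
        return np.linalg.norm(self.velocity(t), axis=-1)


def _noise_variance(x: np.ndarray) -> float:
    # Second-difference estimator: for iid noise sigma^2 on a smooth
    # signal, E[(x[i-1] - 2 x[i] + x[i+1])^2] = 6 sigma^2.
    d2 = np.diff(x, n=2)
    return float(np.mean(d2**2) / 6.0) if d2.size else 0.0


def fit_smooth_track(raw: RawTrack, smoothing: float | None = None) -> SmoothTrack:
    """Fit quintic smoothing splines to each coordinate of a raw track.

    Parameters
    ----------
    raw : RawTrack
        At least 6 samples with strictly increasing times.
    smoothing : float or None
        Total squared-residual budget per coordinate (m^2). 0 yields an
        interpolating spline. ``None`` (default) selects the budget
        automatically as ``n * sigma_hat^2`` where ``sigma_hat^2`` is a
        second-difference estimate of the per-sample noise variance.
    """
    if len(raw) < _MIN_SAMPLES:
        raise ValueError(
            f"need at least {_MIN_SAMPLES} samples for quintic smoothing, got {len(raw)}"
        )
    if smoothing is not None and smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    splines = []
    n = len(raw)
    for j in range(3):
        x = raw.positions[:, j]
        s = smoothing if smoothing is not None else n * _noise_variance(x)
        splines.append(UnivariateSpline(raw.times, x, k=5, s=s))
    return SmoothTrack(splines, (raw.times[0], raw.times[-1]))


def approach_angle(bat: SmoothTrack, target_position, t: float) -> float:
    """Angle (degrees) between the bat's flight vector and the bat->target vector.

    0 deg means flying straight at the target; 90 deg tangential. Returns
    NaN (flagged missing) when bat speed is below ``MIN_SPEED_M_S``.
    """
    v = bat.velocity(t)
    speed = np.linalg.norm(v)
    if speed < MIN_SPEED_M_S:
        return float("nan")
    to_target = np.asarray(target_position, float) - bat.position(t)
    d = np.linalg.norm(to_target)
    if d == 0:
        return float("nan")
    cosang = np.dot(v, to_target) / (speed * d)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass(frozen=True)
class WandRecord:
    """Measured inter-marker distances of a calibration wand."""

    measured_cm: np.ndarray
    true_separation_cm: float

    def __post_init__(self) -> None:
        m = np.asarray(self.measured_cm, float)
        if m.size == 0:
            raise ValueError("wand record is empty")
        if np.any(m <= 0):
            raise ValueError("measured distances must be positive")
        object.__setattr__(self, "measured_cm", m)


def wand_error(w: WandRecord) -> tuple[float, float]:
    """Mean absolute wand-length error (cm) and percent error.

    ``percent = 100 * mean|measured - true| / true``.
    """
    if w.true_separation_cm <= 0:
        raise ValueError("true separation must be positive")
    mae = float(np.mean(np.abs(w.measured_cm - w.true_separation_cm)))
    return mae, 100.0 * mae / w.true_separation_cm
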