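"""Raw frame matrix -> clean one-dimensional vital signal.

Three stages: (1) loopback-filter clutter removal — a first-order recursive
estimate of the static background is subtracted from every frame; (2) range
bin selection — the fast-time column with the highest slow-time variance is
the one modulated by chest motion; (3) scalar Kalman smoothing of that
column against measurement noise. A small evaluation helper reports SNR and
RMSE before/after filtering on synthetic data where the clean signal is
known.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .simulate import RadarFrameMatrix

__all__ = [
    "PreprocessConfig",
    "VitalSignal",
    "NoiseReport",
    "NoMotionFoundError",
    "remove_clutter",
    "select_range_bin",
    "kalman_smooth",
    "evaluate_noise",
    "SNR_CAP_DB",
]

#: Reported in place of an infinite SNR (zero residual power).
SNR_CAP_DB = 300.0


class NoMotionFoundError(ValueError):
    """Raised when every fast-time column has zero slow-time variance."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    alpha
        Loopback-filter forgetting factor in [0, 1). The clutter estimate is
        ``c_m = alpha * c_{m-1} + (1 - alpha) * r_m`` with ``c_0 = r_0``; the
        output frame is ``r_m - c_m``. Default 0.995 settles in ~2 s at
        92.71 frames/s while leaving the breathing band (>= 10 cpm) almost
        untouched.
    window_frames
        Slow-time window length used per estimate.
    kalman_q, kalman_r
        Process and measurement noise variances of the scalar random-walk
        Kalman filter.
    """

    alpha: float = 0.995
    window_frames: int = 2048
    kalman_q: float = 1e-4
    kalman_r: float = 1e-2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")
        if self.kalman_q <= 0 or self.kalman_r <= 0:
            raise ValueError("kalman_q and kalman_r must be > 0")


@dataclass(frozen=True)
class VitalSignal:
    """One slow-time series (radar amplitude) from a selected range bin."""

    values: np.ndarray
    frame_rate_hz: float
    source_bin: int = -1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("vital signal must be 1-D with length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("vital signal must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def remove_clutter(frames: RadarFrameMatrix, alpha: float = 0.995) -> RadarFrameMatrix:
    """Subtract a recursive (loopback-filter) clutter estimate from each frame.

    The static background estimate for each range bin follows
    ``c_m = alpha * c_{m-1} + (1 - alpha) * r_m`` with ``c_0 = r_0``, so
    row-constant components decay to zero while slow-time variation above the
    filter's corner frequency passes through. ``alpha = 0`` degenerates to
    ``c_m = r_m`` and the output is identically zero.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    r = frames.values
    if r.size == 0:
        raise ValueError("empty frame matrix")
    # y_m = r_m - c_m with c the one-pole recursive average; vectorised over
    # range bins via lfilter with the initial state chosen so that c_0 = r_0.
    b = np.array([1.0 - alpha])
    a = np.array([1.0, -alpha])
    zi = alpha * r[0][np.newaxis, :]
    clutter, _ = sps.lfilter(b, a, r, axis=0, zi=zi)
    return replace(frames, values=r - clutter)


def select_range_bin(frames: RadarFrameMatrix) -> VitalSignal:
    """Pick the fast-time column with the highest slow-time variance.

    Chest motion modulates the echo amplitude, so after clutter removal the
    most active column marks the subject. Ties break toward the smallest
    index. Raises :class:`NoMotionFoundError` if every column is constant.
    """
    variances = np.var(frames.values, axis=0)
    if np.max(variances) <= 0.0:
        raise NoMotionFoundError("no motion found: all range bins are constant")
    bin_idx = int(np.argmax(variances))
    return VitalSignal(
        values=frames.values[:, bin_idx].copy(),
        frame_rate_hz=frames.frame_rate_hz,
        source_bin=bin_idx,
    )


def kalman_smooth(
    vital: VitalSignal, q: float = 1e-4, r: float = 1e-2
) -> VitalSignal:
    """Scalar random-walk Kalman filter over the slow-time signal.

    State model: ``x_m = x_{m-1} + w`` with process variance ``q``;
    observation ``z_m = x_m + v`` with measurement variance ``r``. The filter
    is initialised at the first observation with prior variance ``r``. The
    steady-state gain lies strictly in (0, 1); as ``r -> 0`` the output
    approaches the input.
    """
    if q <= 0 or r <= 0:
        raise ValueError("q and r must be > 0")
    z = vital.values
    out = np.empty_like(z)
    x = z[0]
    p = r
    out[0] = x
    for m in range(1, z.size):
        p = p + q
        k = p / (p + r)
        x = x + k * (z[m] - x)
        p = (1.0 - k) * p
        out[m] = x
    return replace(vital, values=out)


@dataclass(frozen=True)
class NoiseReport:
    snr_before_db: float
    snr_after_db: float
    rmse_before: float
    rmse_after: float


def _snr_db(clean: np.ndarray, residual: np.ndarray) -> float:
    p_clean = float(np.mean(np.square(clean)))
    p_resid = float(np.mean(np.square(residual)))
    if p_resid == 0.0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(p_clean / p_resid), SNR_CAP_DB)


def evaluate_noise(
    clean: np.ndarray, noisy: np.ndarray, filtered: np.ndarray
) -> NoiseReport:
    """SNR and RMSE of a noisy and a filtered signal against the clean truth.

    SNR = 10 log10(power(clean) / power(residual)); a zero-power residual is
    reported as :data:`SNR_CAP_DB`.
    """
    clean = np.asarray(clean, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if not (clean.shape == noisy.shape == filtered.shape):
        raise ValueError("clean, noisy and filtered must have equal shapes")
    if np.mean(np.square(clean)) == 0.0:
        raise ValueError("clean signal has zero power")
    return NoiseReport(
        snr_before_db=_snr_db(clean, noisy - clean),
        snr_after_db=_snr_db(clean, filtered - clean),
        rmse_before=float(np.sqrt(np.mean(np.square(noisy - clean)))),
        rmse_after=float(np.sqrt(np.mean(np.square(filtered - clean)))),
    )
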