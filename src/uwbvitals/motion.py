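"""Random-body-movement detection from autocorrelation width.

While the subject is stationary the slow-time vital signal is quasi-periodic
(breathing plus heartbeat), so its normalized autocorrelation stays high out
to an appreciable lag. Random body movement (speaking, head shake,
whole-body shift) injects broadband amplitude fluctuation that decorrelates
consecutive frames, shrinking the lag at which the autocorrelation first
drops below a set level — the "correlation width". Motion is declared when
the width, normalized by a known-stationary baseline, falls below a
threshold; vital-sign output is then held at its last valid value until the
subject is stationary again.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .preprocess import VitalSignal

__all__ = [
    "MotionConfig",
    "MotionStatus",
    "MotionDetector",
    "autocorrelation",
    "correlation_width",
    "update_motion_state",
]


@dataclass(frozen=True)
class MotionConfig:
    """Motion-detector parameters.

    segment_s
        Slow-time analysis segment, seconds. Default 6 s covers at least one
        full breathing period down to 10 cycles/min, keeping the stationary
        width stable across windows.
    acf_level
        Autocorrelation magnitude defining the width (first crossing below
        this level). 0.5 is the standard half-maximum width and shrinks
        monotonically under decorrelation.
    width_ratio_threshold
        Motion is declared when width / baseline_width drops below this.
        A stationary subject sits near 1.0 and even mild speaking motion
        falls to ~0.7, so the operating point lies between.
    baseline_width
        Reference width in lags from a known-stationary period; ``None``
        means the detector learns it from its first segment.
    hysteresis
        Consecutive below/above-threshold segments required to switch state,
        preventing chatter near the threshold.
    """

    segment_s: float = 6.0
    acf_level: float = 0.5
    width_ratio_threshold: float = 0.85
    baseline_width: int | None = None
    hysteresis: int = 2

    def __post_init__(self) -> None:
        if self.segment_s <= 0:
            raise ValueError("segment_s must be > 0")
        if not 0.0 < self.acf_level < 1.0:
            raise ValueError("acf_level must be in (0, 1)")
        if not 0.0 < self.width_ratio_threshold < 1.0:
            raise ValueError("width_ratio_threshold must be in (0, 1)")
        if self.baseline_width is not None and self.baseline_width < 1:
            raise ValueError("baseline_width must be >= 1 lag")
        if self.hysteresis < 1:
            raise ValueError("hysteresis must be >= 1")


@dataclass(frozen=True)
class MotionStatus:
    """Current motion state of the subject."""

    moving: bool
    normalized_width: float
    since_s: float = 0.0

    def __post_init__(self) -> None:
        if self.normalized_width < 0:
            raise ValueError("normalized_width must be >= 0")


def autocorrelation(segment: VitalSignal) -> np.ndarray:
    """Normalized autocorrelation of a mean-removed slow-time segment.

    Biased estimator over lags 0..L-1, normalized so ``acf[0] == 1``; by
    Cauchy-Schwarz every value lies in [-1, 1]. Raises on a zero-variance
    segment.
    """
    x = segment.values
    if x.size < 4:
        raise ValueError("segment length must be >= 4")
    x = x - np.mean(x)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("zero-variance segment")
    full = sps.correlate(x, x, mode="full", method="fft")
    acf = full[x.size - 1 :] / denom
    acf[0] = 1.0
    return acf


def correlation_width(acf: np.ndarray, acf_level: float = 0.5) -> int:
    """First positive lag where the autocorrelation falls below ``acf_level``.

    Returns an integer lag >= 1; if the autocorrelation never falls below the
    level, the width is capped at the last available lag.
    """
    if not 0.0 < acf_level < 1.0:
        raise ValueError("acf_level must be in (0, 1)")
    below = np.flatnonzero(acf[1:] < acf_level)
    if below.size == 0:
        return int(acf.size - 1)
    return int(below[0] + 1)


def update_motion_state(
    status: MotionStatus | None,
    width: float,
    config: MotionConfig,
    t_s: float = 0.0,
) -> MotionStatus:
    """Single-shot threshold update against a configured baseline width.

    Stateless form of the detector: declares motion whenever
    ``width / baseline_width`` is below the threshold, with no hysteresis.
    Requires ``config.baseline_width``; use :class:`MotionDetector` for the
    streaming version that learns its own baseline and debounces.
    """
    if config.baseline_width is None:
        raise ValueError("baseline_width unset; configure it or use MotionDetector")
    ratio = width / config.baseline_width
    moving = ratio < config.width_ratio_threshold
    if status is not None and status.moving == moving:
        return replace(status, normalized_width=ratio)
    return MotionStatus(moving=moving, normalized_width=ratio, since_s=t_s)


class MotionDetector:
    """Streaming motion detector with baseline learning and hysteresis.

    The first segment after startup (assumed stationary) sets the baseline
    width unless the config provides one. A state flip requires
    ``config.hysteresis`` consecutive segments on the other side of the
    threshold.
    """

    def __init__(self, config: MotionConfig | None = None) -> None:
        self.config = config or MotionConfig()
        self.baseline_width: int | None = self.config.baseline_width
        self.status = MotionStatus(moving=False, normalized_width=1.0)
        self._flip_count = 0

    def update(self, segment: VitalSignal, t_s: float = 0.0) -> MotionStatus:
        """Process one slow-time segment; returns the updated status."""
        acf = autocorrelation(segment)
        width = correlation_width(acf, self.config.acf_level)
        return self.update_width(width, t_s)

    def update_width(self, width: int, t_s: float = 0.0) -> MotionStatus:
        """Advance the state machine with a precomputed correlation width."""
        if self.baseline_width is None:
            self.baseline_width = width
        ratio = width / self.baseline_width
        raw_moving = ratio < self.config.width_ratio_threshold
        if raw_moving != self.status.moving:
            self._flip_count += 1
            if self._flip_count >= self.config.hysteresis:
                self.status = MotionStatus(
                    moving=raw_moving, normalized_width=ratio, since_s=t_s
                )
                self._flip_count = 0
            else:
                self.status = replace(self.status, normalized_width=ratio)
        else:
            self._flip_count = 0
            self.status = replace(self.status, normalized_width=ratio)
        return self.status
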