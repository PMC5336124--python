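"""Synthetic IR-UWB radar frame generation with known ground truth.

An impulse-radio UWB radar facing a seated person records, at each slow-time
instant, one fast-time waveform: the transmitted pulse reflected by everything
in front of the antenna. Stacking ``m`` consecutive waveforms of ``n`` fast-time
samples gives the slow-time x fast-time frame matrix that every downstream
stage consumes. The physiological content is the chest-surface displacement:
a breathing fundamental ``f_b`` with integer harmonics (chest motion is not
sinusoidal), plus a much weaker heartbeat component ``f_h``. This module
renders that displacement into pulse echoes embedded in static clutter and
additive white noise, so the full estimation chain can be exercised, and
graded against a known ground truth, without hardware.

The chest displacement model is a phase-randomised sum of sinusoids

    d(t) = A_b * sum_k w_k sin(2 pi k f_b t + phi_b)
         + A_h * sin(2 pi f_h t + phi_h) + RBM(t),      w_1 = 1,

where ``RBM(t)`` is a bounded random walk active only inside declared motion
events (speaking, head, whole body). The echo of a subject at range ``r`` with
displacement ``d`` is an even-order Gaussian-derivative pulse evaluated on the
fast-time range axis at ``r + d``; the carrier is folded into an
amplitude-only echo because the downstream algorithms use only the magnitude
variation over slow time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import hermite_e

__all__ = [
    "SubjectProfile",
    "RadarConfig",
    "MotionEvent",
    "RadarFrameMatrix",
    "GroundTruth",
    "generate_displacement",
    "generate_frames",
    "make_scenario",
    "SCENARIO_NAMES",
    "BACK_ASPECT_BREATH_SCALE",
]

#: Breathing-amplitude scale applied when the radar faces the subject's back.
#: Chosen so the heartbeat peak dominates the spectrum in that geometry.
BACK_ASPECT_BREATH_SCALE = 0.06

#: Random-walk step scale (mm per sqrt-second) and default excursion bound
#: (mm) per motion class. Speaking is a small fast vibration that only
#: moderately decorrelates the slow-time signal; a whole-body shift is a
#: large fast excursion that destroys it almost immediately.
_MOTION_KIND_PARAMS = {
    "speaking": {"rate_mm_sqrt_s": 25.0, "amplitude_mm": 4.0},
    "head": {"rate_mm_sqrt_s": 20.0, "amplitude_mm": 20.0},
    "body": {"rate_mm_sqrt_s": 400.0, "amplitude_mm": 15.0},
}


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth vital-sign parameters of one simulated subject.

    Parameters
    ----------
    rr_cpm : float
        Breathing fundamental, cycles per minute. Must lie in (0, 60].
    hr_bpm : float
        Heartbeat frequency, beats per minute. Must lie in (0, 200].
    breath_amp_mm : float
        Peak chest displacement of the breathing fundamental, millimetres.
    harmonic_weights : tuple of float
        Relative amplitudes of breathing harmonics k = 2, 3, ... (the
        fundamental has implicit weight 1). Each weight must be <= 1.
    heart_amp_mm : float
        Heartbeat displacement amplitude, millimetres.
    range_m : float
        Nominal subject range from the antenna, metres.
    aspect : {"front", "back"}
        Radar aspect. ``"back"`` scales the breathing amplitude down by
        :data:`BACK_ASPECT_BREATH_SCALE`, since breathing motion is far less
        visible from the back of the torso.
    """

    rr_cpm: float
    hr_bpm: float
    breath_amp_mm: float = 5.0
    harmonic_weights: tuple[float, ...] = (0.5, 0.25, 0.12)
    heart_amp_mm: float = 0.5
    range_m: float = 1.0
    aspect: str = "front"

    def __post_init__(self) -> None:
        if not 0 < self.rr_cpm <= 60:
            raise ValueError(f"rr_cpm must be in (0, 60], got {self.rr_cpm}")
        if not 0 < self.hr_bpm <= 200:
            raise ValueError(f"hr_bpm must be in (0, 200], got {self.hr_bpm}")
        if self.breath_amp_mm < 0 or self.heart_amp_mm < 0:
            raise ValueError("displacement amplitudes must be >= 0")
        if any(w < 0 or w > 1 for w in self.harmonic_weights):
            raise ValueError("harmonic weights must lie in [0, 1]")
        if self.aspect not in ("front", "back"):
            raise ValueError(f"aspect must be 'front' or 'back', got {self.aspect!r}")
        if (
            self.aspect == "front"
            and self.breath_amp_mm > 0
            and self.heart_amp_mm >= self.breath_amp_mm
        ):
            raise ValueError("front aspect requires heart_amp_mm < breath_amp_mm")

    @property
    def effective_breath_amp_mm(self) -> float:
        """Breathing amplitude after the aspect scaling."""
        if self.aspect == "back":
            return self.breath_amp_mm * BACK_ASPECT_BREATH_SCALE
        return self.breath_amp_mm

    @property
    def max_displacement_mm(self) -> float:
        """Upper bound on |d(t)| ignoring motion events."""
        return (
            self.effective_breath_amp_mm * (1.0 + sum(self.harmonic_weights))
            + self.heart_amp_mm
        )


@dataclass(frozen=True)
class MotionEvent:
    """One random-body-movement (RBM) interval on the slow-time axis.

    ``kind`` selects the step rate and default excursion bound of the bounded
    random walk: ``"speaking"`` (small, fast vibration), ``"head"`` (1-3 cm
    head shake), ``"body"`` (1-2 cm whole-body shift).
    """

    start_s: float
    duration_s: float
    kind: str = "body"
    amplitude_mm: float | None = None

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s <= 0:
            raise ValueError("motion event times must be non-negative, duration > 0")
        if self.kind not in _MOTION_KIND_PARAMS:
            raise ValueError(
                f"unknown motion kind {self.kind!r}; "
                f"expected one of {sorted(_MOTION_KIND_PARAMS)}"
            )
        if self.amplitude_mm is not None and self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def walk_amplitude_mm(self) -> float:
        if self.amplitude_mm is not None:
            return self.amplitude_mm
        return _MOTION_KIND_PARAMS[self.kind]["amplitude_mm"]

    @property
    def walk_rate_mm_sqrt_s(self) -> float:
        return _MOTION_KIND_PARAMS[self.kind]["rate_mm_sqrt_s"]


@dataclass(frozen=True)
class RadarConfig:
    """Functional radar model parameters.

    Only the slow-time frame rate, the fast-time bin spacing and an
    amplitude-only pulse shape are modelled; carrier, antenna and RF
    front-end effects are out of scope.
    """

    frame_rate_hz: float = 92.71
    n_fast: int = 300
    bin_spacing_m: float = 0.004
    pulse_order: int = 5
    pulse_width_m: float = 0.03
    clutter_profile: np.ndarray | None = None
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.n_fast < 2:
            raise ValueError("n_fast must be >= 2")
        if self.bin_spacing_m <= 0 or self.pulse_width_m <= 0:
            raise ValueError("bin_spacing_m and pulse_width_m must be > 0")
        if self.pulse_order < 1:
            raise ValueError("pulse_order must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.clutter_profile is not None:
            clutter = np.asarray(self.clutter_profile, dtype=float)
            if clutter.shape != (self.n_fast,):
                raise ValueError("clutter_profile must have shape (n_fast,)")

    @property
    def max_range_m(self) -> float:
        return self.n_fast * self.bin_spacing_m


@dataclass(frozen=True)
class RadarFrameMatrix:
    """m x n slow-time x fast-time sample grid.

    Rows are frames (slow time, one per pulse train); columns are range bins
    (fast time, ``bin_spacing_m`` apart).
    """

    values: np.ndarray
    frame_rate_hz: float
    bin_spacing_m: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("frame matrix must be 2-D with m >= 2 and n >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("frame matrix must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_fast(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows and the estimator must recover."""

    rr_cpm: float
    hr_bpm: float
    range_bin: int
    motion_intervals: tuple[tuple[float, float, str], ...] = ()
    profile: SubjectProfile | None = None

    def to_dict(self) -> dict:
        return {
            "rr_cpm": self.rr_cpm,
            "hr_bpm": self.hr_bpm,
            "range_bin": self.range_bin,
            "motion_intervals": [list(iv) for iv in self.motion_intervals],
        }


def _validate_events(events: Sequence[MotionEvent]) -> list[MotionEvent]:
    ordered = sorted(events, key=lambda e: e.start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_s < prev.end_s:
            raise ValueError(
                f"overlapping motion events: [{prev.start_s}, {prev.end_s}) and "
                f"[{nxt.start_s}, {nxt.end_s})"
            )
    return ordered


def _bounded_walk(steps: np.ndarray, bound: float) -> np.ndarray:
    """Cumulative sum of ``steps`` reflected into [-bound, bound]."""
    walk = np.cumsum(steps)
    period = 4.0 * bound
    folded = np.mod(walk + bound, period)
    folded = np.where(folded > 2.0 * bound, period - folded, folded)
    return folded - bound


def generate_displacement(
    profile: SubjectProfile,
    times: np.ndarray,
    events: Sequence[MotionEvent] = (),
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Chest-surface displacement d(t) in millimetres.

    Sum of the breathing fundamental and its harmonics, the heartbeat, and a
    bounded random walk inside each motion event. Phases are drawn from
    ``rng`` so repeated runs with the same seed are bit-identical.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    events = _validate_events(events)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    phi_b, phi_h = rng.uniform(0.0, 2.0 * np.pi, size=2)
    f_b = profile.rr_cpm / 60.0
    f_h = profile.hr_bpm / 60.0

    d = np.zeros_like(times)
    breath = profile.effective_breath_amp_mm
    if breath > 0:
        for k, w in enumerate((1.0, *profile.harmonic_weights), start=1):
            if w > 0:
                d += breath * w * np.sin(2.0 * np.pi * k * f_b * times + phi_b)
    if profile.heart_amp_mm > 0:
        d += profile.heart_amp_mm * np.sin(2.0 * np.pi * f_h * times + phi_h)

    for event in events:
        mask = (times >= event.start_s) & (times < event.end_s)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        t_ev = times[idx]
        dt = np.diff(t_ev, prepend=event.start_s)
        steps = rng.normal(0.0, 1.0, size=idx.size) * (
            event.walk_rate_mm_sqrt_s * np.sqrt(np.maximum(dt, 0.0))
        )
        walk = _bounded_walk(steps, event.walk_amplitude_mm)
        # Half-second cosine taper at both ends avoids step discontinuities.
        tau = min(0.5, event.duration_s / 2.0)
        ramp_in = np.clip((t_ev - event.start_s) / tau, 0.0, 1.0)
        ramp_out = np.clip((event.end_s - t_ev) / tau, 0.0, 1.0)
        taper = np.sin(0.5 * np.pi * ramp_in) * np.sin(0.5 * np.pi * ramp_out)
        d[idx] += walk * taper

    return d


def _gauss_deriv(u: np.ndarray, order: int) -> np.ndarray:
    coeffs = np.zeros(order + 1)
    coeffs[order] = 1.0
    return hermite_e.hermeval(u, coeffs) * np.exp(-0.5 * np.square(u))


def _pulse_shape(u: np.ndarray, order: int) -> np.ndarray:
    """Gaussian-derivative pulse of given order, normalised to unit peak.

    The n-th derivative of a Gaussian is He_n(u) * exp(-u^2/2) up to sign,
    with He_n the probabilists' Hermite polynomial. The argument is shifted
    so that u = 0 is the point of maximum slope |p'|: that is the fast-time
    sample whose amplitude is most sensitive to target displacement, i.e.
    the bin the range-bin selector should find at the nominal subject range.
    """
    grid = np.linspace(-6.0, 6.0, 12001)
    peak = np.max(np.abs(_gauss_deriv(grid, order)))
    slope = np.abs(_gauss_deriv(grid, order + 1))  # d/du of order-th derivative
    u0 = grid[int(np.argmax(slope))]
    return _gauss_deriv(u + u0, order) / peak


def generate_frames(
    profile: SubjectProfile,
    config: RadarConfig,
    events: Sequence[MotionEvent] = (),
    duration_s: float = 60.0,
    reflectivity: float = 1.0,
) -> tuple[RadarFrameMatrix, GroundTruth]:
    """Render a subject into an m x n radar frame matrix.

    Each row holds the subject echo — the pulse shape evaluated on the range
    axis at ``range_m + d(t_m)`` — plus the static clutter profile (identical
    in every row) plus white noise. Raises if the frame rate violates Nyquist
    for the heartbeat or if the subject leaves the observable range span.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if config.frame_rate_hz <= 2.0 * profile.hr_bpm / 60.0:
        raise ValueError(
            f"frame_rate_hz={config.frame_rate_hz} violates Nyquist for "
            f"hr_bpm={profile.hr_bpm}"
        )
    max_disp_m = (profile.max_displacement_mm + _max_event_amp_mm(events)) * 1e-3
    if reflectivity != 0 and (
        profile.range_m - max_disp_m < 0
        or profile.range_m + max_disp_m > config.max_range_m
    ):
        raise ValueError(
            f"subject at {profile.range_m} m (+/- {max_disp_m:.3f} m) outside "
            f"observable range [0, {config.max_range_m:.3f}] m"
        )

    rng = np.random.default_rng(config.seed)
    m = int(round(duration_s * config.frame_rate_hz))
    if m < 2:
        raise ValueError("duration too short for two frames")
    times = np.arange(m) / config.frame_rate_hz
    d_mm = generate_displacement(profile, times, events, rng)

    x = np.arange(config.n_fast) * config.bin_spacing_m
    if config.clutter_profile is not None:
        clutter = np.asarray(config.clutter_profile, dtype=float)
    else:
        # Smooth pseudo-static background: low-pass filtered white noise.
        raw = rng.normal(0.0, 1.0, size=config.n_fast + 40)
        kernel = np.hanning(21)
        kernel /= kernel.sum()
        clutter = 0.5 * np.convolve(raw, kernel, mode="valid")[: config.n_fast]

    values = np.tile(clutter, (m, 1))
    if reflectivity != 0:
        target = profile.range_m + d_mm * 1e-3
        u = (x[np.newaxis, :] - target[:, np.newaxis]) / config.pulse_width_m
        values = values + reflectivity * _pulse_shape(u, config.pulse_order)
    if config.noise_sigma > 0:
        values = values + rng.normal(0.0, config.noise_sigma, size=values.shape)

    frames = RadarFrameMatrix(
        values=values,
        frame_rate_hz=config.frame_rate_hz,
        bin_spacing_m=config.bin_spacing_m,
    )
    truth = GroundTruth(
        rr_cpm=profile.rr_cpm,
        hr_bpm=profile.hr_bpm,
        range_bin=int(round(profile.range_m / config.bin_spacing_m)),
        motion_intervals=tuple((e.start_s, e.end_s, e.kind) for e in events),
        profile=profile,
    )
    return frames, truth


def _max_event_amp_mm(events: Sequence[MotionEvent]) -> float:
    return max((e.walk_amplitude_mm for e in events), default=0.0)


# ---------------------------------------------------------------------------
# Named scenarios

_SCENARIOS: dict[str, dict] = {
    # Harmonic confusion: the 3rd and 4th breathing harmonics (54 and 72 cpm)
    # fall inside the heart band and exceed the heartbeat peak at 70 bpm.
    "HC-1": {
        "profile": dict(rr_cpm=18.0, hr_bpm=70.0, harmonic_weights=(0.5, 0.4, 0.3)),
        "events": [],
        "duration_s": 100.0,
    },
    # Stationary subject, no motion events.
    "STAT-1": {
        "profile": dict(rr_cpm=13.0, hr_bpm=74.0),
        "events": [],
        "duration_s": 80.0,
    },
    # Stationary subject with one whole-body movement at 12-18 s.
    "RBM-1": {
        "profile": dict(rr_cpm=13.0, hr_bpm=74.0),
        "events": [MotionEvent(start_s=12.0, duration_s=6.0, kind="body")],
        "duration_s": 40.0,
    },
    # Radar behind the subject: breathing heavily attenuated, heartbeat
    # becomes the tallest spectral peak.
    "BACK-1": {
        "profile": dict(rr_cpm=20.0, hr_bpm=68.0, aspect="back"),
        "events": [],
        "duration_s": 80.0,
    },
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def make_scenario(
    name: str,
    seed: int = 0,
    duration_s: float | None = None,
    config: RadarConfig | None = None,
) -> tuple[RadarFrameMatrix, GroundTruth]:
    """Generate one of the named study scenarios.

    Deterministic for a fixed seed. ``duration_s`` overrides the scenario's
    default recording length; ``config`` overrides the radar model (the seed
    argument still wins over ``config.seed``).
    """
    try:
        spec = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(_SCENARIOS)}"
        ) from None
    profile = SubjectProfile(**spec["profile"])
    if config is None:
        config = RadarConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    return generate_frames(
        profile,
        config,
        events=spec["events"],
        duration_s=duration_s if duration_s is not None else spec["duration_s"],
    )
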