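"""Spectral respiration-rate estimation and the voting heart-rate selector.

The respiration rate (RR) is the tallest spectral peak in the 10-30
cycles/min band — breathing dominates chest displacement, so this is
unambiguous. The heart rate (HR) is not: breathing harmonics (integer
multiples of RR) and intermodulation products can exceed the heartbeat peak
inside the 48-120 beats/min heart band. The selector therefore takes, in
each of the last N analysis windows, the K strongest in-band peaks, discards
those at integer multiples of RR, and votes: the peak location that recurs
in the most windows is the HR, with mean magnitude breaking ties. Occurrence
across windows, not magnitude, is the primary criterion, because harmonic
and intermodulation peaks drift while the true heartbeat location recurs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sps

from .preprocess import VitalSignal

__all__ = [
    "AlgorithmConfig",
    "Spectrum",
    "PeakCandidate",
    "VoteTally",
    "NoRespirationError",
    "NoHeartRateError",
    "compute_spectrum",
    "estimate_rr",
    "find_hr_candidates",
    "conventional_hr",
    "reject_harmonics",
    "update_tally",
    "select_hr",
]


class NoRespirationError(ValueError):
    """No spectral energy in the respiration band."""


class NoHeartRateError(ValueError):
    """The vote tally holds no candidates."""


@dataclass(frozen=True)
class AlgorithmConfig:
    """Bands and voting parameters of the HR selection algorithm.

    rr_band_cpm
        Respiration search band, cycles/min.
    hr_band_bpm
        Heart search band, beats/min (0.8-2 Hz).
    k_peaks
        Number of candidate peaks retained per analysis window.
    n_iterations
        Length N of the sliding vote window (number of spectra).
    harmonic_tol_bpm
        A candidate within this distance of any integer multiple (k >= 2) of
        RR is discarded as a breathing harmonic.
    pad_factor
        FFT zero-padding multiple; refines peak-location quantisation (not
        resolution).
    """

    rr_band_cpm: tuple[float, float] = (10.0, 30.0)
    hr_band_bpm: tuple[float, float] = (48.0, 120.0)
    k_peaks: int = 3
    n_iterations: int = 20
    harmonic_tol_bpm: float = 1.0
    pad_factor: int = 8

    def __post_init__(self) -> None:
        if self.rr_band_cpm[0] >= self.rr_band_cpm[1]:
            raise ValueError("rr_band_cpm must be a non-empty interval")
        if self.hr_band_bpm[0] >= self.hr_band_bpm[1]:
            raise ValueError("hr_band_bpm must be a non-empty interval")
        if self.k_peaks < 1 or self.n_iterations < 1:
            raise ValueError("k_peaks and n_iterations must be >= 1")
        if self.harmonic_tol_bpm < 0:
            raise ValueError("harmonic_tol_bpm must be >= 0")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum with the frequency axis in cycles/min."""

    freqs_cpm: np.ndarray
    mags: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_cpm, dtype=float)
        mags = np.asarray(self.mags, dtype=float)
        if freqs.ndim != 1 or freqs.shape != mags.shape:
            raise ValueError("freqs_cpm and mags must be 1-D of equal length")
        if freqs.size >= 2 and np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs_cpm must be strictly increasing")
        object.__setattr__(self, "freqs_cpm", freqs)
        object.__setattr__(self, "mags", mags)

    @property
    def resolution_cpm(self) -> float:
        return float(self.freqs_cpm[1] - self.freqs_cpm[0])


@dataclass(frozen=True)
class PeakCandidate:
    """One quantised in-band spectral peak."""

    loc_bpm: int
    magnitude: float


def compute_spectrum(vital: VitalSignal, config: AlgorithmConfig | None = None) -> Spectrum:
    """Magnitude of the zero-padded FFT, frequency axis in cycles/min.

    No taper is applied: the rectangular window has the narrowest main lobe,
    which is what lets a heartbeat sit two beats/min from a breathing
    harmonic and still resolve. Zero padding only refines the bin grid. The
    mean is removed first — otherwise padding smears the DC level across the
    whole axis as a sinc skirt.
    """
    if config is None:
        config = AlgorithmConfig()
    x = vital.values
    if x.size < 2:
        raise ValueError("signal length must be >= 2")
    x = x - np.mean(x)
    n_pad = int(x.size * config.pad_factor)
    mags = np.abs(sp_fft.rfft(x, n=n_pad))
    freqs_cpm = sp_fft.rfftfreq(n_pad, d=1.0 / vital.frame_rate_hz) * 60.0
    return Spectrum(freqs_cpm=freqs_cpm, mags=mags)


def _band_mask(spectrum: Spectrum, band: tuple[float, float]) -> np.ndarray:
    return (spectrum.freqs_cpm >= band[0]) & (spectrum.freqs_cpm <= band[1])


def estimate_rr(spectrum: Spectrum, config: AlgorithmConfig | None = None) -> int:
    """Respiration rate: location of the tallest peak in the RR band (cpm).

    Quantised to integer cycles/min. Raises :class:`NoRespirationError` when
    the band holds no energy.
    """
    if config is None:
        config = AlgorithmConfig()
    mask = _band_mask(spectrum, config.rr_band_cpm)
    if not np.any(mask) or np.max(spectrum.mags[mask]) <= 0.0:
        raise NoRespirationError("no respiration detected in band")
    idx = np.flatnonzero(mask)[np.argmax(spectrum.mags[mask])]
    return int(round(spectrum.freqs_cpm[idx]))


def find_hr_candidates(
    spectrum: Spectrum, config: AlgorithmConfig | None = None
) -> list[PeakCandidate]:
    """Up to ``k_peaks`` strongest local maxima in the heart band.

    A local maximum is a bin strictly greater than both neighbours (band-edge
    bins therefore never qualify by adjacency alone). Candidates are ordered
    by magnitude, strongest first, and quantised to integer beats/min with
    duplicates collapsed onto the stronger peak.
    """
    if config is None:
        config = AlgorithmConfig()
    peaks, _ = sps.find_peaks(spectrum.mags)
    in_band = peaks[_band_mask(spectrum, config.hr_band_bpm)[peaks]]
    order = in_band[np.argsort(spectrum.mags[in_band])[::-1]]
    candidates: list[PeakCandidate] = []
    seen: set[int] = set()
    for idx in order:
        loc = int(round(spectrum.freqs_cpm[idx]))
        if loc in seen:
            continue
        seen.add(loc)
        candidates.append(PeakCandidate(loc_bpm=loc, magnitude=float(spectrum.mags[idx])))
        if len(candidates) == config.k_peaks:
            break
    return candidates


def conventional_hr(spectrum: Spectrum, config: AlgorithmConfig | None = None) -> int:
    """Single-spectrum baseline: plain argmax over the heart band (bpm).

    Stands in for magnitude-only HR pickers in ablation comparisons; it is
    fooled whenever a breathing harmonic or intermodulation product tops the
    heartbeat peak.
    """
    if config is None:
        config = AlgorithmConfig()
    mask = _band_mask(spectrum, config.hr_band_bpm)
    idx = np.flatnonzero(mask)[np.argmax(spectrum.mags[mask])]
    return int(round(spectrum.freqs_cpm[idx]))


def reject_harmonics(
    candidates: list[PeakCandidate], rr_cpm: float, tol_bpm: float = 1.0
) -> list[PeakCandidate]:
    """Drop candidates at integer multiples (k >= 2) of the respiration rate.

    A candidate is discarded when ``|loc - k * rr| <= tol`` for some integer
    k >= 2; order of the survivors is preserved.
    """
    if rr_cpm <= 0:
        raise ValueError("rr_cpm must be > 0")
    survivors = []
    for cand in candidates:
        k = max(2, int(round(cand.loc_bpm / rr_cpm)))
        dist = min(abs(cand.loc_bpm - k * rr_cpm), abs(cand.loc_bpm - (k + 1) * rr_cpm))
        if dist > tol_bpm:
            survivors.append(cand)
    return survivors


@dataclass(frozen=True)
class VoteTally:
    """Sliding-window vote record over the last N analysis windows.

    ``history`` holds, per window, the surviving (location, magnitude) pairs;
    ``counts`` and ``mag_sums`` are derived views. ``iterations_done`` counts
    every window ever fed in, while the history itself retires entries older
    than ``n_iterations`` so the tally always reflects the last N spectra.
    """

    n_iterations: int = 20
    history: tuple[tuple[tuple[int, float], ...], ...] = ()
    iterations_done: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if len(self.history) > self.n_iterations:
            raise ValueError("history longer than n_iterations")

    @property
    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for window in self.history:
            for loc, _ in window:
                out[loc] = out.get(loc, 0) + 1
        return out

    @property
    def mag_sums(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for window in self.history:
            for loc, mag in window:
                out[loc] = out.get(loc, 0.0) + mag
        return out

    @classmethod
    def from_counts(
        cls,
        counts: dict[int, int],
        mag_means: dict[int, float] | None = None,
        n_iterations: int = 20,
    ) -> "VoteTally":
        """Build a tally equivalent to given per-location occurrence counts.

        Convenience for worked examples and tests: locations are spread over
        ``n_iterations`` synthetic windows, each carrying its mean magnitude.
        """
        if any(c < 0 or c > n_iterations for c in counts.values()):
            raise ValueError("counts must lie in [0, n_iterations]")
        mag_means = mag_means or {}
        windows = []
        for i in range(n_iterations):
            window = tuple(
                (loc, float(mag_means.get(loc, 1.0)))
                for loc, count in counts.items()
                if i < count
            )
            windows.append(window)
        return cls(
            n_iterations=n_iterations,
            history=tuple(windows),
            iterations_done=n_iterations,
        )


def update_tally(tally: VoteTally, survivors: list[PeakCandidate]) -> VoteTally:
    """Append one window of surviving candidates, retiring the oldest.

    Each survivor's location gains one vote and accumulates its magnitude.
    Once ``n_iterations`` windows are held, the oldest window's contributions
    drop out, keeping the tally a view of the last N spectra.
    """
    window = tuple((cand.loc_bpm, cand.magnitude) for cand in survivors)
    history = deque(tally.history, maxlen=tally.n_iterations)
    history.append(window)
    return VoteTally(
        n_iterations=tally.n_iterations,
        history=tuple(history),
        iterations_done=tally.iterations_done + 1,
    )


def select_hr(tally: VoteTally) -> int:
    """Heart rate: the vote location with the highest occurrence count.

    Votes in adjacent 1-bpm bins are first merged into the stronger bin
    (spectral jitter otherwise splits a single heartbeat line across two
    bins). Ties on count break toward the higher mean magnitude, then the
    lower location, making the choice deterministic.
    """
    counts = tally.counts
    if not counts:
        raise NoHeartRateError("no heart rate found: empty tally")
    mag_sums = tally.mag_sums
    merged_counts = dict(counts)
    merged_mags = dict(mag_sums)
    # Greedy adjacent-bin merge: absorb each bin's +/-1 neighbours into the
    # stronger bin, strongest bins claiming first.
    by_strength = sorted(
        counts, key=lambda loc: (counts[loc], mag_sums[loc], -loc), reverse=True
    )
    absorbed: set[int] = set()
    for loc in by_strength:
        if loc in absorbed:
            continue
        for neighbor in (loc - 1, loc + 1):
            if neighbor in merged_counts and neighbor not in absorbed:
                merged_counts[loc] += merged_counts[neighbor]
                merged_mags[loc] += merged_mags[neighbor]
                absorbed.add(neighbor)
    for loc in absorbed:
        del merged_counts[loc]
        del merged_mags[loc]

    def rank(loc: int) -> tuple[float, float, float]:
        return (merged_counts[loc], merged_mags[loc] / merged_counts[loc], -loc)

    return max(merged_counts, key=rank)
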