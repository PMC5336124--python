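"""Shared fixtures: small synthetic recordings reused across test modules."""

from __future__ import annotations

import pytest

from uwbvitals import (
    MotionEvent,
    PipelineConfig,
    RadarConfig,
    SubjectProfile,
    generate_frames,
    make_scenario,
    run_stream,
)


def small_radar_config(seed: int = 0, **overrides) -> RadarConfig:
    """Short-range radar model keeping matrices small for fast tests."""
    kwargs = dict(seed=seed, n_fast=100)
    kwargs.update(overrides)
    return RadarConfig(**kwargs)


def small_subject(**overrides) -> SubjectProfile:
    kwargs = dict(rr_cpm=13.0, hr_bpm=74.0, range_m=0.3)
    kwargs.update(overrides)
    return SubjectProfile(**kwargs)


@pytest.fixture(scope="session")
def hc1_short():
    """HC-1 harmonic-confusion scenario, 50 s — enough for one 40 s window."""
    return make_scenario("HC-1", seed=1, duration_s=50)


@pytest.fixture(scope="session")
def hc1_full():
    """HC-1 at full length for streaming runs (warm-up + 30+ updates)."""
    return make_scenario("HC-1", seed=1)


@pytest.fixture(scope="session")
def hc1_stream(hc1_full):
    frames, truth = hc1_full
    return run_stream(frames, PipelineConfig()), truth


@pytest.fixture(scope="session")
def rbm1_stream():
    frames, truth = make_scenario("RBM-1", seed=5)
    return run_stream(frames, PipelineConfig(window_s=10.0)), truth


def motion_frames(kind: str, seed: int, start_s=10.0, duration_s=14.0,
                  total_s=26.0, amplitude_mm=None):
    """Short recording of a stationary subject with one motion event."""
    events = [
        MotionEvent(start_s=start_s, duration_s=duration_s, kind=kind,
                    amplitude_mm=amplitude_mm)
    ]
    return generate_frames(
        small_subject(), small_radar_config(seed), events=events,
        duration_s=total_s,
    )
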