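"""Plain-text I/O: frame matrices as CSV with a JSON metadata sidecar.

A recording is two files: ``<stem>.csv`` holding the m x n frame matrix (one
frame per row, no header) and ``<stem>.meta.json`` holding the frame rate,
bin spacing and — for synthetic data — the ground truth. Estimate streams
are written as a headed CSV, one update per row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pipeline import VitalEstimate
from .simulate import GroundTruth, RadarFrameMatrix

__all__ = [
    "write_frames",
    "read_frames",
    "write_estimates",
    "read_estimates",
    "sidecar_path",
]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".meta.json")


def write_frames(
    frames: RadarFrameMatrix,
    csv_path: str | Path,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write one frame per CSV row plus the JSON metadata sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(frames.values).to_csv(
        csv_path, header=False, index=False, float_format="%.6e"
    )
    meta = {
        "frame_rate_hz": frames.frame_rate_hz,
        "bin_spacing_m": frames.bin_spacing_m,
    }
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth.to_dict()
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=2))


def read_frames(
    csv_path: str | Path,
    frame_rate_hz: float | None = None,
    bin_spacing_m: float = 0.004,
) -> tuple[RadarFrameMatrix, dict | None]:
    """Read a frame CSV; metadata comes from the sidecar or the arguments.

    Returns the matrix and the ground-truth dict (None when absent).
    """
    csv_path = Path(csv_path)
    values = pd.read_csv(csv_path, header=None).to_numpy(dtype=float)
    truth = None
    meta_file = sidecar_path(csv_path)
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        frame_rate_hz = meta.get("frame_rate_hz", frame_rate_hz)
        bin_spacing_m = meta.get("bin_spacing_m", bin_spacing_m)
        truth = meta.get("ground_truth")
    if frame_rate_hz is None:
        raise ValueError(
            f"no frame rate: pass frame_rate_hz or provide {meta_file.name}"
        )
    frames = RadarFrameMatrix(
        values=values, frame_rate_hz=frame_rate_hz, bin_spacing_m=bin_spacing_m
    )
    return frames, truth


_ESTIMATE_COLUMNS = [
    "t_s",
    "rr_cpm",
    "hr_bpm",
    "moving",
    "held",
    "valid",
    "provisional",
    "normalized_width",
    "source_bin",
]


def write_estimates(estimates: list[VitalEstimate], path: str | Path) -> None:
    """Write the per-update estimate stream as a headed CSV."""
    rows = [
        {
            "t_s": est.t_s,
            "rr_cpm": est.rr_cpm,
            "hr_bpm": est.hr_bpm,
            "moving": est.moving,
            "held": est.held,
            "valid": "" if est.valid is None else est.valid,
            "provisional": est.provisional,
            "normalized_width": est.normalized_width,
            "source_bin": est.source_bin,
        }
        for est in estimates
    ]
    pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS).to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
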