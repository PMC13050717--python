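"""Swim-velocity and darting metrics from centroid trajectories.

Operates on tracked centroid tables (frame, x, y in mm at a fixed frame
rate, nominally 50 fps).  The instantaneous velocity is the frame-to-
frame Euclidean displacement times the frame rate, lightly smoothed with
a centered moving average (default 5 frames) to suppress single-frame
centroid jitter.  Darting — the behavioural seizure correlate — is the
percentage of frames whose (smoothed) velocity exceeds a fixed
high-velocity threshold shared by every cohort (default 20 mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xenphys.simulate import Trajectory

__all__ = ["LocomotionSummary", "compute_velocity_series", "locomotion_metrics"]


@dataclass(frozen=True)
class LocomotionSummary:
    mean_velocity_mm_s: float
    total_distance_mm: float
    darting_pct: float
    dart_threshold_mm_s: float


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the truncated window."""
    if window == 1:
        return x
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def compute_velocity_series(traj: Trajectory, smooth_frames: int = 5) -> np.ndarray:
    """Per-frame speed (mm/s): displacement x fps, then moving average."""
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two frames")
    if smooth_frames < 1 or smooth_frames % 2 == 0:
        raise ValueError("smooth_frames must be a positive odd integer")
    disp = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
    speed = disp * traj.fps
    return _moving_average(speed, smooth_frames)


def locomotion_metrics(
    traj: Trajectory,
    dart_threshold_mm_s: float = 20.0,
    smooth_frames: int = 5,
) -> LocomotionSummary:
    """Mean swim velocity, path length, and time spent darting (%)."""
    velocity = compute_velocity_series(traj, smooth_frames)
    disp = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
    return LocomotionSummary(
        mean_velocity_mm_s=float(velocity.mean()),
        total_distance_mm=float(disp.sum()),
        darting_pct=float(100.0 * np.mean(velocity > dart_threshold_mm_s)),
        dart_threshold_mm_s=dart_threshold_mm_s,
    )
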