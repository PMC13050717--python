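"""File formats: TIFF movies and masks, CSV tables, JSON/YAML configs.

Conventions are fixed to avoid locale drift: CSV is comma-separated
UTF-8 with a header row and '.' decimals; times are seconds, frequencies
Hz, positions mm, traces ΔF/F₀%.  Movies are multi-page grayscale TIFF
(32-bit float); masks are single-page label images with the region map
{1: FB_L, 2: FB_R, 3: MB_L, 4: MB_R} (0 = background / non-brain).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from xenphys.events import EventSet, ThresholdModel
from xenphys.imaging import MovieStack, RegionMasks, Trace
from xenphys.simulate import GroundTruth, Trajectory
from xenphys.spectral import PowerSpectrum
from xenphys.synchrony import CorrelationMatrix

__all__ = [
    "REGION_LABEL_MAP",
    "read_movie",
    "write_movie",
    "read_region_masks",
    "write_region_masks",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_trajectory",
    "write_trajectory",
    "read_spectrum",
    "write_spectrum",
    "read_matrix",
    "write_matrix",
    "write_ground_truth",
    "read_threshold_model",
    "write_threshold_model",
    "read_config",
    "write_config",
]

REGION_LABEL_MAP = {1: "FB_L", 2: "FB_R", 3: "MB_L", 4: "MB_R"}


# ---------------------------------------------------------------- TIFF

def read_movie(path, fs: float = 2.0) -> MovieStack:
    """Read a multi-page grayscale TIFF stack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(f"{path}: single page; a movie needs multiple pages")
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages (T x H x W), got shape {data.shape} "
            "(RGB or irregular pages are not supported)"
        )
    return MovieStack(np.asarray(data), fs)


def write_movie(stack: MovieStack, path) -> None:
    tifffile.imwrite(
        path, np.asarray(stack.data, dtype=np.float32), photometric="minisblack"
    )


def read_region_masks(path) -> RegionMasks:
    """Read a 4-label region image; brain = union of labelled pixels."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: mask must be a single grayscale page")
    regions = {}
    for label, name in REGION_LABEL_MAP.items():
        mask = img == label
        if mask.any():
            regions[name] = mask
    brain = img > 0
    return RegionMasks(brain, regions)


def write_region_masks(masks: RegionMasks, path) -> None:
    out = np.zeros(masks.brain.shape, dtype=np.uint8)
    out[masks.brain] = 255  # brain-only pixels
    for label, name in REGION_LABEL_MAP.items():
        if name in masks.regions:
            out[masks.regions[name]] = label
    tifffile.imwrite(path, out)


# ----------------------------------------------------------------- CSV

def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing or extra:
        raise ValueError(
            f"{path}: bad table schema; missing columns {missing}, unexpected {extra}"
        )


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "value_pct": trace.values}).to_csv(path, index=False)


def read_trace(path, fs: float | None = None, provenance: str = "whole_brain") -> Trace:
    df = pd.read_csv(path)
    _check_columns(df, ["time_s", "value_pct"], path)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: non-uniform time column; pass fs explicitly")
        fs = 1.0 / dt[0]
    return Trace(df["value_pct"].to_numpy(float), fs, provenance)


def write_events(events: EventSet, path, animal_id: str = "animal") -> None:
    order = np.argsort(events.peak_times_s)
    pd.DataFrame(
        {
            "animal_id": animal_id,
            "peak_time_s": events.peak_times_s[order],
            "amplitude_pct": events.amplitudes[order],
            "width_s": events.widths_s[order],
        }
    ).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["animal_id", "peak_time_s", "amplitude_pct", "width_s"], path)
    return df.sort_values("peak_time_s", kind="stable").reset_index(drop=True)


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(traj)), "x_mm": traj.x_mm, "y_mm": traj.y_mm}
    ).to_csv(path, index=False)


def read_trajectory(path, fps: float = 50.0) -> Trajectory:
    df = pd.read_csv(path)
    _check_columns(df, ["frame", "x_mm", "y_mm"], path)
    frames = df["frame"].to_numpy()
    step = np.diff(frames)
    if len(step) and not np.all(step == 1):
        bad = (np.flatnonzero(step != 1) + 1).tolist()
        raise ValueError(f"{path}: non-uniform frame column at rows {bad[:10]}")
    return Trajectory(frames / fps, df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float), fps)


def write_spectrum(spec: PowerSpectrum, path) -> None:
    pd.DataFrame(
        {"freq_hz": spec.freqs, "power": spec.power, "source": spec.source}
    ).to_csv(path, index=False)


def read_spectrum(path) -> PowerSpectrum:
    df = pd.read_csv(path)
    _check_columns(df, ["freq_hz", "power", "source"], path)
    return PowerSpectrum(
        df["freq_hz"].to_numpy(float), df["power"].to_numpy(float), str(df["source"].iloc[0])
    )


def write_matrix(mat: CorrelationMatrix, path) -> None:
    pd.DataFrame(mat.r, index=list(mat.labels), columns=list(mat.labels)).to_csv(path)


def read_matrix(path) -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    return CorrelationMatrix(tuple(df.columns), df.to_numpy(float))


def write_ground_truth(truths: dict[str, GroundTruth], path) -> None:
    rows = []
    for animal_id, truth in truths.items():
        regions = truth.regions if truth.regions is not None else ["whole_brain"] * len(truth)
        for t, a, r in zip(truth.event_times_s, truth.event_amplitudes, regions):
            rows.append({"animal_id": animal_id, "region": r, "event_time_s": t, "amplitude": a})
    pd.DataFrame(rows, columns=["animal_id", "region", "event_time_s", "amplitude"]).to_csv(
        path, index=False
    )


# ----------------------------------------------------------- JSON/YAML

def write_threshold_model(model: ThresholdModel, path) -> None:
    payload = {
        "pooled_sd": model.pooled_sd,
        "multiplier": model.multiplier,
        "threshold": model.threshold,
        "n_traces": model.n_traces,
        "n_samples": model.n_samples,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_threshold_model(path) -> ThresholdModel:
    payload = json.loads(Path(path).read_text())
    model = ThresholdModel(
        pooled_sd=payload["pooled_sd"],
        multiplier=payload["multiplier"],
        n_traces=payload.get("n_traces", 0),
        n_samples=payload.get("n_samples", 0),
    )
    if not np.isclose(model.threshold, payload["threshold"]):
        raise ValueError(f"{path}: stored threshold inconsistent with pooled_sd x multiplier")
    return model


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
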