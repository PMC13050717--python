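"""Movie -> ΔF/F₀ conversion, masking, ROI segmentation and trace extraction.

The imaging model: a widefield fluorescence movie ``F(t, y, x)`` is
normalized against a per-pixel temporal-median baseline ``F₀`` to give
``ΔF/F₀% = 100 (F - F₀)/F₀``.  All downstream analysis operates on mean
traces over pixel sets (the whole-brain mask, segmented calcium-active
ROIs, or fixed-area centroid ROIs).

Coordinates are (row, col), 0-based, origin top-left.  Pixels whose
baseline is non-positive carry no information and are flagged invalid
rather than silently zeroed; they are excluded from every trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MovieStack",
    "BaselineImage",
    "DffStack",
    "RegionMasks",
    "Roi",
    "RoiSet",
    "Trace",
    "REGION_NAMES",
    "compute_baseline",
    "compute_dff",
    "segment_active_rois",
    "extract_roi_trace",
    "whole_brain_trace",
]

#: Canonical region order: left/right forebrain, left/right midbrain.
REGION_NAMES = ("FB_L", "FB_R", "MB_L", "MB_R")


@dataclass
class MovieStack:
    """Raw fluorescence time-lapse, shape (T, H, W), arbitrary units."""

    data: np.ndarray
    fs: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class BaselineImage:
    """Per-pixel baseline F₀ (same units as the movie)."""

    f0: np.ndarray

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.f0.ndim != 2:
            raise ValueError("baseline must be a 2-D image")
        if not np.all(np.isfinite(self.f0)):
            raise ValueError("baseline contains non-finite values")


@dataclass
class DffStack:
    """ΔF/F₀ in percent, shape (T, H, W); ``valid`` flags pixels with F₀ > 0."""

    data: np.ndarray
    fs: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("ΔF/F₀ stack must be T x H x W")
        if self.valid.shape != self.data.shape[1:]:
            raise ValueError("valid mask shape does not match frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class RegionMasks:
    """Whole-brain mask plus the four hemispheric region masks.

    Invariants: regions are pairwise disjoint, non-empty and contained in
    the brain mask.
    """

    brain: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain, dtype=bool)
        self.regions = {k: np.asarray(v, dtype=bool) for k, v in self.regions.items()}
        if not self.brain.any():
            raise ValueError("brain mask is empty")
        occupancy = np.zeros_like(self.brain, dtype=int)
        for name, mask in self.regions.items():
            if mask.shape != self.brain.shape:
                raise ValueError(f"region {name!r} shape mismatch")
            if not mask.any():
                raise ValueError(f"region {name!r} is empty")
            if np.any(mask & ~self.brain):
                raise ValueError(f"region {name!r} extends outside the brain mask")
            occupancy += mask
        if np.any(occupancy > 1):
            raise ValueError("region masks overlap")


@dataclass
class Roi:
    """A labelled pixel set (boolean mask over the frame)."""

    label: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiSet:
    rois: list[Roi]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def label_image(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or (self.rois[0].mask.shape if self.rois else None)
        out = np.zeros(shape, dtype=int)
        for roi in self.rois:
            out[roi.mask] = roi.label
        return out


@dataclass
class Trace:
    """A ΔF/F₀% time series with its sampling rate and provenance."""

    values: np.ndarray
    fs: float
    provenance: str = "whole_brain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


def compute_baseline(movie: MovieStack) -> BaselineImage:
    """Per-pixel temporal median over the full recording.

    For an even frame count the median is the mean of the two central
    order statistics.
    """
    return BaselineImage(np.median(movie.data, axis=0))


def compute_dff(movie: MovieStack, f0: BaselineImage) -> DffStack:
    """ΔF/F₀ in percent: ``100 (F(t) - F₀) / F₀``.

    Pixels with F₀ <= 0 are flagged invalid (NaN in the stack, False in
    ``valid``) and never contribute to traces.
    """
    if f0.f0.shape != movie.frame_shape:
        raise ValueError("baseline shape does not match movie frames")
    valid = f0.f0 > 0
    if not valid.any():
        raise ValueError("every baseline pixel is non-positive; ΔF/F₀ undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = 100.0 * (movie.data - f0.f0) / f0.f0
    dff[:, ~valid] = np.nan
    return DffStack(dff, movie.fs, valid)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def segment_active_rois(
    dff: DffStack,
    brain: np.ndarray,
    tile_px: int = 4,
    r_min: float = 0.7,
    min_tiles: int = 4,
) -> RoiSet:
    """Correlation-based segmentation of calcium-active ROIs.

    Tiles the masked area into ``tile_px`` x ``tile_px`` blocks, computes
    each tile's mean ΔF/F₀ trace, merges 4-connected adjacent tiles whose
    traces correlate at Pearson r >= ``r_min`` (union-find components),
    and keeps components of at least ``min_tiles`` tiles.  Labels are
    assigned deterministically in top-left raster order of each
    component's first tile.
    """
    brain = np.asarray(brain, dtype=bool)
    h, w = brain.shape
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    rows = np.flatnonzero(brain.any(axis=1))
    cols = np.flatnonzero(brain.any(axis=0))
    if len(rows) == 0:
        raise ValueError("brain mask is empty")
    if tile_px > len(rows) or tile_px > len(cols):
        raise ValueError("tile_px larger than mask extent")

    member = brain & dff.valid
    tiles: list[tuple[int, int]] = []
    tile_traces: list[np.ndarray] = []
    index: dict[tuple[int, int], int] = {}
    for ti, r0 in enumerate(range(0, h, tile_px)):
        for tj, c0 in enumerate(range(0, w, tile_px)):
            block = member[r0 : r0 + tile_px, c0 : c0 + tile_px]
            if not block.any():
                continue
            sub = dff.data[:, r0 : r0 + tile_px, c0 : c0 + tile_px]
            trace = np.nanmean(sub[:, block], axis=1)
            index[(ti, tj)] = len(tiles)
            tiles.append((ti, tj))
            tile_traces.append(trace)

    traces = np.asarray(tile_traces)
    sd = traces.std(axis=1)
    uf = _UnionFind(len(tiles))
    for k, (ti, tj) in enumerate(tiles):
        for dij in ((0, 1), (1, 0)):
            nb = (ti + dij[0], tj + dij[1])
            if nb not in index:
                continue
            m = index[nb]
            if sd[k] == 0 or sd[m] == 0:
                continue  # zero-variance tiles never merge
            r = np.corrcoef(traces[k], traces[m])[0, 1]
            if r >= r_min:
                uf.union(k, m)

    components: dict[int, list[int]] = {}
    for k in range(len(tiles)):
        components.setdefault(uf.find(k), []).append(k)

    keep = sorted(
        (sorted(members) for members in components.values() if len(members) >= min_tiles),
        key=lambda ms: tiles[ms[0]],
    )
    rois = []
    for label, members in enumerate(keep, start=1):
        mask = np.zeros((h, w), dtype=bool)
        for k in members:
            ti, tj = tiles[k]
            r0, c0 = ti * tile_px, tj * tile_px
            mask[r0 : r0 + tile_px, c0 : c0 + tile_px] |= member[
                r0 : r0 + tile_px, c0 : c0 + tile_px
            ]
        rois.append(Roi(label, mask))
    return RoiSet(rois)


def extract_roi_trace(dff: DffStack, roi: Roi | np.ndarray, provenance: str | None = None) -> Trace:
    """Per-frame mean ΔF/F₀% over the ROI's valid pixels."""
    mask = roi.mask if isinstance(roi, Roi) else np.asarray(roi, dtype=bool)
    member = mask & dff.valid
    if not member.any():
        raise ValueError("ROI has no valid pixels")
    values = dff.data[:, member].mean(axis=1)
    if provenance is None:
        provenance = f"roi_{roi.label}" if isinstance(roi, Roi) else "roi"
    return Trace(values, dff.fs, provenance)


def whole_brain_trace(dff: DffStack, brain: np.ndarray) -> Trace:
    """Mean ΔF/F₀% over all valid brain-mask pixels, per frame."""
    return extract_roi_trace(dff, np.asarray(brain, dtype=bool), provenance="whole_brain")
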