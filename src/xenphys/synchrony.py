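"""Interhemispheric synchrony from fixed-area centroid ROIs.

To minimize light scatter from neighbouring structures, each region's
signal is read from a fixed-area (default 500-pixel) circular ROI placed
at the region's geometric centroid.  Synchrony between the four regions
(left/right forebrain and midbrain) is the Pearson correlation between
their raw ΔF/F₀% centroid traces, collected into a symmetric 4x4 matrix.

Centroid circles are *not* clipped to the region mask by default: for a
concave region the geometric centroid (and hence part of the circle) may
fall outside the member pixels; pass ``clip_to_region=True`` to restrict
candidate pixels to the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xenphys.imaging import REGION_NAMES, DffStack, RegionMasks, extract_roi_trace

__all__ = [
    "CentroidRoi",
    "CorrelationMatrix",
    "centroid_circular_roi",
    "centroid_rois",
    "synchrony_matrix",
    "synchrony_summary",
    "pearson_r",
]


@dataclass
class CentroidRoi:
    region: str
    center: tuple[float, float]
    mask: np.ndarray
    target_area_px: int = 500

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CorrelationMatrix:
    """Pearson coefficients between region traces; NaN marks undefined
    entries (zero-variance traces), never a silent zero."""

    labels: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.labels)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")

    def entry(self, a: str, b: str) -> float:
        return float(self.r[self.labels.index(a), self.labels.index(b)])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (not 0) when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def centroid_circular_roi(
    region_mask: np.ndarray,
    area_px: int = 500,
    clip_to_region: bool = False,
    region: str = "roi",
) -> CentroidRoi:
    """Fixed-area circular ROI at the region's geometric centroid.

    The centroid is the mean of member pixel coordinates.  The ROI takes
    the ``area_px`` pixels nearest the centroid (Euclidean distance of
    pixel centers; ties broken in row-major order), which is equivalent
    to growing the nominal radius ``sqrt(area/pi)`` until at least
    ``area_px`` pixels are covered and trimming back by distance rank.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    if area_px < 1:
        raise ValueError("area_px must be >= 1")
    rows, cols = np.nonzero(mask)
    center = (float(rows.mean()), float(cols.mean()))

    if clip_to_region:
        cand_r, cand_c = rows, cols
    else:
        h, w = mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cand_r, cand_c = yy.ravel(), xx.ravel()
    if len(cand_r) < area_px:
        raise ValueError(
            f"only {len(cand_r)} candidate pixels available for a {area_px}-pixel ROI"
        )
    d2 = (cand_r - center[0]) ** 2 + (cand_c - center[1]) ** 2
    order = np.lexsort((cand_c, cand_r, d2))[:area_px]
    out = np.zeros(mask.shape, dtype=bool)
    out[cand_r[order], cand_c[order]] = True
    return CentroidRoi(region, center, out, area_px)


def centroid_rois(
    masks: RegionMasks, area_px: int = 500, clip_to_region: bool = False
) -> dict[str, CentroidRoi]:
    """Centroid ROIs for the four canonical regions."""
    missing = [n for n in REGION_NAMES if n not in masks.regions]
    if missing:
        raise ValueError(f"missing region masks: {missing}")
    return {
        name: centroid_circular_roi(masks.regions[name], area_px, clip_to_region, name)
        for name in REGION_NAMES
    }


def synchrony_matrix(dff: DffStack, rois: dict[str, CentroidRoi]) -> CorrelationMatrix:
    """4x4 Pearson matrix between the centroid-ROI mean traces."""
    labels = tuple(rois.keys())
    if len(set(labels)) != len(labels) or len(labels) < 2:
        raise ValueError("need distinct regions")
    traces = [extract_roi_trace(dff, rois[name].mask, provenance=name).values for name in labels]
    k = len(labels)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = pearson_r(traces[i], traces[j])
    return CorrelationMatrix(labels, r)


def synchrony_summary(mat: CorrelationMatrix) -> dict[str, float]:
    """The four named pairwise couplings used for group comparisons."""
    return {
        "mb_lr": mat.entry("MB_L", "MB_R"),
        "fb_lr": mat.entry("FB_L", "FB_R"),
        "mbfb_left": mat.entry("MB_L", "FB_L"),
        "mbfb_right": mat.entry("MB_R", "FB_R"),
    }
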