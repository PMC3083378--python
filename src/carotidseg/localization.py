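"""Phase 1 — rough localization of the carotid artery in a full slice.

The artery is found from three features: intensity (two-stage Otsu
thresholding separates first foreground from background/air, then bright
vessel lumens from other tissue), area (the two largest bright components of
an image side are the jugular vein and the carotid artery) and shape (the
artery is the rounder of the two, measured by the major/minor axis ratio of
a PCA of its boundary points).  A square region of interest centered on the
selected candidate is handed to phase 2.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "SegmentationMasks",
    "VesselCandidate",
    "CenterEstimate",
    "Roi",
    "NoCandidateError",
    "otsu_threshold",
    "two_stage_segmentation",
    "morphological_open",
    "extract_candidates",
    "select_artery",
    "extract_roi",
    "default_roi_half_width",
]

BACKGROUND_SENTINEL = -1.0

# structure element: central pixel plus its 4-neighborhood (disk of radius 1)
_OPEN_STRUCTURE = ndimage.generate_binary_structure(2, 1)


class NoCandidateError(RuntimeError):
    """No vessel candidate found on the requested image side."""


@dataclasses.dataclass
class SegmentationMasks:
    stage1_labels: np.ndarray  # raw values on foreground, -1 on background
    stage2_mask: np.ndarray  # candidate lumens within the foreground
    opened_mask: np.ndarray  # stage2_mask after morphological opening


@dataclasses.dataclass
class VesselCandidate:
    label_id: int
    centroid: tuple[float, float]  # (row, col)
    area_px2: float
    boundary_points: np.ndarray  # (n, 2) (row, col)
    major_axis_len: float
    minor_axis_len: float

    @property
    def axis_ratio(self) -> float:
        if self.minor_axis_len <= 0:
            return math.inf
        return self.major_axis_len / self.minor_axis_len


@dataclasses.dataclass
class CenterEstimate:
    center: tuple[float, float]  # (row, col)
    side: str  # "left" | "right"
    roi_half_width: int


@dataclasses.dataclass
class Roi:
    """Square window extracted around an estimated artery center.

    ``center`` is the position of the estimated artery center inside the
    window; ``origin`` the (row, col) of the window's top-left pixel in the
    source image.  When the window is clipped at an image border the center
    is not the geometric middle — the offset is preserved here.
    """

    image: np.ndarray
    center: tuple[int, int]
    origin: tuple[int, int]


def otsu_threshold(values: np.ndarray, ignore_value: float | None = None) -> float:
    """Threshold maximizing the between-class variance of the histogram.

    Values equal to ``ignore_value`` (e.g. the background sentinel -1) are
    removed before the histogram is formed.  Integer-valued inputs are
    histogrammed at their native gray levels; continuous inputs (e.g.
    normalized edge maps) use 256 uniform bins.  The returned threshold lies
    strictly between the last level of the low class and the first level of
    the high class; foreground is ``values > threshold``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if ignore_value is not None:
        v = v[v != ignore_value]
    if v.size == 0:
        raise ValueError("no values left after removing the ignore sentinel")
    integral = bool(np.all(v == np.rint(v)))
    if integral:
        levels, counts = np.unique(v, return_counts=True)
        if levels.size < 2:
            raise ValueError("constant input: no separable classes")
    else:
        counts, edges = np.histogram(v, bins=256)
        levels = 0.5 * (edges[:-1] + edges[1:])
        nz = counts > 0
        levels, counts = levels[nz], counts[nz]
        if levels.size < 2:
            raise ValueError("constant input: no separable classes")

    w = counts.astype(np.float64)
    cw = np.cumsum(w)
    cs = np.cumsum(w * levels)
    total_w = cw[-1]
    total_s = cs[-1]
    w0 = cw[:-1]
    w1 = total_w - w0
    mu0 = cs[:-1] / w0
    mu1 = (total_s - cs[:-1]) / w1
    crit = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(crit))
    return float(0.5 * (levels[k] + levels[k + 1]))


def two_stage_segmentation(raw: np.ndarray) -> SegmentationMasks:
    """Two-stage Otsu segmentation of a full slice.

    Stage 1 separates the subject from the (dark) background and air
    chambers; background pixels are marked -1 and ignored thereafter.
    Stage 2 thresholds the remaining foreground to isolate the bright vessel
    lumens, and a morphological opening removes speckle noise and cuts thin
    connections between the jugular vein and the carotid artery.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw image intensities must be nonnegative")
    t1 = otsu_threshold(raw)
    foreground = raw > t1
    stage1 = np.where(foreground, raw, BACKGROUND_SENTINEL)
    t2 = otsu_threshold(stage1, ignore_value=BACKGROUND_SENTINEL)
    stage2 = stage1 > t2
    return SegmentationMasks(
        stage1_labels=stage1,
        stage2_mask=stage2,
        opened_mask=morphological_open(stage2),
    )


def morphological_open(mask: np.ndarray) -> np.ndarray:
    """Binary opening with the 5-pixel disk (center + 4-neighborhood)."""
    return ndimage.binary_opening(np.asarray(mask, dtype=bool), structure=_OPEN_STRUCTURE)


def _boundary_points(component: np.ndarray) -> np.ndarray:
    # Sobel magnitude on the binary component mask; component pixels with a
    # nonzero response form the morphological edge.
    grad = filters.sobel(component.astype(np.float64))
    return np.argwhere(component & (grad > 1e-12))


def _pca_axes(points: np.ndarray) -> tuple[float, float]:
    if points.shape[0] < 3:
        return 0.0, 0.0
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / points.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    # full axis length of the equivalent uniform ring: 2 * sqrt(2 * lambda)
    minor, major = (2.0 * np.sqrt(2.0 * eigvals)).tolist()
    return major, minor


def extract_candidates(mask: np.ndarray, side: str) -> list[VesselCandidate]:
    """Two largest 8-connected components on one side of the midline.

    The slice is split at its vertical midline; ``side`` selects the image
    half.  Each candidate carries its Sobel-derived boundary points and the
    PCA major/minor axis lengths of those points.
    """
    mask = np.asarray(mask, dtype=bool)
    half = mask.shape[1] // 2
    if side == "left":
        sub, col_offset = mask[:, :half], 0
    elif side == "right":
        sub, col_offset = mask[:, half:], half
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    labels = measure.label(sub, connectivity=2)
    if labels.max() == 0:
        raise NoCandidateError(f"no vessel candidate on the {side} side")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    order = np.argsort(areas)[::-1]
    candidates = []
    for label_id in order[:2]:
        if areas[label_id] == 0:
            continue
        component = labels == label_id
        pts = np.argwhere(component).astype(float)
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean() + col_offset))
        boundary = _boundary_points(component).astype(float)
        boundary[:, 1] += col_offset
        major, minor = _pca_axes(boundary)
        candidates.append(
            VesselCandidate(
                label_id=int(label_id),
                centroid=centroid,
                area_px2=float(areas[label_id]),
                boundary_points=boundary,
                major_axis_len=major,
                minor_axis_len=minor,
            )
        )
    return candidates


def select_artery(
    candidates: list[VesselCandidate],
    side: str = "left",
    roi_half_width: int | None = None,
    pixel_size_mm: float = 0.53125,
) -> CenterEstimate:
    """Pick the roundest candidate (axis ratio closest to 1) as the artery.

    If two candidates tie in roundness within 0.01 the smaller one wins (the
    carotid artery is usually smaller than the jugular vein).
    """
    if not candidates:
        raise NoCandidateError("no candidates to select from")
    best_ratio = min(c.axis_ratio for c in candidates)
    tied = [c for c in candidates if c.axis_ratio <= best_ratio + 0.01]
    chosen = min(tied, key=lambda c: c.area_px2)
    if roi_half_width is None:
        roi_half_width = default_roi_half_width(pixel_size_mm)
    return CenterEstimate(center=chosen.centroid, side=side, roi_half_width=roi_half_width)


def default_roi_half_width(pixel_size_mm: float, half_width_mm: float = 7.5) -> int:
    """First-frame ROI half-width: 7.5 mm comfortably exceeds a normal CCA radius."""
    return int(math.ceil(half_width_mm / pixel_size_mm))


def extract_roi(raw: np.ndarray, est: CenterEstimate) -> Roi:
    """Square window of side ``2*roi_half_width + 1`` anchored on the center.

    The window is clipped at image borders; the anchoring offset is recorded
    in the returned :class:`Roi`.
    """
    raw = np.asarray(raw)
    cr = int(round(est.center[0]))
    cc = int(round(est.center[1]))
    h, w = raw.shape
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError(f"center {est.center} lies outside the image")
    hw = est.roi_half_width
    r0, r1 = max(0, cr - hw), min(h, cr + hw + 1)
    c0, c1 = max(0, cc - hw), min(w, cc + hw + 1)
    return Roi(image=raw[r0:r1, c0:c1].copy(), center=(cr - r0, cc - c0), origin=(r0, c0))
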