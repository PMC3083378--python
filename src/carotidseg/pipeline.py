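"""Two-phase segmentation pipeline over an image sequence.

Frame 1 runs the full localization (two-stage Otsu, opening, candidate
shape analysis).  Every subsequent frame reuses the previous frame's
detected lumen center as its ROI center and sets the ROI half-width to
``ceil(1.5 * previous mean radius)``, so only the first frame pays the
full-slice cost.  Each frame then runs directional gradient -> binary edge
-> circle Hough -> polar DP -> smoothing -> area.  A frame whose propagated
ROI fails falls back to full localization; if that also fails the frame is
recorded as failed, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from typing import Any

import numpy as np

from . import __version__
from .gradient import binarize_negative_edges, directional_gradient
from .hough import default_radius_range, hough_circles
from .localization import (
    CenterEstimate,
    default_roi_half_width,
    extract_candidates,
    extract_roi,
    select_artery,
    two_stage_segmentation,
)
from .polar_dp import DPParams, trace_lumen

__all__ = ["PipelineConfig", "FrameRecord", "SequenceResult", "process_frame", "process_sequence"]

logger = logging.getLogger("carotidseg")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full pipeline.

    The defaults ``alpha=0.3, sigma=2, d_r=1`` are the standard working
    point of the guided DP; the radius search range and ROI sizes derive
    from carotid anatomy and the pixel size.
    """

    alpha: float = 0.3
    sigma: float = 2.0
    d_r: int = 1
    r_min_mm: float = 1.5
    r_max_mm: float = 6.0
    n_angles: int = 360
    pixel_size_mm: float = 0.53125
    side: str = "left"
    roi_expansion_factor: float = 1.5
    roi_half_width_mm: float = 7.5
    gray_max: float = 255.0
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


@dataclasses.dataclass
class FrameRecord:
    frame: int
    status: str  # "ok" | "failed"
    center: tuple[float, float] | None = None  # (row, col) in full-image coords
    radius_px: float | None = None  # mean sub-pixel contour radius
    hough_radius_px: int | None = None
    contour: np.ndarray | None = None  # (n, 2) full-image (row, col)
    area_px2: float | None = None
    area_mm2: float | None = None
    roi_half_width: int | None = None
    used_full_localization: bool = False
    message: str = ""


@dataclasses.dataclass
class SequenceResult:
    records: list[FrameRecord]
    config: PipelineConfig
    version: str
    started: float
    finished: float

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.asarray(
            [r.area_mm2 if r.area_mm2 is not None else np.nan for r in self.records]
        )


def _localize(frame: np.ndarray, config: PipelineConfig) -> CenterEstimate:
    masks = two_stage_segmentation(frame)
    candidates = extract_candidates(masks.opened_mask, config.side)
    return select_artery(
        candidates,
        side=config.side,
        roi_half_width=default_roi_half_width(config.pixel_size_mm, config.roi_half_width_mm),
        pixel_size_mm=config.pixel_size_mm,
    )


def process_frame(
    raw: np.ndarray,
    center: tuple[float, float],
    roi_half_width: int,
    config: PipelineConfig,
) -> FrameRecord:
    """Phase-2 boundary extraction for one frame around a known rough center."""
    est = CenterEstimate(center=center, side=config.side, roi_half_width=roi_half_width)
    roi = extract_roi(raw, est)
    edge = directional_gradient(roi.image, roi.center)
    edges = binarize_negative_edges(edge)
    h, w = roi.image.shape
    max_border = min(roi.center[0], roi.center[1], h - 1 - roi.center[0], w - 1 - roi.center[1])
    radius_range = default_radius_range(
        config.pixel_size_mm,
        roi_half_width=max(3, int(max_border)),
        r_min_mm=config.r_min_mm,
        r_max_mm=config.r_max_mm,
    )
    circle = hough_circles(edges.mask, radius_range)
    params = DPParams(
        alpha=config.alpha, sigma=config.sigma, d_r=config.d_r, prior_radius=circle.radius
    )
    contour = trace_lumen(
        edge,
        circle,
        params=params,
        n_angles=config.n_angles,
        pixel_size_mm=config.pixel_size_mm,
    )
    origin = np.asarray(roi.origin, dtype=np.float64)
    points = contour.cartesian_points + origin
    center_full = (roi.origin[0] + circle.center[0], roi.origin[1] + circle.center[1])
    return FrameRecord(
        frame=-1,
        status="ok",
        center=(float(center_full[0]), float(center_full[1])),
        radius_px=float(contour.radii_smoothed.mean()),
        hough_radius_px=circle.radius,
        contour=points,
        area_px2=contour.area_px2,
        area_mm2=contour.area_mm2,
        roi_half_width=roi_half_width,
    )


def process_sequence(frames: np.ndarray, config: PipelineConfig | None = None) -> SequenceResult:
    """Run the full two-phase pipeline with inter-frame ROI propagation."""
    if config is None:
        config = PipelineConfig()
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("need at least one frame")
    started = time.time()
    records: list[FrameRecord] = []
    prev_center: tuple[float, float] | None = None
    prev_radius: float | None = None
    for i, frame in enumerate(frames):
        record = None
        if i > 0 and prev_center is not None and prev_radius is not None:
            half = int(math.ceil(config.roi_expansion_factor * prev_radius))
            try:
                record = process_frame(frame, prev_center, half, config)
            except Exception as exc:  # noqa: BLE001 - fall back to full localization
                logger.warning("frame %d: propagated ROI failed (%s); re-localizing", i, exc)
                record = None
        if record is None:
            try:
                est = _localize(frame, config)
                record = process_frame(frame, est.center, est.roi_half_width, config)
                record.used_full_localization = True
            except Exception as exc:  # noqa: BLE001
                if i == 0:
                    raise RuntimeError(f"localization failed on the first frame: {exc}") from exc
                logger.error("frame %d failed: %s", i, exc)
                record = FrameRecord(frame=i, status="failed", message=str(exc))
        record.frame = i
        records.append(record)
        if record.status == "ok":
            prev_center = record.center
            prev_radius = record.radius_px
    finished = time.time()
    logger.info(
        "processed %d frames in %.2f s", frames.shape[0], finished - started
    )
    return SequenceResult(
        records=records,
        config=config,
        version=__version__,
        started=started,
        finished=finished,
    )
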