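"""Circle Hough transform seeding the dynamic-programming circle prior.

One accumulator per integer radius; each edge pixel votes with unit weight
for every center on the circle of that radius around it.  The global vote
maximum over all (radius, center) combinations gives the artery's rough
center and radius.  Ties are broken deterministically: smallest radius
first, then lexicographic (row, col) of the center.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.draw import circle_perimeter

__all__ = ["CircleHypothesis", "RadiusRange", "NoCircleError", "hough_circles", "default_radius_range"]


class NoCircleError(RuntimeError):
    """Raised when the edge mask is empty and no circle can be voted for."""


@dataclasses.dataclass(frozen=True)
class RadiusRange:
    r_min: int
    r_max: int

    def __post_init__(self):
        if not (1 <= self.r_min < self.r_max):
            raise ValueError(f"need 1 <= r_min < r_max, got [{self.r_min}, {self.r_max}]")


@dataclasses.dataclass(frozen=True)
class CircleHypothesis:
    center: tuple[int, int]  # (row, col)
    radius: int
    score: float  # accumulator votes


def default_radius_range(
    pixel_size_mm: float,
    roi_half_width: int | None = None,
    r_min_mm: float = 1.5,
    r_max_mm: float = 6.0,
) -> RadiusRange:
    """Anatomy-derived search range for the common carotid artery radius."""
    r_min = max(1, int(math.ceil(r_min_mm / pixel_size_mm)))
    r_max = int(math.floor(r_max_mm / pixel_size_mm))
    if roi_half_width is not None:
        r_max = min(r_max, roi_half_width - 1)
    if r_max <= r_min:
        r_max = r_min + 1
    return RadiusRange(r_min, r_max)


def _perimeter_offsets(radius: int) -> np.ndarray:
    rr, cc = circle_perimeter(0, 0, radius)
    return np.unique(np.column_stack([rr, cc]), axis=0)


def hough_circles(edges: np.ndarray, radius_range: RadiusRange) -> CircleHypothesis:
    """Best-voted circle over the given integer radius range.

    Each edge pixel casts one vote per distinct perimeter cell of the
    candidate circle around it; votes landing outside the raster are
    discarded.
    """
    mask = np.asarray(edges, dtype=bool)
    if not mask.any():
        raise NoCircleError("edge mask is empty")
    h, w = mask.shape
    pixels = np.argwhere(mask)
    best: CircleHypothesis | None = None
    for radius in range(radius_range.r_min, radius_range.r_max + 1):
        offsets = _perimeter_offsets(radius)
        centers = pixels[:, None, :] - offsets[None, :, :]
        centers = centers.reshape(-1, 2)
        valid = (
            (centers[:, 0] >= 0)
            & (centers[:, 0] < h)
            & (centers[:, 1] >= 0)
            & (centers[:, 1] < w)
        )
        centers = centers[valid]
        acc = np.zeros((h, w), dtype=np.int64)
        np.add.at(acc, (centers[:, 0], centers[:, 1]), 1)
        score = int(acc.max())
        if best is None or score > best.score:
            # first maximum in C-order = lexicographic (row, col)
            row, col = np.unravel_index(int(np.argmax(acc)), acc.shape)
            best = CircleHypothesis(center=(int(row), int(col)), radius=int(radius), score=score)
    assert best is not None
    return best
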