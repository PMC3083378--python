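"""Sub-pixel lumen boundary by circle-model-guided dynamic programming.

The normalized edge map is resampled on a polar grid about the circle found
by the Hough stage: rows are radii 1..M px, columns a uniform angle grid on
[0, 2*pi) with the first column duplicated at the end so that a left-to-right
path is a closed contour.  Dynamic programming then finds the path that
minimizes

    C(x, y) = w(y) * R_p(x, y) + min_{|j| <= d_r} [ C(x-1, y+j) + alpha*|j| ]

with boundary condition ``C(1, y) = R_p(1, y)``, where ``w(y) =
exp(-(y - r)^2 / (2*sigma^2))`` is the Gaussian circle prior around the
Hough radius r.  Edge values are negative at the lumen boundary, so small
costs mean strong boundary evidence; the multiplicative weight suppresses
off-circle evidence when sigma is small and vanishes (w -> 1, plain DP) as
sigma grows.  ``alpha`` penalizes radial jumps ``j`` between neighboring
angles; ``d_r`` bounds them, giving each node at most ``2*d_r + 1``
predecessors.

The integer DP path is smoothed with a circular 5-point moving average,
which yields fractional (sub-pixel) radii, converted back to a Cartesian
polygon whose shoelace area is the lumen area.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import ndimage

from .gradient import EdgeMap
from .hough import CircleHypothesis

__all__ = [
    "PolarMap",
    "DPParams",
    "DPResult",
    "LumenContour",
    "to_polar",
    "circle_weight",
    "dp_boundary",
    "smooth_contour",
    "polar_to_cartesian",
    "contour_area",
    "trace_lumen",
]


@dataclasses.dataclass
class PolarMap:
    """Angle-by-radius resampling of an edge map.

    ``values`` has M rows (radii 1..M px) and N+1 columns (angles on
    [0, 2*pi]; the last column is a copy of the first, enforcing closure).
    """

    values: np.ndarray
    center: tuple[int, int]
    angle_step: float

    @property
    def n_radii(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1] - 1


@dataclasses.dataclass(frozen=True)
class DPParams:
    """Dynamic-programming parameters.

    alpha : smoothness weight in (0, 1]; larger gives smoother contours.
    sigma : width (px) of the Gaussian circle prior; small values force a
        near-circular result, ``math.inf`` disables the prior entirely.
        Suggested working range [0.4, 4].
    d_r : maximum radial jump (px) between adjacent angle columns.
    prior_radius : circle-prior radius in px (from the Hough stage); may be
        None when sigma is infinite.
    """

    alpha: float = 0.3
    sigma: float = 2.0
    d_r: int = 1
    prior_radius: float | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.d_r < 1 or int(self.d_r) != self.d_r:
            raise ValueError(f"d_r must be a positive integer, got {self.d_r}")
        if self.prior_radius is None and not math.isinf(self.sigma):
            raise ValueError("a finite sigma requires a prior_radius")


@dataclasses.dataclass
class DPResult:
    cost_map: np.ndarray  # C(x, y), shape (M, K)
    index_map: np.ndarray  # X(x, y): predecessor row index, shape (M, K)
    path: np.ndarray  # radius (px, 1-based) per angle column, ints, length K
    total_cost: float


@dataclasses.dataclass
class LumenContour:
    radii_smoothed: np.ndarray  # sub-pixel radius per angle (wrap excluded)
    cartesian_points: np.ndarray  # (n, 2) (row, col) closed polygon vertices
    area_px2: float
    area_mm2: float
    center: tuple[float, float]


def to_polar(
    edge: EdgeMap | np.ndarray,
    center: tuple[int, int] | None = None,
    max_radius: int = 14,
    n_angles: int = 360,
) -> PolarMap:
    """Bilinear polar resampling of an edge map about a center.

    Samples at ``center + rho * (sin(theta), cos(theta))`` for rho = 1..max_radius,
    theta on a uniform grid; samples falling outside the raster are 0 (the
    uncalculated border).  A wrap column (bit-exact copy of the first) is
    appended.
    """
    if isinstance(edge, EdgeMap):
        values = edge.values
        if center is None:
            center = edge.center
    else:
        values = np.asarray(edge, dtype=np.float64)
        if center is None:
            raise ValueError("center is required for a bare array")
    theta = np.arange(n_angles) * (2.0 * math.pi / n_angles)
    rho = np.arange(1, max_radius + 1, dtype=np.float64)
    rows = center[0] + rho[:, None] * np.sin(theta)[None, :]
    cols = center[1] + rho[:, None] * np.cos(theta)[None, :]
    sampled = ndimage.map_coordinates(
        values, [rows, cols], order=1, mode="constant", cval=0.0
    )
    sampled = np.concatenate([sampled, sampled[:, :1]], axis=1)
    return PolarMap(values=sampled, center=tuple(center), angle_step=2.0 * math.pi / n_angles)


def circle_weight(y, prior_radius: float, sigma: float):
    """Gaussian circle-prior strength ``exp(-(y - r)^2 / (2 sigma^2))``.

    Equals 1 at the prior radius and tends to 1 everywhere as sigma grows,
    reducing the guided DP to plain DP.  ``y`` may be an array.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=np.float64)
    if math.isinf(sigma):
        return np.ones_like(y) if y.ndim else 1.0
    out = np.exp(-((y - prior_radius) ** 2) / (2.0 * sigma**2))
    return out if y.ndim else float(out)


def _offset_order(d_r: int) -> np.ndarray:
    # tie-break preference: smallest |j| first, negative before positive
    order = [0]
    for j in range(1, d_r + 1):
        order.extend([-j, j])
    return np.asarray(order)


def dp_boundary(polar: PolarMap | np.ndarray, params: DPParams) -> DPResult:
    """Minimum-cost closed path through the polar edge map.

    The path endpoint is the cost minimum over the last (wrap) column and is
    traced backward through the stored predecessor indices.  Ties are broken
    deterministically: among equal-cost transitions the smallest ``|j|``
    wins (negative before positive); among equal-cost endpoints the row
    nearest the prior radius wins, then the smaller row.  A path whose two
    ends differ by more than ``d_r`` triggers a closure warning.
    """
    values = polar.values if isinstance(polar, PolarMap) else np.asarray(polar, np.float64)
    m, k = values.shape
    if m < 2 * params.d_r + 1:
        raise ValueError(f"need at least {2 * params.d_r + 1} radius rows, got {m}")
    if k < 2:
        raise ValueError("polar map needs at least two angle columns")
    radii = np.arange(1, m + 1, dtype=np.float64)
    if math.isinf(params.sigma):
        weights = np.ones(m)
    else:
        weights = circle_weight(radii, params.prior_radius, params.sigma)

    offsets = _offset_order(params.d_r)
    cost = np.empty((m, k))
    index = np.zeros((m, k), dtype=np.int64)
    cost[:, 0] = values[:, 0]
    row_ids = np.arange(m)
    for x in range(1, k):
        cand = np.full((offsets.size, m), np.inf)
        for i, j in enumerate(offsets):
            src = row_ids + j
            valid = (src >= 0) & (src < m)
            cand[i, valid] = cost[src[valid], x - 1] + params.alpha * abs(j)
        pick = np.argmin(cand, axis=0)  # first minimum = preferred offset
        cost[:, x] = weights * values[:, x] + cand[pick, row_ids]
        index[:, x] = row_ids + offsets[pick]

    last = cost[:, k - 1]
    best_cost = last.min()
    ties = np.flatnonzero(last == best_cost)
    if params.prior_radius is not None and ties.size > 1:
        dist = np.abs(radii[ties] - params.prior_radius)
        ties = ties[dist == dist.min()]
    end_row = int(ties[0])

    path_rows = np.empty(k, dtype=np.int64)
    path_rows[k - 1] = end_row
    for x in range(k - 1, 0, -1):
        path_rows[x - 1] = index[path_rows[x], x]
    path = path_rows + 1  # radii in px

    if abs(int(path[0]) - int(path[-1])) > params.d_r:
        warnings.warn(
            "contour endpoints differ by more than d_r; the boundary may not close"
        )
    return DPResult(cost_map=cost, index_map=index, path=path, total_cost=float(best_cost))


def smooth_contour(path: np.ndarray) -> np.ndarray:
    """Circular 5-point moving average (center + 2 neighbors each side).

    Turns the integer DP radii into fractional, sub-pixel radii while
    preserving the circular mean exactly.
    """
    p = np.asarray(path, dtype=np.float64)
    if p.size < 5:
        raise ValueError("need at least 5 points to smooth")
    return (
        np.roll(p, 2) + np.roll(p, 1) + p + np.roll(p, -1) + np.roll(p, -2)
    ) / 5.0


def polar_to_cartesian(
    radii: np.ndarray, center: tuple[float, float], angle_step: float
) -> np.ndarray:
    """Closed polygon vertices ``(row, col) = center + rho*(sin, cos)(theta)``."""
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    theta = np.arange(radii.size) * angle_step
    return np.column_stack(
        [center[0] + radii * np.sin(theta), center[1] + radii * np.cos(theta)]
    )


def contour_area(polygon: np.ndarray, pixel_size_mm: float) -> tuple[float, float]:
    """Shoelace area of a closed polygon, in px^2 and mm^2."""
    pts = np.asarray(polygon, dtype=np.float64)
    if pts.shape[0] < 3 or np.unique(pts, axis=0).shape[0] < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    r = pts[:, 0]
    c = pts[:, 1]
    area_px2 = 0.5 * abs(float(np.dot(c, np.roll(r, -1)) - np.dot(np.roll(c, -1), r)))
    return area_px2, area_px2 * pixel_size_mm**2


def trace_lumen(
    edge: EdgeMap,
    circle: CircleHypothesis,
    params: DPParams | None = None,
    n_angles: int = 360,
    max_radius: int | None = None,
    pixel_size_mm: float = 0.53125,
) -> LumenContour:
    """Full phase-2 refinement: polar transform, guided DP, smoothing, area."""
    if params is None:
        params = DPParams(prior_radius=circle.radius)
    elif params.prior_radius is None and not math.isinf(params.sigma):
        params = dataclasses.replace(params, prior_radius=circle.radius)
    h, w = edge.values.shape
    cr, cc = circle.center
    if max_radius is None:
        max_radius = int(min(cr, cc, h - 1 - cr, w - 1 - cc)) - 1
    polar = to_polar(edge, circle.center, max_radius=max_radius, n_angles=n_angles)
    result = dp_boundary(polar, params)
    radii = smooth_contour(result.path[:-1])  # drop the duplicated wrap sample
    points = polar_to_cartesian(radii, circle.center, polar.angle_step)
    area_px2, area_mm2 = contour_area(points, pixel_size_mm)
    return LumenContour(
        radii_smoothed=radii,
        cartesian_points=points,
        area_px2=area_px2,
        area_mm2=area_mm2,
        center=(float(cr), float(cc)),
    )
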