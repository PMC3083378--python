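"""Radial directional gradient of an ROI about the artery center.

For each pixel the intensity derivative is taken along the ray from the
artery center through that pixel.  The ray direction is resolved at 45
degree resolution: the plane is split into eight sectors, and within a
sector the gradient is a linear blend of the central differences along the
two bracketing 8-neighbor axes, with blend weight ``t = 4*theta/pi``
measured from the sector's start.  Because the lumen is brighter than the
wall, the lumen boundary produces *negative* values when walking outward;
the near edge of the adjacent jugular vein (dark tissue into bright vein) is
positive and is discarded, which is what makes the search immune to the
vein despite its proximity.

Angles use the image convention of a top-down row axis: ``theta =
atan2(d_row, d_col)``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .localization import otsu_threshold

__all__ = [
    "EdgeMap",
    "BinaryEdge",
    "region_index",
    "directional_gradient",
    "binarize_negative_edges",
]

# 8-neighbor offsets (d_row, d_col); axis k sits at angle k*45deg under
# theta = atan2(d_row, d_col)
_AXIS_OFFSETS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)

_SECTOR_LABELS = {0: "1", 1: "2", 2: "3", 3: "4", -4: "1'", -3: "6", -2: "7", -1: "8"}


@dataclasses.dataclass
class EdgeMap:
    """Signed radial gradient raster, normalized to [-1, 1].

    Negative values mark bright-to-dark transitions along the outward radial
    direction, i.e. the lumen boundary.
    """

    values: np.ndarray
    center: tuple[int, int]  # (row, col) within the ROI


@dataclasses.dataclass
class BinaryEdge:
    mask: np.ndarray
    threshold: float | None = None


def region_index(theta: float) -> str:
    """45-degree sector containing a radial direction.

    Sectors over positive angles are labelled 1-4, over negative angles
    8 down to 6, and the sector ``[-pi, -3*pi/4)`` is labelled ``1'`` since it
    reuses Region 1's interpolation pairs.  Angles outside ``[-pi, pi]`` are
    wrapped, never rejected.
    """
    wrapped = math.remainder(theta, 2.0 * math.pi)  # (-pi, pi]
    if wrapped == math.pi:
        wrapped = -math.pi
    k = math.floor(wrapped / (math.pi / 4.0))
    if k == 4:  # guard against floating wrap at +pi
        k = -4
    return _SECTOR_LABELS[k]


def directional_gradient(roi: np.ndarray, center: tuple[int, int]) -> EdgeMap:
    """Signed radial gradient of ``roi`` about ``center``, normalized to [-1, 1].

    Pixels on the ROI border are not calculated (their 8-neighborhood is
    incomplete) and are left at 0, as is the center pixel, whose radial
    direction is undefined.
    """
    g = np.asarray(roi, dtype=np.float64)
    h, w = g.shape
    cr, cc = center
    if not (1 <= cr < h - 1 and 1 <= cc < w - 1):
        raise ValueError("center must lie strictly inside the ROI border")

    # central differences along the 8 axes (forward minus backward neighbor);
    # opposite axes are negations, so only 4 are computed
    diffs = np.zeros((8, h, w))
    for k in range(4):
        dr, dc = _AXIS_OFFSETS[k]
        d = np.zeros((h, w))
        d[1:-1, 1:-1] = (
            g[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
            - g[1 - dr : h - 1 - dr, 1 - dc : w - 1 - dc]
        )
        diffs[k] = d
        diffs[k + 4] = -d

    rows = np.arange(h)[:, None] - cr
    cols = np.arange(w)[None, :] - cc
    theta = np.arctan2(rows, cols)  # [-pi, pi], top-down row axis
    sector = np.floor(theta / (math.pi / 4.0)).astype(int)
    t = theta / (math.pi / 4.0) - sector
    k0 = np.mod(sector, 8)
    k1 = np.mod(sector + 1, 8)

    flat0 = diffs.reshape(8, -1)[k0.ravel(), np.arange(h * w)].reshape(h, w)
    flat1 = diffs.reshape(8, -1)[k1.ravel(), np.arange(h * w)].reshape(h, w)
    values = (1.0 - t) * flat0 + t * flat1

    values[0, :] = values[-1, :] = 0.0
    values[:, 0] = values[:, -1] = 0.0
    values[cr, cc] = 0.0

    peak = np.max(np.abs(values))
    if peak > 0:
        values = values / peak
    return EdgeMap(values=values, center=(cr, cc))


def binarize_negative_edges(edge: EdgeMap) -> BinaryEdge:
    """Keep only strong bright-to-dark edges.

    Positive gradients are zeroed, Otsu's threshold is computed on the
    remaining raster, and pixels *below* the threshold form the mask.  With
    no negative values anywhere the mask is empty (with a warning).
    """
    v = np.minimum(edge.values, 0.0)
    if not np.any(v < 0):
        warnings.warn("edge map has no negative values; binary edge mask is empty")
        return BinaryEdge(mask=np.zeros_like(v, dtype=bool), threshold=None)
    threshold = otsu_threshold(v)
    return BinaryEdge(mask=v < threshold, threshold=threshold)
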