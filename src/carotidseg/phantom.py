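"""Synthetic neck-slice phantoms with known lumen geometry.

A phantom emulates the intensity layout the segmentation pipeline relies on
in a transverse neck slice: a dark background, a bright tissue disc, per side
one near-circular bright artery lumen wrapped in a dark wall ring, a larger
bright elliptical jugular vein directly adjacent to it, and dark air chambers.
Frame-to-frame the artery radius is modulated sinusoidally to emulate the
systolic/diastolic lumen change over one RR-cycle.

The module also implements the two degradation protocols used for the
reliability study: integer contrast scaling and additive white noise injected
at a controlled SNR.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomSpecError",
    "generate_phantom",
    "lumen_mask",
    "degrade_contrast",
    "compute_snr_db",
    "add_noise_at_snr",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of a synthetic neck slice.

    Intensities are on the scale ``[0, gray_max]`` and must satisfy
    ``background_level < wall_level < tissue_level < lumen_level <= gray_max``:
    the lumen is the brightest structure and the vessel wall the darkest ring,
    which is the ordering the detection algorithm exploits.

    Centers and radii are in pixels; fractional values are allowed (real
    vessels are never lattice-aligned) and the defaults are deliberately
    off-lattice.  ``texture_sd`` controls multiplicative texture noise: each
    pixel is scaled by ``1 + N(0, texture_sd / gray_max)``, i.e. the standard
    deviation equals ``texture_sd`` intensity units at full scale.
    """

    image_height: int = 320
    image_width: int = 320
    pixel_size_mm: float = 0.53125
    gray_max: int = 255
    background_level: float = 8.0
    wall_level: float = 40.0
    tissue_level: float = 100.0
    lumen_level: float = 220.0
    vein_level: float = 200.0
    artery_center: tuple[float, float] = (160.3, 100.6)  # (row, col)
    artery_radius: float = 9.0
    radius_amplitude_px: float | None = None  # default: 10% of artery_radius
    wall_thickness_px: float = 2.0
    vein_center: tuple[float, float] = (160.3, 72.0)
    vein_semi_axes: tuple[float, float] = (16.0, 11.0)  # (a, b), a >= b; a along columns
    air_chamber_centers_radii: tuple[tuple[tuple[float, float], float], ...] = (
        ((160.0, 160.0), 12.0),
    )
    tissue_center: tuple[float, float] = (160.0, 160.0)
    tissue_semi_axes: tuple[float, float] = (150.0, 130.0)  # (rows, cols)
    texture_sd: float = 0.0
    n_frames: int = 1
    rng_seed: int = 0
    mirror: bool = True

    def validate(self) -> None:
        lv = (self.background_level, self.wall_level, self.tissue_level, self.lumen_level)
        if not (lv[0] < lv[1] < lv[2] < lv[3] <= self.gray_max):
            raise PhantomSpecError(
                "intensity ordering must be background < wall < tissue < lumen <= gray_max"
            )
        a, b = self.vein_semi_axes
        if a < b:
            raise PhantomSpecError("vein_semi_axes must satisfy a >= b")
        if math.pi * a * b <= math.pi * self.artery_radius**2:
            raise PhantomSpecError("vein area must exceed artery area")
        if self.artery_radius <= 0 or self.wall_thickness_px < 1:
            raise PhantomSpecError("artery radius must be > 0 and wall thickness >= 1 px")
        if self.n_frames < 1:
            raise PhantomSpecError("n_frames must be >= 1")
        # artery (including its wall ring, at maximal radius) and vein must be disjoint
        r_out = self.radius_at(_argmax_radius_frame(self)) + self.wall_thickness_px
        if _disc_ellipse_overlap(
            self.artery_center, r_out, self.vein_center, self.vein_semi_axes
        ):
            raise PhantomSpecError("artery (wall included) and vein shapes overlap")

    @property
    def _radius_amplitude(self) -> float:
        if self.radius_amplitude_px is None:
            return 0.1 * self.artery_radius
        return float(self.radius_amplitude_px)

    def radius_at(self, frame: int) -> float:
        """Artery lumen radius of a given frame (sinusoidal heart-cycle model)."""
        return self.artery_radius + self._radius_amplitude * math.sin(
            2.0 * math.pi * frame / self.n_frames
        )


@dataclasses.dataclass(frozen=True)
class PhantomGroundTruth:
    """Known lumen geometry of a generated phantom sequence.

    ``area_px2`` is the exact pixel count of the rasterized lumen mask, the
    same quantity a manual tracer of the discrete image would report.
    """

    centers: np.ndarray  # (n_frames, 2) (row, col)
    radii: np.ndarray  # (n_frames,)
    area_px2: np.ndarray  # (n_frames,)
    area_mm2: np.ndarray  # (n_frames,)


def _argmax_radius_frame(spec: PhantomSpec) -> int:
    radii = [spec.radius_at(i) for i in range(spec.n_frames)]
    return int(np.argmax(radii))


def _disc_ellipse_overlap(c_disc, r_disc, c_ell, semi_axes) -> bool:
    # conservative raster check on a local grid
    a, b = semi_axes
    pad = int(math.ceil(r_disc + a + 4))
    r0 = int(min(c_disc[0], c_ell[0])) - pad
    r1 = int(max(c_disc[0], c_ell[0])) + pad
    c0 = int(min(c_disc[1], c_ell[1])) - pad
    c1 = int(max(c_disc[1], c_ell[1])) + pad
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    disc = (rr - c_disc[0]) ** 2 + (cc - c_disc[1]) ** 2 <= r_disc**2
    ell = ((cc - c_ell[1]) / a) ** 2 + ((rr - c_ell[0]) / b) ** 2 <= 1.0
    return bool(np.any(disc & ell))


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    a, b = semi_axes  # a along columns, b along rows
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((cc - center[1]) / a) ** 2 + ((rr - center[0]) / b) ** 2 <= 1.0


def _mirror_col(col: float, width: int) -> float:
    return (width - 1) - col


def lumen_mask(spec: PhantomSpec, frame: int = 0) -> np.ndarray:
    """Boolean mask of the primary-side artery lumen in a given frame."""
    shape = (spec.image_height, spec.image_width)
    return _disc_mask(shape, spec.artery_center, spec.radius_at(frame))


def _paint_frame(spec: PhantomSpec, frame: int) -> np.ndarray:
    shape = (spec.image_height, spec.image_width)
    img = np.full(shape, spec.background_level, dtype=np.float64)
    img[_ellipse_mask(shape, spec.tissue_center, spec.tissue_semi_axes)] = spec.tissue_level
    for center, radius in spec.air_chamber_centers_radii:
        img[_disc_mask(shape, center, radius)] = spec.background_level

    r = spec.radius_at(frame)
    sides = [(spec.artery_center, spec.vein_center)]
    if spec.mirror:
        sides.append(
            (
                (spec.artery_center[0], _mirror_col(spec.artery_center[1], shape[1])),
                (spec.vein_center[0], _mirror_col(spec.vein_center[1], shape[1])),
            )
        )
    for artery_c, vein_c in sides:
        # vein: bright ellipse directly on tissue (no wall ring; jugular walls are thin)
        img[_ellipse_mask(shape, vein_c, spec.vein_semi_axes)] = spec.vein_level
        # artery: dark wall ring then bright lumen disc
        img[_disc_mask(shape, artery_c, r + spec.wall_thickness_px)] = spec.wall_level
        img[_disc_mask(shape, artery_c, r)] = spec.lumen_level
    return img


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Generate a phantom sequence and its ground truth.

    Returns ``(frames, truth)`` where ``frames`` has shape
    ``(n_frames, H, W)`` (float64, clamped to ``[0, gray_max]``).  Generation
    is deterministic for a fixed ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = (spec.image_height, spec.image_width)
    frames = np.empty((spec.n_frames,) + shape, dtype=np.float64)
    radii = np.empty(spec.n_frames)
    areas = np.empty(spec.n_frames)
    for i in range(spec.n_frames):
        img = _paint_frame(spec, i)
        if spec.texture_sd > 0:
            factor = 1.0 + (spec.texture_sd / spec.gray_max) * rng.standard_normal(shape)
            img = img * factor
        np.clip(img, 0.0, spec.gray_max, out=img)
        frames[i] = img
        radii[i] = spec.radius_at(i)
        areas[i] = int(np.count_nonzero(lumen_mask(spec, i)))
    centers = np.tile(np.asarray(spec.artery_center, dtype=float), (spec.n_frames, 1))
    truth = PhantomGroundTruth(
        centers=centers,
        radii=radii,
        area_px2=areas,
        area_mm2=areas * spec.pixel_size_mm**2,
    )
    return frames, truth


def degrade_contrast(image: np.ndarray, ratio: float) -> np.ndarray:
    """Scale the contrast resolution of an image by ``ratio``.

    Each pixel is mapped to the nearest integer of ``ratio * g`` (ties round
    half to even), so the output range of an image on ``[0, g_max]`` becomes
    ``[0, int(ratio * g_max)]``.  ``ratio == 1`` is the identity.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"contrast ratio must be in (0, 1], got {ratio}")
    image = np.asarray(image, dtype=np.float64)
    if ratio == 1.0:
        return image.copy()
    return np.rint(ratio * image)


def compute_snr_db(
    signal: np.ndarray, noise: np.ndarray, on_zero_noise: str = "inf"
) -> float:
    """Signal-to-noise ratio in decibels, ``10*log10(sum g^2 / sum n^2)``.

    Pixels where either the signal or the noise is exactly zero are excluded
    from both sums.  Under this definition 20 dB corresponds to a noise
    amplitude one tenth of the signal amplitude.

    Parameters
    ----------
    on_zero_noise : {"inf", "raise"}
        Behaviour when the noise power over the valid support is zero.
    """
    signal = np.asarray(signal, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if signal.shape != noise.shape:
        raise ValueError("signal and noise must have the same shape")
    if np.any(signal < 0):
        raise ValueError("signal intensities must be nonnegative")
    if not np.any(noise):
        if on_zero_noise == "raise":
            raise ValueError("noise is identically zero")
        return math.inf
    valid = (signal != 0) & (noise != 0)
    if not np.any(valid):
        raise ValueError("no pixels with both signal and noise nonzero")
    p_signal = float(np.sum(signal[valid] ** 2))
    p_noise = float(np.sum(noise[valid] ** 2))
    return 10.0 * math.log10(p_signal / p_noise)


def add_noise_at_snr(
    image: np.ndarray,
    target_snr_db: float,
    rng_seed: int,
    gray_max: float = 255.0,
    return_noise: bool = False,
):
    """Add zero-mean Gaussian white noise scaled to a target SNR.

    The noise raster is rescaled so that ``compute_snr_db(image, noise)``
    equals ``target_snr_db`` (to well within 0.01 dB) *before* the sum is
    clamped to ``[0, gray_max]``.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.any(image != 0):
        raise ValueError("cannot attain a target SNR on an all-zero image")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(image.shape)
    valid = (image != 0) & (noise != 0)
    p_signal = float(np.sum(image[valid] ** 2))
    p_noise = float(np.sum(noise[valid] ** 2))
    scale = math.sqrt(p_signal / (p_noise * 10.0 ** (target_snr_db / 10.0)))
    noise *= scale
    achieved = compute_snr_db(image, noise)
    if abs(achieved - target_snr_db) > 0.01:  # pragma: no cover - analytic guarantee
        warnings.warn(
            f"achieved SNR {achieved:.4f} dB deviates from target {target_snr_db} dB"
        )
    degraded = np.clip(image + noise, 0.0, gray_max)
    if return_noise:
        return degraded, noise
    return degraded
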