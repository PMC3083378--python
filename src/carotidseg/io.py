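"""Reading image sequences and writing result files.

Sequences may be a directory of numbered PNG/TIFF files, a single
multi-page TIFF, or a DICOM series; results are written as plain CSV
(areas, contours), a JSON config snapshot, and a run log.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import PhantomGroundTruth
from .pipeline import PipelineConfig, SequenceResult

__all__ = [
    "read_sequence",
    "write_results",
    "write_phantom_sequence",
    "write_ground_truth",
    "read_areas_csv",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _numeric_key(path: Path):
    numbers = re.findall(r"\d+", path.stem)
    return (int(numbers[-1]) if numbers else 0, path.name)


def read_sequence(
    path: str | Path, pixel_size_mm: float | None = None
) -> tuple[np.ndarray, float]:
    """Load an ordered grayscale sequence and its pixel size in mm.

    Accepts a directory of numbered PNG/TIFF frames, a directory of DICOM
    files (ordered by instance number, pixel spacing read from the header
    when present), or a single multi-page TIFF.  A DICOM pixel spacing
    overrides ``pixel_size_mm``; otherwise the argument (default 0.53125 mm)
    is used.
    """
    path = Path(path)
    default_px = 0.53125 if pixel_size_mm is None else pixel_size_mm
    if path.is_dir():
        images = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
            key=_numeric_key,
        )
        dicoms = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"}
        )
        if images:
            frames = [np.asarray(iio.imread(p), dtype=np.float64) for p in images]
        elif dicoms:
            return _read_dicom_series(dicoms, default_px)
        else:
            raise FileNotFoundError(f"no readable image files in {path}")
    elif path.suffix.lower() in {".tif", ".tiff"}:
        stack = np.asarray(iio.imread(path), dtype=np.float64)
        frames = list(stack) if stack.ndim == 3 else [stack]
    else:
        raise ValueError(f"unsupported input {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
    return np.stack(frames), default_px


def _read_dicom_series(paths, default_px: float) -> tuple[np.ndarray, float]:
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = [np.asarray(d.pixel_array, dtype=np.float64) for d in datasets]
    px = default_px
    spacing = getattr(datasets[0], "PixelSpacing", None)
    if spacing is not None:
        px = float(spacing[0])
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
    return np.stack(frames), px


def write_phantom_sequence(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Write frames as numbered 16-bit PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames)):
        p = out_dir / f"frame_{i:03d}.png"
        iio.imwrite(p, np.rint(frame).astype(np.uint16))
        paths.append(p)
    return paths


def write_ground_truth(truth: PhantomGroundTruth, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(truth.radii)),
            "center_row": truth.centers[:, 0],
            "center_col": truth.centers[:, 1],
            "radius_px": truth.radii,
            "area_px2": truth.area_px2,
            "area_mm2": truth.area_mm2,
        }
    )
    df.to_csv(out_path, index=False)
    return out_path


def areas_frame(result: SequenceResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        rows.append(
            {
                "frame": r.frame,
                "status": r.status,
                "center_row": r.center[0] if r.center else np.nan,
                "center_col": r.center[1] if r.center else np.nan,
                "radius_px": r.radius_px if r.radius_px is not None else np.nan,
                "area_px2": r.area_px2 if r.area_px2 is not None else np.nan,
                "area_mm2": r.area_mm2 if r.area_mm2 is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def contours_frame(result: SequenceResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        if r.contour is None:
            continue
        n = r.contour.shape[0]
        angles = np.arange(n) * (360.0 / n)
        radii = np.hypot(r.contour[:, 0] - r.center[0], r.contour[:, 1] - r.center[1])
        for angle, radius, (row, col) in zip(angles, radii, r.contour):
            rows.append(
                {
                    "frame": r.frame,
                    "angle_deg": angle,
                    "radius_px": radius,
                    "row": row,
                    "col": col,
                }
            )
    return pd.DataFrame(rows)


def write_results(
    result: SequenceResult,
    out_dir: str | Path,
    overlays: bool = False,
    frames: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write areas/contours CSVs, a config snapshot, and a run log.

    With ``overlays=True`` (and the source frames supplied) one PNG per
    frame is written with the detected contour drawn on top.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["areas"] = out_dir / "areas.csv"
    areas_frame(result).to_csv(paths["areas"], index=False)
    paths["contours"] = out_dir / "contours.csv"
    contours_frame(result).to_csv(paths["contours"], index=False)
    paths["config"] = out_dir / "config.json"
    paths["config"].write_text(result.config.to_json() + "\n")
    paths["log"] = out_dir / "run.log"
    n_ok = sum(1 for r in result.records if r.status == "ok")
    lines = [
        f"carotidseg {result.version}",
        f"frames processed: {len(result.records)} ({n_ok} ok)",
        f"wall time: {result.finished - result.started:.2f} s",
    ]
    for r in result.records:
        if r.status != "ok":
            lines.append(f"frame {r.frame}: FAILED ({r.message})")
        elif r.used_full_localization and r.frame > 0:
            lines.append(f"frame {r.frame}: fell back to full localization")
    paths["log"].write_text("\n".join(lines) + "\n")
    if overlays and frames is not None:
        paths["overlays"] = _write_overlays(result, frames, out_dir / "overlays")
    return paths


def _write_overlays(result: SequenceResult, frames: np.ndarray, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in result.records:
        frame = np.asarray(frames[r.frame], dtype=np.float64)
        peak = frame.max() if frame.max() > 0 else 1.0
        rgb = np.stack([frame / peak * 255] * 3, axis=-1).astype(np.uint8)
        if r.contour is not None:
            rows = np.clip(np.rint(r.contour[:, 0]).astype(int), 0, frame.shape[0] - 1)
            cols = np.clip(np.rint(r.contour[:, 1]).astype(int), 0, frame.shape[1] - 1)
            rgb[rows, cols] = (255, 32, 32)
        iio.imwrite(out_dir / f"overlay_{r.frame:03d}.png", rgb)
    return out_dir


def read_areas_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_json(Path(path).read_text())
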