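"""Accuracy and reliability metrics for lumen area measurements.

The per-frame agreement between an automated area and a reference area is
the relative signed error

    eps_i = 100 * (A_ref(i) - A_auto(i)) / A_ref(i)   [%]

so that an automated measurement *larger* than the reference yields a
*negative* error.  Summaries report the mean and sample standard deviation
(n-1 denominator) of the signed errors and of their absolute values, and
Bland-Altman agreement uses the per-frame mean as abscissa, the per-frame
difference as ordinate, and limits of agreement at mean +/- 2 SD of the
differences.

``run_reliability_study`` drives the robustness experiment: the full
pipeline is re-run on contrast-scaled and SNR-controlled noise-degraded
copies of a sequence and each condition is summarized against the reference
areas.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .phantom import add_noise_at_snr, degrade_contrast

__all__ = [
    "ErrorSummary",
    "BlandAltman",
    "relative_signed_error",
    "error_summary",
    "bland_altman",
    "run_reliability_study",
]


@dataclasses.dataclass(frozen=True)
class ErrorSummary:
    signed_mean: float
    signed_sd: float
    unsigned_mean: float
    unsigned_sd: float
    n_frames: int


@dataclasses.dataclass(frozen=True)
class BlandAltman:
    means: np.ndarray
    diffs: np.ndarray
    mean_diff: float
    lower_limit: float
    upper_limit: float


def relative_signed_error(auto: float, ref: float) -> float:
    """Relative signed error in percent; auto > ref gives a negative value."""
    if ref <= 0:
        raise ValueError(f"reference area must be positive, got {ref}")
    return 100.0 * (ref - auto) / ref


def _sample_sd(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1))


def error_summary(errors: Sequence[float]) -> ErrorSummary:
    """Mean/SD of signed errors and of their absolute values."""
    e = np.asarray(list(errors), dtype=np.float64)
    if e.size == 0:
        raise ValueError("cannot summarize an empty error list")
    return ErrorSummary(
        signed_mean=float(e.mean()),
        signed_sd=_sample_sd(e),
        unsigned_mean=float(np.abs(e).mean()),
        unsigned_sd=_sample_sd(np.abs(e)),
        n_frames=int(e.size),
    )


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltman:
    """Agreement between two area series, limits at mean +/- 2 sample SD."""
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    means = (a + b) / 2.0
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd = _sample_sd(diffs)
    return BlandAltman(
        means=means,
        diffs=diffs,
        mean_diff=mean_diff,
        lower_limit=mean_diff - 2.0 * sd,
        upper_limit=mean_diff + 2.0 * sd,
    )


def bland_altman_plot(ba: BlandAltman, ax=None):
    """Scatter of differences vs means with the mean and +/- 2 SD lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=12)
    for y, style in ((ba.mean_diff, "-"), (ba.lower_limit, "--"), (ba.upper_limit, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of measurements (mm$^2$)")
    ax.set_ylabel("difference (mm$^2$)")
    return ax


def _condition_summary(frames, ref_areas, config) -> tuple[ErrorSummary | None, int]:
    from .pipeline import process_sequence

    result = process_sequence(frames, config)
    errors = []
    n_failed = 0
    for record, ref in zip(result.records, ref_areas):
        if record.status != "ok":
            n_failed += 1
            continue
        errors.append(relative_signed_error(record.area_mm2, ref))
    if not errors:
        return None, n_failed
    return error_summary(errors), n_failed


def run_reliability_study(
    frames: np.ndarray,
    reference_areas_mm2: Sequence[float],
    contrasts: Sequence[float],
    snrs_db: Sequence[float],
    seed: int,
    config=None,
    gray_max: float = 255.0,
) -> pd.DataFrame:
    """Robustness of the pipeline to contrast scaling and additive noise.

    For every contrast ratio and every target SNR the entire sequence is
    degraded, the full two-phase pipeline re-run, and the per-frame areas
    compared against ``reference_areas_mm2``.  Returns one row per condition
    (plus the undegraded baseline) with signed/unsigned error statistics and
    the number of failed frames.
    """
    from .pipeline import PipelineConfig

    if config is None:
        config = PipelineConfig()
    frames = np.asarray(frames, dtype=np.float64)
    ref = np.asarray(list(reference_areas_mm2), dtype=np.float64)
    if frames.shape[0] != ref.size:
        raise ValueError("one reference area per frame is required")

    rows = []

    def add_row(kind, level, summary, n_failed):
        rows.append(
            {
                "condition": kind,
                "level": level,
                "signed_mean_pct": summary.signed_mean if summary else np.nan,
                "signed_sd_pct": summary.signed_sd if summary else np.nan,
                "unsigned_mean_pct": summary.unsigned_mean if summary else np.nan,
                "unsigned_sd_pct": summary.unsigned_sd if summary else np.nan,
                "n_frames": summary.n_frames if summary else 0,
                "n_failed": n_failed,
            }
        )

    summary, n_failed = _condition_summary(frames, ref, config)
    add_row("raw", np.nan, summary, n_failed)

    for ratio in contrasts:
        degraded = np.stack([degrade_contrast(f, ratio) for f in frames])
        summary, n_failed = _condition_summary(degraded, ref, config)
        add_row("contrast", float(ratio), summary, n_failed)

    for i, snr in enumerate(snrs_db):
        noisy = np.stack(
            [
                add_noise_at_snr(
                    f,
                    snr,
                    rng_seed=int(
                        np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % 2**31
                    ),
                    gray_max=gray_max,
                )
                for j, f in enumerate(frames)
            ]
        )
        summary, n_failed = _condition_summary(noisy, ref, config)
        add_row("snr", float(snr), summary, n_failed)

    return pd.DataFrame(rows)
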