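# carotidseg

Fully automatic detection of the common carotid artery (CCA) lumen boundary
in cross-sectional MR image sequences, for vascular studies that need the
lumen area over a complete heart cycle (e.g. local compliance from the
systolic/diastolic diameter change) without hand tracing hundreds of frames.

In cine FLASH neck slices the flowing blood makes the lumen bright and the
vessel wall dark; the internal jugular vein — larger, less round, and
directly adjacent — is the main distractor. The pipeline has two phases:

1. **Localization** — two-stage Otsu thresholding (foreground vs background,
   then bright lumens vs tissue, with background marked −1 and ignored),
   a binary opening with the 5-pixel diamond element, and selection of the
   roundest of the two largest components per image side (PCA axis ratio of
   the boundary points).
2. **Boundary extraction** — the signed *radial directional gradient* about
   the artery center keeps only bright→dark (lumen→wall) transitions, Otsu
   binarization and a circle Hough transform give a circle prior
   (center, radius r), and a circle-model-guided dynamic program on the
   polar-resampled edge map extracts the closed boundary:

   C(x, y) = w(y)·R_p(x, y) + min over |j| ≤ d_r of [C(x−1, y+j) + α·|j|],
   with w(y) = exp(−(y − r)²/(2σ²)) and C(1, y) = R_p(1, y).

   A circular 5-point moving average makes the integer path sub-pixel; the
   contour's shoelace area is reported in px² and mm². Defaults: α = 0.3,
   σ = 2, d_r = 1; each detected frame seeds the next frame's ROI
   (half-width 1.5× the detected radius).

A synthetic neck-phantom generator with exact ground truth, controlled
contrast scaling, and SNR-targeted white-noise injection supports the
reliability study end to end with no external data.

## Worked example

```python
import numpy as np
from carotidseg import PhantomSpec, PipelineConfig, generate_phantom, process_sequence
from carotidseg.evaluation import error_summary, relative_signed_error

spec = PhantomSpec(n_frames=10, radius_amplitude_px=1.0, texture_sd=8.0, rng_seed=0)
frames, truth = generate_phantom(spec)          # 10 frames, radius 8-10 px
result = process_sequence(frames, PipelineConfig(side="left"))
for rec, ref in list(zip(result.records, truth.area_mm2))[:3]:
    print(f"frame {rec.frame}: center=({rec.center[0]:.0f}, {rec.center[1]:.0f}) "
          f"radius={rec.radius_px:.2f} px  area={rec.area_mm2:.2f} mm^2  (truth {ref:.2f})")
errors = [relative_signed_error(r.area_mm2, ref)
          for r, ref in zip(result.records, truth.area_mm2)]
s = error_summary(errors)
print(f"unsigned error over {s.n_frames} frames: {s.unsigned_mean:.2f}% +/- {s.unsigned_sd:.2f}%")
```

```
frame 0: center=(160, 100) radius=8.81 px  area=68.96 mm^2  (truth 71.97)
frame 1: center=(160, 101) radius=9.22 px  area=75.50 mm^2  (truth 81.00)
frame 2: center=(160, 101) radius=9.97 px  area=88.14 mm^2  (truth 88.05)
unsigned error over 10 frames: 2.64% +/- 1.99%
```

Each line is one cine frame: the detected lumen center (pixels), the mean
sub-pixel contour radius, and the enclosed area (0.53125 mm pixels, so one
pixel is ≈0.28 mm²) against the phantom's exact pixel-count ground truth;
the summary is the mean ± SD of the per-frame unsigned relative area error.

The same operations are available from the shell:

```sh
carotidseg phantom out/phantom --frames 50 --seed 0      # frames + ground_truth.csv
carotidseg segment out/phantom out/run --side left       # areas.csv, contours.csv, config.json
carotidseg evaluate out/run/areas.csv out/phantom/ground_truth.csv out/eval.csv
carotidseg reliability out/reliability.csv --seed 0      # contrast/SNR robustness table
```

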