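# Methods

## Problem and approach

`carotidseg` measures the cross-sectional lumen area of the common carotid
artery (CCA) in cine MR sequences (one RR-cycle, typically 50 frames of a
320×320 slice with 0.53125 mm pixels). In such T2*-weighted FLASH images
flowing blood renders the lumen bright, the vessel wall dark, and the
adjacent internal jugular vein — larger, less round, and very close to the
artery — is the main distractor. Detection runs in two phases.

**Phase 1 — localization.** Otsu's threshold is applied twice: first to
separate the subject from the dark background and air chambers (background
pixels are marked with the sentinel −1 and excluded thereafter), then to
separate the bright vessel lumens from the remaining tissue. A binary
opening with the 5-pixel diamond element (center + 4-neighborhood) removes
speckle and cuts thin bridges between vein and artery. Per image side (split
at the vertical midline), the two largest 8-connected components are taken
as vein and artery candidates; the boundary points of each (Sobel response
on the component mask) are analyzed by PCA, and the candidate whose
major/minor axis ratio is closest to 1 — the roundest — is the artery. Ties
within 0.01 go to the smaller candidate. A square ROI (default half-width
⌈7.5 mm / pixel size⌉, comfortably above a normal CCA radius) is extracted
around the centroid.

**Phase 2 — boundary extraction.** The radial *directional gradient* of the
ROI is taken with respect to the artery center: for each pixel the intensity
derivative along the ray from the center, resolved at 45° and linearly
blended between the two bracketing 8-neighbor central differences with
weight t = 4θ/π inside each sector. Walking outward, the lumen→wall
transition is negative while the tissue→vein transition on the vein's facing
side is positive; keeping only negative values makes the search immune to
the vein. The map is normalized to [−1, 1], positives are zeroed, Otsu's
threshold on the remainder yields a binary edge mask, and a circle Hough
transform over an anatomy-derived radius range (default 1.5–6 mm) gives the
rough circle (center, radius r). The edge map is resampled on a polar grid
about that center (rows = radii 1..M px, 360 columns, first column
duplicated at 2π to enforce closure) and dynamic programming finds the
minimum-cost left-to-right path with

    C(x, y) = w(y)·R_p(x, y) + min_{|j|≤d_r} [ C(x−1, y+j) + α·|j| ],
    C(1, y) = R_p(1, y),     w(y) = exp(−(y − r)² / (2σ²)).

The multiplicative Gaussian weight suppresses off-circle edge evidence; as
σ→∞ it reduces exactly to prior-free DP, while σ≤0.5 forces a nearly round
result. The integer path is smoothed with a circular 5-point moving average
(the sub-pixel step), converted to a Cartesian polygon, and its shoelace
area reported in px² and mm² (mm² = px² · pixel_size²; 0.53125² ≈ 0.28).

Frame-to-frame, the detected center seeds the next frame's ROI with
half-width ⌈1.5 × previous mean radius⌉; a frame whose propagated ROI fails
falls back to full localization and is flagged, never dropped.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| α | 0.3 | radial-jump penalty, (0, 1]; near 1 → smoother contour |
| σ | 2 px | circle-prior width; suggested working range 0.4–4 |
| d_r | 1 px | max radial jump per 1° step; bounds each node at 2·d_r+1 predecessors |
| n_angles | 360 | polar angular resolution |
| pixel size | 0.53125 mm | from the acquisition protocol; DICOM header overrides |
| ROI half-width | ⌈7.5 mm/px⌉ first frame, ⌈1.5·r⌉ after | anatomy + tracking rule |
| Hough radius range | ⌈1.5 mm/px⌉–⌊6 mm/px⌋ | CCA anatomy, clamped to the ROI |

Reconstruction notes: the sector layout of the directional gradient is one
consistent rotation of the 8-neighborhood (any consistent rotation yields
the same operator; a 90°-rotation equivariance test pins consistency); the
circle prior enters multiplicatively (an additive penalty would not reduce
to plain DP as σ→∞ while also reproducing near-round output at small σ).

## Numerical choices

* Otsu maximizes the between-class variance over native integer gray levels
  (matching degraded integer contrast ranges); continuous inputs such as
  normalized edge maps use 256 uniform bins. The returned threshold is the
  midpoint between the optimal split level and the next occupied level. The
  implementation is exactly equivalent to exhaustive search (oracle-tested).
* DP tie-breaks are fully deterministic: smallest |j| first, negative before
  positive; endpoint ties resolve toward the prior radius, then the smaller
  row. Out-of-range predecessors are forbidden (infinite cost), not clamped.
  Closure is enforced only through the duplicated wrap column; a path whose
  ends differ by more than d_r triggers a warning.
* Hough votes are unit-weight per distinct perimeter cell (duplicate
  rasterization cells are collapsed); ties resolve to the smallest radius,
  then the lexicographically first center.
* Contrast degradation rounds ratio·g half-to-even, so the output range of
  an 8-bit image at ratio ρ is [0, int(ρ·255)]; ratio 1 is the identity.
* Noise injection rescales a zero-mean Gaussian field so the SNR definition
  10·log10(Σg²/Σn²) (pixels with g=0 or n=0 excluded from both sums) meets
  the target analytically, before clamping to [0, g_max].

## The phantom generator

The phantom emulates exactly the features the algorithm relies on: a dark
background (level 8), a bright tissue ellipse (100), per side a bright
artery lumen disc (220) inside a dark 2 px wall ring (40 — about one
intima–media thickness at this pixel size), a larger bright jugular-vein
ellipse (200, 16×11 px semi-axes) a few pixels away with no wall ring (so
its facing edge is a pure dark→bright transition, as in the images), and a
dark air chamber. Vessel centers are deliberately off-lattice. The artery
radius follows a sinusoid over the sequence (default amplitude 10% of the
radius; the study sequence uses 9±1 px ≈ systole/diastole change).
Multiplicative texture noise scales each pixel by 1 + N(0, s/g_max) with
s = 8 intensity units at full scale for the "moderate" setting. Ground-truth
area is the exact pixel count of the rasterized lumen mask — the discrete
analogue of a manual tracing.

What the phantom does **not** emulate: flow and motion artifacts, coil
sensitivity profiles, partial-volume plaque, phase-shift effects, or
anatomical variability. Passing tests therefore demonstrate the geometric
and numerical correctness of the pipeline and its degradation robustness,
not clinical performance.

## Study sizes and observed behaviour

The reliability study processes a 50-frame 320×320 sequence under 12
conditions (raw, contrast ratios 1.0–0.5, SNR 20–16 dB) — 600 full frame
segmentations, about 15 s on one CPU. On the moderate-texture phantom the
mean unsigned area error is ≈1.8% (signed ≈ +1%), the spread across contrast
ratios is ≈0.1 pp, and worsening SNR raises the error by a few tenths of a
percentage point — the same flat-contrast / mild-noise pattern the method is
designed for. Oracle suites (DP path enumeration, exhaustive Otsu) agree
exactly; Hough recovery over radii 5–25 px (clean and 10% salt) is within
1 px radius and 2 px center.

## Known limitations

* **Small-radius inward bias.** The positive wall→tissue edge sits only one
  wall-thickness outside the lumen edge; it weakens the outer flank of the
  negative gradient valley, and under the multiplicative circle prior the
  integer DP then dips inward slightly more often than outward. Net effect
  ≈0.1–0.2 px of radius, i.e. up to ≈5% area at r = 6 px in the worst
  off-lattice case and ≲2% for r ≥ 12 px; with σ=∞ the bias vanishes. The
  sub-pixel recovery test asserts the attained ≤5% per-radius bound.
* The localization assumes the lateral symmetry split at the image midline
  and a plaque-free, near-round lumen; the DP assumes a star-shaped contour
  about a known rough center.
* The Hough center is integer; its sub-pixel offset (≤0.7 px) is absorbed,
  not corrected, by the DP stage.
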