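# Methods

`pteryquant` quantifies corneal healing in the murine pterygium model from
colour micrographs of fluorescein-stained eyes. This note records the models
and procedures the package implements, the parameters that matter, what the
synthetic scenes do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Imaging model and calibration

Input images are 8-bit RGB micrographs of a single eye under black light.
The fluorescein-stained lesion fluoresces green; the healthy eyeball is a
dark saturated red whose red-channel luminosity tracks corneal crystallinity
(high luminosity = healthy, drift toward pink = opaque). Physical
calibration is a single scalar, `mm_per_px` (default 2.61 × 10⁻³ mm/px, the
calibration of the original acquisition setup); all areas scale with its
square, lengths linearly, and the dimensionless descriptors not at all.

## Lesion segmentation (HSB colour threshold)

Segmentation runs in HSB space with all channels rescaled to 0–255 (pure
green → H = 85). A pixel belongs to the lesion iff

- hue lies in the fluorescein-green band, default H ∈ [55, 110] (≈78°–155°);
- saturation lies in its window, default S ∈ [0, 255];
- brightness passes the cut, and the pixel is inside the eye ROI.

The brightness cut (`brightness_method="otsu_within_gate"`, the default) is
Otsu's threshold computed on the brightness histogram of the
hue/saturation-gated pixels inside the eye ROI, floored at `b_min` (default
48). The floor keeps dim green texture (iris speckle, reflections) out of
the mask even when the gated histogram is unimodal; a `fixed` mode using the
window bounds directly is also available. All connected components passing
the gates are kept — fluorescein staining can fragment a lesion and the
union is the lesion.

The eye ROI is the largest 8-connected component above Otsu's threshold on
overall brightness, holes filled. It is the denominator of the percent
damaged area and the photometry region.

Vessels are segmented on the green channel inside the eye ROI: linear
contrast stretch saturating 0.35% of ROI pixels per tail, rolling-ball
background subtraction (default radius 50 px; for large radii the ball is
rolled on a downscaled copy, the standard speed-up), then Otsu binarization
of the positive residual. The Otsu threshold is floored at mean + 3 sd of
the lower 90% of residuals: the trimmed floor makes a vessel-free eye
produce an (almost) empty mask instead of thresholded noise, without letting
a dense vessel bed inflate its own threshold. Lesion pixels, also
green-bright, are excluded from both the statistics and the mask.

## Morphometry

Per-image descriptors of the lesion mask:

- **area** — foreground count × (mm/px)²;
- **perimeter** — total marching-squares (0.5-level) contour length over all
  components, with a light 3-point circular moving average of the contour
  vertices before measuring. The raw staircase polygon overestimates the
  length of smooth boundaries by ≈5% (a rasterized disk would cap
  circularity near 0.90); the smoothing brings the disk to within 1% of 2πr
  while rounding true right-angle corners by only a few percent. The raw
  length is available with `smoothing=1`.
- **Feret diameter** — maximum caliper distance, computed as the maximum
  pairwise distance between convex-hull vertices of the foreground pixel
  *corners* (each pixel a unit square). Corner points match the
  boundary-polygon convention: for a 100 × 2 px bar the result is
  √(100² + 2²) exactly, where pixel centers would be short by 1 px.
- **circularity** — 4π·area/perimeter², clamped at 1; **solidity** — area
  over the pixelated convex-hull area (`convex_hull_image`), so it cannot
  exceed 1.
- **percent damaged area** — 100 × lesion area / eye-ROI area of the same
  image.

An empty mask is a valid healed-eye observation: an all-zero record flagged
`empty`, not an error. Group summaries report mean and standard error
(sd/√n; missing for n = 1 cells).

## Fractal irregularity

Scar irregularity is measured by two box-counting dimensions: AFD on the
filled mask (plane-filling regular limit 2.0) and PFD on the one-pixel inner
boundary (smooth-outline limit 1.0), the boundary being foreground pixels
with at least one 4-neighbour outside the mask. Counting uses a single grid
anchored at the top-left of the mask's bounding box over the fixed ladder
{2, 3, 4, 6, 8, 12, 16, 32, 64} px; no offset minimization (offset choice
shifts the dimension by < 0.05 on test shapes) and no size-range pruning.
The dimension is the OLS slope of log(count) against log(1/size), with the
log–log r² as a diagnostic. Known bias: when the object is small relative
to the largest boxes (lesions below ≈3000 px²), the large-box counts
saturate and inflate the estimate; trend analyses over time are still
meaningful because the ladder is fixed, but absolute values of small lesions
should be read with this in mind. Time courses of AFD/PFD are summarized by
OLS lines per group.

## Photometry

- **Opacity**: red luminosity is the mode (peak bin) of the 256-bin
  red-channel histogram over the eye ROI, ties broken toward the lower bin,
  no smoothing. ΔOpacity = left-eye minus right-eye luminosity, the intact
  contralateral eye serving as the per-animal internal reference.
- **Angiogenesis**: vessel foreground pixels × mm/px × 1000 gives vessel
  microns; the angiogenesis index IA = µ_day / µ_basal divides by the mean
  vessel microns of the basal (healthy-control) group, so the basal group's
  own mean IA is 1 by construction.
- **Opacity/area index**: ΔOpacity ÷ percent damaged area. The source
  analyses plot an index "relating" the two variables without writing the
  formula; this ratio is the only dimensionally simple combination of
  exactly those two quantities and is adopted as such, explicitly an
  assumption. Undefined (reported missing) for a fully healed eye.

## Healing kinetics

Lesion-area time courses follow y = A·e^(k·t), k < 0 for healing (units per
day). The default fit is log-linear — OLS of ln y on t, A = e^intercept,
k = slope — exact on noiseless exponential data and reproducible; a
nonlinear least-squares fit on the original scale, initialized from the
log-linear solution, handles series that touch zero. Derived statistics:

- percent initial difference 100·(1 − A_treat/A_ref) — treatment effect on
  fitted initial lesion size (defined on amplitudes, i.e. t = 0, which is
  what the published percentages equal exactly);
- rate slowdown 100·(1 − |k_treat|/|k_ref|);
- interval decrease 100·(1 − e^(k·Δt)), amplitude-free;
- fold change (value − baseline)/baseline, the "X times" phrasing;
- trend ratio slope_a/slope_b for comparing AFD/PFD time trends.

## Synthetic scenes: what they emulate and what they don't

A scene is an elliptical eye on a dark background (default 320 × 240 px,
semi-axes 100 × 75 — a desk-scale stand-in for the original 2592 × 1944
frames; all geometry parameters are free):

- interior red channel constant at `red_luminosity_mode`, so the red mode is
  exact by construction at zero noise;
- 10% of interior pixels carry a dim desaturated-green iris texture
  (brightness 30, i.e. below the segmenter's brightness floor). This both
  mimics iris speckle and gives the Otsu-within-gate histogram its dark
  class, as dim greenish structure does in real micrographs;
- the lesion is a radial star polygon r(θ) = r₀(1 + irr·Σ aₙcos(nθ+φₙ)),
  aₙ ∝ 1/n for n = 2…16, normalized so `irregularity` = 1 is an RMS radial
  perturbation of 0.25·r₀, with r₀ rescaled so the expected enclosed area
  equals the request (realized areas within 5%). Lesion colour has hue
  ≈ 82, safely inside the gate;
- vessels are one connected branching random-walk tree (trunk 3 px wide,
  branches 1 px) in a yellow-green (hue ≈ 26) outside the lesion hue band
  but bright in the green channel; newly covered pixels, weighted by stroke
  width, count toward the requested extent so foreground scales linearly
  with it;
- noise is additive Gaussian per channel, clamped to [0, 255]; longitudinal
  series get multiplicative lognormal noise, exp(ε) with ε ~ N(0, σ),
  σ = √ln(1 + cv²) (median 1, so log-linear rate recovery is unbiased).

Not emulated: photorealistic corneal texture, specular highlights,
illumination drift between sessions, motion blur, partially occluding
eyelids, and colour crosstalk between fluorescein and vasculature. Passing
tests therefore validate the measurement chain — given objects with the
stated colour contrasts, the pipeline recovers their geometry and kinetics —
not robustness to acquisition pathologies of real micrographs.

## The synthetic cohort

`make_fixture` writes 4 groups × 6 animals × 4 days (3, 7, 10, 15) of
left-eye scenes plus one right-eye reference per animal. Healing rates are
the printed treatment-study values (negative control −0.174/day,
dexamethasone −0.100, experimental extract −0.108); amplitudes 6000, 2000,
1300 px² are scaled to the scene size; per-animal areas carry 5% CV
lognormal noise; the healthy-control group is lesion-free with baseline
vessels; opacity modes interpolate per group between day-3 and day-15
values, the dexamethasone-like group recovering fastest and the
experimental-treatment group getting the roughest, slowest-closing outlines.
End-to-end, the pipeline recovers the per-group rates within ±0.004 (the
acceptance tolerance is ±0.015) at this problem size, which keeps a full
cohort run under ~20 s.

## Numerical choices and degenerate inputs

- Otsu thresholds follow the convention foreground = value ≥ t; with fewer
  than two populated bins there is nothing to separate and everything
  passes (the brightness floor still applies).
- Histogram modes break ties toward the lower bin.
- Hue/saturation gates that select no pixels yield an empty lesion mask plus
  a warning; a blank frame fails eye-ROI segmentation with an error.
- Log-linear fits refuse nonpositive values with a message pointing to the
  nonlinear method; constant series fit k = 0 with r² = 1.
- A perfect fit to a zero-variance series defines r² = 1.
- All randomness flows from explicit integer seeds (`numpy` Generator /
  SeedSequence); identical seeds give bit-identical images, series, and
  output CSVs.

## Known limitations

- The fixed box ladder biases absolute fractal dimensions of small objects
  upward (see above).
- The percent-initial-difference statistic compares fitted amplitudes at
  t = 0, not measured day-3 sizes; the two coincide only under a perfect
  exponential.
- IA normalization assumes the basal group has nonzero vessel extent; a
  vessel-free basal set leaves IA undefined (warned, reported missing).
- The opacity/area index formula is an assumption (see Photometry).
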