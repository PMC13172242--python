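# Methods

This note documents the models, estimator conventions, numerical choices
and known limitations of `dwidistort`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic phantom

The generator rasterizes an idealized axial prostate slice on a 128 × 128
grid at 0.5 × 0.5 mm: an elliptical prostate (anteroposterior × left-right
semi-axes 16 × 20 mm), whose posterior crescent of depth 7 mm is the
peripheral zone (PZ), a circular rectal gas region (radius 10 mm) separated
from the prostate by a 2 mm gap, and surrounding soft tissue. The row axis
is the anteroposterior axis (row index grows posteriorly) and doubles as
the phase-encoding axis for all distortion operations; this convention is
stated once in `image.py` and used everywhere.

DWI channels are generated as S(b) = S0·exp(−b·ADC) at b = 50, 400,
800 s/mm², with zone values (PZ ADC 1.8 × 10⁻³, transition zone
1.3 × 10⁻³ mm²/s; PZ bright and rectal gas dark on the T2-like image)
chosen for qualitative realism of a 3-T prostate exam — they are
configurable defaults in `data/phantom_defaults.yaml`, not measurements.
Noise is Rician — the magnitude of a complex Gaussian perturbation, the
standard magnitude-MRI noise model — with scale σ = 15 by default (prostate
SNR ≈ 50 at b = 50); zero-signal pixels then follow a Rayleigh law with
mean σ√(π/2), which the tests verify. The T2 reference is kept noise-free:
it plays the role of anatomical truth and nothing downstream estimates
noise from it.

2D axial slices are the primary unit; 3D volumes are treated as stacks of
independent slices sharing a spacing. What the phantom does *not* emulate:
anatomical variability of real glands (shape, zonal heterogeneity,
lesions), spatially correlated noise, partial-volume effects at zone
borders, and any k-space/EPI physics (no B0 field map, no off-resonance
phase evolution — the simulator below is purely geometric). Tests passing
on the phantom therefore validate the geometric and statistical machinery,
not performance on clinical images.

## Distortion simulator

Four stages, applied in a fixed order (elastic → AP scale → rotation →
translation) to every b-channel identically, each stage resampling once.

**Displacement field.** Both components at each node of a coarse lattice
(spacing 32 px = 16 mm) are i.i.d. Normal(0, σ²) in pixels; nodes outside
the rectal-adjacent target region are zeroed; a bicubic spline interpolates
the lattice to pixel resolution; the dense field is then re-masked to
exactly zero outside the region. The target region is derived from the
masks: pixels within 10 mm of the rectal gas, dilated by 2 mm, intersected
with the posterior half of the prostate bounding box (the delineation of
this region in practice is unspecified; this margin/posterior-half rule is
one reasonable, configurable reading).

**Warping.** Backward mapping — the output at pixel p samples the input at
p + u(p) — with bilinear interpolation for images and nearest-neighbour for
masks; out-of-grid samples are 0. Backward mapping is artifact-free for
arbitrary fields; the alternative forward-splatting convention would leave
holes. |J| is the Jacobian determinant of that same backward map
(central finite differences in the interior, one-sided at borders), so
multiplying the warped image by |J| is exactly the change-of-variables
factor and the elastic + modulation stage conserves total signal up to
discretization error. Folding (J < 0) is allowed and |J| used as-is; a
per-simulation diagnostic reports the folded-pixel fraction.

Measured on the default phantom at σ = 3, the interior-signal change is
0.2% on average; because the hard re-masking at the region edge makes the
map discontinuous there, the error distribution has a tail, and roughly 1
in 100 field draws slightly exceeds 2%. This is an intrinsic property of
masking the field sharply (which the field contract requires — exact zero
outside the region), not of the warping scheme.

**Rigid stages.** AP scaling and rotation are taken about the geometric
image centre (the convention is otherwise arbitrary); rotation operates in
physical (mm) coordinates so anisotropic grids are handled correctly;
translation is drawn per axis as an independent uniform magnitude within
the preset range with a random sign ("in-plane" read as a per-component
bound). Each rigid sub-step that is exactly the identity is skipped, so a
degenerate preset is a bit-exact fixed point of the whole pipeline — a
property the acceptance tests assert.

**Presets.** mild: σ = 3 px, scale 0.95–1.05, rotation 0–3°, translation
≤ 0.5 mm; moderate: σ = 5, scale 0.95–0.99 ∪ 1.01–1.05, rotation 1–3°,
translation 0.5–1 mm; severe: σ = 7, scale 0.90–0.95 ∪ 1.05–1.10, rotation
3–5°, translation 1–1.5 mm; extreme: σ = 10, scale 0.85–0.95 ∪ 1.05–1.15,
rotation 5–15°, translation 1.5–2 mm. The mild/moderate rotation split
overlaps; the assignment here (0–3° / 1–3°) is one reading of an ambiguous
printed list and is configurable by constructing a `SeverityPreset`
directly. Scale intervals in a union are selected with probability
proportional to their length, then sampled uniformly. The `training` preset
(σ = 10, scale 0.9–1.1, rotation ≤ 15°, translation ≤ 2 mm per axis) draws
continuously varying distortions rather than severity levels. Only the DWI
channels and masks are distorted; the T2 image stays undistorted, serving
as the anatomical reference.

Every simulation returns a `DistortionRecord` (field, Jacobian, rigid
parameters, seed) that replays bit-exactly; determinism is part of the
contract and tested.

## Severity grading

The mismatch estimator is deliberately explicit, because "boundary
mismatch in mm" admits several readings:

- `boundary_mismatch` extracts the 4-connected inner boundaries of the two
  masks and computes, for every boundary point of each mask, the distance
  to the nearest boundary point of the other (anisotropic spacing
  respected). The pooled distances are reduced by a named statistic:
  **p95** (default; robust to single-pixel spurs) or **max** (the
  Hausdorff distance). Whether human raters grade worst-case or typical
  displacement is unknowable from a rule statement alone, so both are
  exposed and every report names the statistic used.
- `grade` bins the mismatch with half-open intervals: none < 0.5 mm
  (sub-pixel threshold, configurable), mild [0.5, 2), moderate [2, 4),
  severe [4, 6), extreme ≥ 6 mm. The edge convention (2.0 → moderate,
  6.0 → extreme) is fixed and tested.
- `grade_simulated` computes the same quantity from the *known* transform
  instead of a warped mask: the exact composed backward map B (closed-form
  rigid inverses; bilinear lookup of the elastic field) is evaluated on
  the pixel grid, the displaced mask is rasterized as mask[round(B(p))],
  and its boundary is compared to the original with the same symmetric
  statistic. Rasterizing through B handles folding fields exactly (a
  boundary point may have several preimages) where a per-point push-forward
  would not; and using the nearest-boundary statistic rather than raw
  displacement magnitude avoids overstating rotations, whose boundary
  motion is largely tangential. The two estimators agree within one pixel
  diagonal (0.71 mm at 0.5 mm spacing) in ≥ 90% of random simulations —
  an acceptance property.

## Diffusion fitting

Unweighted ordinary least squares of ln S against b per pixel (slope =
−ADC, intercept = ln S0); no weighted or nonlinear refinement, matching the
plain linear-regression convention. Pixels with any channel at or below a
signal floor (default 10⁻⁶) are excluded from the valid mask and zeroed
rather than clamped — ln 0 must be avoided, and flagging is more honest
than imputing. The slope is computed against channel-0-shifted log-signals
so a constant signal yields ADC exactly 0. On noiseless mono-exponential
data the fit is exact to machine precision; under Rician noise at prostate
SNR 20 the median ADC bias is below 5% (200-realization experiment in the
acceptance suite). Synthesis S(b) = S0·exp(−b·ADC) defaults to
b = 1500 s/mm², the conventional computed high-b image.

## Image-quality metrics

- **PSNR** = 10·log10(L²/MSE) with the MSE over mask pixels only and the
  dynamic range L taken from the *reference within the mask* (the range
  convention is otherwise unstated; a masked range makes strata with
  different anatomy comparable). Identical inputs return a documented
  99 dB sentinel. A constant reference raises rather than returning an
  arbitrary value. With a masked range, strongly distorted inputs can
  legitimately score below 0 dB.
- **S-SSIM** is only the structure term of SSIM,
  s = (σ_xy + C3)/(σ_x σ_y + C3), with 11 × 11 Gaussian windows of width
  1.5 px and C3 = (0.03·L)²/2. The local map is computed on the full image
  and then averaged over mask pixels — zeroing outside the mask first
  would bias every window that straddles the mask edge. It is invariant to
  positive affine intensity maps of the test image up to C3 effects
  (tested at 10⁻³).
- **Dice** = 2|A∩B|/(|A|+|B|), defined as 1.0 when both masks are empty.
- `evaluate_case` emits one row per (b-channel, region, metric); channel
  aggregation, when reported, is the unweighted mean over b-channels (the
  per-channel-versus-pooled convention is not standardized; per-channel
  rows keep both options open).

All three metrics are verified against independent brute-force
implementations (explicit convolution with a hand-built Gaussian kernel,
per-pixel MSE accumulation, set counting) to 10⁻⁸.

## Preprocessing

Resampling uses nibabel's affine-aware volume resampling (trilinear for
images, nearest for masks), standardizing onto the reference grid at
0.5 × 0.5 × 3 mm voxels. Cropping keeps the prostate bounding box scaled by
a factor (default 2) about its centre, clamped to the grid, with a record
for exact inverse placement. Min-max normalization pools intensities over
the prostate regions of the fitting set — pooled rather than per-case, so
normalized intensities are comparable across cases — and applies the fixed
affine map elsewhere; clipping to [0, 1] is optional and off by default so
out-of-range transfer is visible. Zero-padding to a square canvas
(conventionally 512 × 512) is provided but optional; the phantom pipeline
uses smaller canvases.

## Experiment pipeline and problem sizes

`run_severity_experiment` simulates each configured severity on each
phantom case, grades each simulation both ways, computes masked metrics
against the undistorted reference, and writes a stratified CSV/JSON with
the config hash and base seed embedded; reruns are byte-identical. Child
seeds are drawn from a single generator seeded by `base_seed` and kept
below 2³¹. The concordance harness accepts externally produced mask sets
(e.g. segmenter outputs before/after any correction method) and reports
mean ± sd Dice per severity stratum.

The default experiment sizes — 50 simulations per preset and 100 noise
realizations in the acceptance script, 100 simulations per preset in the
severity-ordering test — were chosen as the smallest sizes at which the
median/mean orderings under study are stable across seeds; all complete in
well under a minute on one CPU.

## Known limitations

- The simulator is geometric, not physical: displacement fields are not
  derived from a B0 map, so their spatial statistics only loosely resemble
  true susceptibility fields, and the elastic deformation is confined to
  the configured rectal-adjacent region by construction.
- The severity grader implements a rule; it cannot capture whatever visual
  context human raters bring to borderline slices, and inter-rater
  variability is out of scope.
- The phantom's two-zone prostate with piecewise-constant parameters makes
  some estimators look better than they would on textured tissue (e.g. the
  masked PSNR range L is small, and zone-constant ADC makes median-based
  recovery summaries insensitive to edge pixels).
- No deep-learning correction model is included; the evaluation harness
  accepts corrected images/masks as plain inputs.
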