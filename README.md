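# dwidistort

Geometric susceptibility-distortion simulation, severity grading and masked
image-quality evaluation for prostate diffusion-weighted MRI (DWI).

## The problem

Prostate DWI is acquired with single-shot echo-planar imaging, whose long
readout makes it sensitive to B0 field inhomogeneity near the air-filled
rectum. The result is geometric distortion along the phase-encoding
(anteroposterior) axis — the posterior prostate, and especially the
peripheral zone (PZ), appears stretched, compressed or displaced relative to
the anatomically faithful T2-weighted reference, with signal pile-ups and
voids where tissue is locally compressed or expanded. Methods that correct
such distortion (deep-learning or otherwise) need three well-defined pieces
of machinery, which this package provides as a reusable toolkit:

1. **A severity-parameterized distortion simulator** that turns undistorted
   DWI slices into realistically distorted ones, with full ground-truth
   bookkeeping, so that paired training/evaluation data can be created
   without extra acquisitions.
2. **A rule-based severity grader** that maps the prostate boundary mismatch
   between T2-derived and DWI-derived masks (in mm) to the standard
   none / mild / moderate / severe / extreme bins.
3. **A masked evaluation suite** — PSNR, the structure-only SSIM component
   (S-SSIM), and the Dice coefficient, computed inside prostate and PZ
   masks — plus mono-exponential ADC fitting for the clinically read maps.

A built-in synthetic prostate phantom generator supplies test data with the
assumed anatomy (0.5 mm axial grid, elliptical prostate, posterior PZ
crescent abutting a rectal gas circle, mono-exponential DWI signal with
zone-dependent ADC and Rician noise), so no external data is ever required.

## The model

The simulated distortion is a sequence of four random transforms applied
identically to every b-value channel of a slice:

1. **Elastic deformation** restricted to the rectal-adjacent posterior
   prostate region: node displacements u = (u_x, u_y) with
   u_x, u_y ~ N(0, σ²) are drawn on a coarse grid (spacing 32 px = 16 mm),
   zeroed outside the target region, and interpolated smoothly to pixel
   resolution.
2. **Jacobian intensity modulation**: with
   J = (1 + ∂u_x/∂x)(1 + ∂u_y/∂y) − (∂u_x/∂y)(∂u_y/∂x),
   the warped image is multiplied by |J| to emulate signal pile-up
   (|J| > 1) and voids (|J| < 1),
   I_distorted = I_elastic · |J|.
3. **Anteroposterior scaling** about the image centre.
4. **Rotation and in-plane translation.**

Four presets fix the sampling ranges: σ = 3 / 5 / 7 / 10 px, AP scale from
0.95–1.05 down to 0.85–0.95 ∪ 1.05–1.15, rotation magnitude up to 15°, and
translation up to 2 mm per axis, for mild / moderate / severe / extreme
distortion; a `training` preset draws from the full continuous ranges.

Severity is graded from boundary mismatch d (mm) as none (d < 0.5),
mild (d < 2), moderate (2 ≤ d < 4), severe (4 ≤ d < 6), extreme (d ≥ 6).

Diffusion maps follow the mono-exponential model S(b) = S0·exp(−b·ADC),
fitted per pixel by linear least squares on ln S against b (b = 50, 400,
800 s/mm² by default), from which high-b images (e.g. b = 1500 s/mm²) are
synthesized.

## Worked example

```python
import numpy as np
import dwidistort as dd

case = dd.make_phantom(dd.PhantomSpec.default(seed=0))
distorted, masks, record = dd.simulate_distortion(case, preset="severe", seed=11)

truth = dd.grade_simulated(record, case.prostate_mask)
measured = dd.boundary_mismatch(case.prostate_mask, masks["prostate"])
prostate = case.prostate_mask.data.astype(bool)

print(f"ground-truth mismatch: {truth.mismatch_mm:.2f} mm -> grade '{truth.label}'")
print(f"mask-based mismatch:   {measured.mismatch_mm:.2f} mm")
print(f"prostate Dice after distortion: {dd.dice(case.prostate_mask, masks['prostate']):.3f}")
print(f"prostate PSNR (b=50):   {dd.psnr(case.dwi.channel(0), distorted.channel(0), prostate):.2f} dB")

fit = dd.fit_monoexp(case.dwi)
pz = case.pz_mask.data.astype(bool)
print(f"median PZ ADC: {np.median(fit.adc.data[pz])*1e3:.2f} x 10^-3 mm^2/s")
```

prints

```
ground-truth mismatch: 3.50 mm -> grade 'moderate'
mask-based mismatch:   3.54 mm
prostate Dice after distortion: 0.879
prostate PSNR (b=50):   3.75 dB
median PZ ADC: 1.80 x 10^-3 mm^2/s
```

The drawn severe-preset transform (σ = 7 px, AP scale 0.925, rotation
+4.2°, translation (−1.07, +1.46) mm) displaced the prostate boundary by
3.5 mm: the two independent mismatch estimators — one evaluated from the
known transform, one measured from the warped mask — agree to 0.04 mm, and
the phantom's PZ ADC of 1.80 × 10⁻³ mm²/s is recovered exactly from the
noiseless channels.

A command-line interface mirrors the library:

```bash
dwidistort phantom --out case --seed 1
dwidistort distort --in case --preset severe --seed 3 --out distorted
dwidistort grade --ref case/prostate_mask.nii.gz --test distorted/prostate_warped.nii.gz
dwidistort fit-adc --dwi case/dwi.nii.gz --bvals 50,400,800 --out maps
dwidistort run --config experiment.yaml
```

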