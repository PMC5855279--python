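# Methods

## Measurement model

The material is a PDMS sheet loaded with an irreversible thermochromic dye
that switches from white to magenta around 75 °C and does not revert.  The
color at any point therefore encodes the **maximum** temperature that point
ever attained; every temperature this package reports is a
maximum-attained temperature, never a snapshot.

The color coordinate is Cr, the red color difference of the YCrCb transform
applied to 8-bit RGB values on the 0–255 scale with **no** +128 chroma offset
and no gamma handling.  Images are used exactly as stored: the calibration
cubic's coefficients are only meaningful on this particular Cr scale, and the
calibration was performed on raw camera output, so the toolkit treats stored
values as the quantities entering the linear transform.  The Cr coefficient
row (0.500, −0.419, −0.081) sums to zero, which makes Cr exactly invariant to
any constant offset added to all three channels — the robustness to
illumination drift that motivates using Cr rather than raw RGB.

All in-memory arithmetic is double precision; quantization to 8 bits happens
only when an image file is written.  Propagating one 8-bit rounding step
through the Cr form bounds the per-pixel quantization error by
0.5·(0.500+0.419+0.081) = 0.5 Cr units.

## Calibration curve

`CrCalibration` fits Cr(T) = Σ aₖTᵏ (cubic by default) by **unweighted**
ordinary least squares on (temperature, mean-Cr) pairs.  Per-point Cr
standard deviations are stored for reporting but do not weight the fit; a
weighted fit is a straightforward extension point, but the standard
calibration procedure for this material uses plain least squares.  The fit is
performed on numpy's scaled polynomial domain and converted back to raw-power
coefficients: raw T, T², T³ regressors over 40–100 °C are conditioned at
~10⁹ and a raw Vandermonde solve loses the leading coefficient's accuracy,
whereas the scaled route recovers noiseless coefficients to ~10⁻¹⁴ relative.

The validity range [t_min, t_max] is set by the extreme calibration
temperatures.  Monotonicity on the range is decided analytically from the
real roots of the derivative polynomial (a derivative that is identically
zero is treated as non-monotone, since it admits no inverse); tests
cross-check against dense sampling.

### Inversion

Temperature estimation inverts the monotone curve at a measured Cr:

* scalar path: bracketed Brent root finding on [t_min, t_max] (xtol 1e-9);
* array path (maps): a 4097-point monotone lookup grid followed by three
  clipped Newton steps.  The two paths agree below 1e-6 °C and the tests
  assert it.

Outside the curve's Cr range the estimate is **clamped, never extrapolated**:
an irreversible dye carries no information below its activation floor, and
extrapolating a cubic is unsafe.  Clamped cells carry a status
(`clamped_low` = "≤ t_min", `clamped_high` = "≥ t_max") and reports treat
`clamped_low` as a censored statement, not a point estimate.

The cubic is nearly flat at the low end of the range (its derivative has a
minimum of ≈0.006 Cr/°C near 43.7 °C, versus ≈0.22 at 80 °C and ≈0.74 at
100 °C), so temperature errors for a given Cr noise are intrinsically
largest around 40–55 °C.  This is a property of the material's response, not
of the algorithm; acceptance checks therefore bound errors over 60–100 °C,
where the curve has usable slope.

## Temperature maps and the resolution trade-off

Maps are computed **average-then-invert**: the Cr plane is reduced by
non-overlapping w×w block means and each tile mean is inverted.  This matches
the calibration procedure, which averages Cr over a region before converting
to temperature.  The alternative invert-then-average order is exposed
(`order="invert_then_average"`) for sensitivity analysis; the two agree to
first order but the alternative acquires a Jensen bias wherever the curve is
convex (measurably low, ≈−0.8 °C at 92 °C with σ_Cr = 2), which is the
regression-tested reason for the default.

Edge tiles that do not fill a complete window are averaged over the pixels
they contain, so no pixel is discarded and map shape is
(⌈H/w⌉, ⌈W/w⌉).

`resolution_curve` pools block-averaged Cr cells over replicate images of a
uniform sheet and tabulates their standard deviation, and that of the
inverted temperatures, per window.  For iid pixel noise of sd σ the cell sd
is σ/w (mean of w² iid values); the suite asserts this within 15% and that
sd is non-increasing in w, making the error/resolution trade-off quantitative
under the synthetic noise model.

## Synthetic phantom generator

The generator emulates the two physical observations used to characterize
the material:

* **uniform sheets** at a known oven temperature (the calibration protocol:
  40–100 °C in 5 °C steps, four replicate 1.6-mm sheets, 480×720-pixel
  frames covering 7×9 mm, i.e. 0.0125 mm/pixel), and
* **wire-heater hot spots**: a 2.4-mm-diameter heater pressed on the sheet,
  modeled as T(r) = heater_t inside the contact disk and a radial Gaussian
  decay `ambient + (heater − ambient)·exp(−(r − r_c)²/2σ_f²)` outside.  The
  Gaussian is a geometric stand-in, not a heat-conduction solution: it is the
  simplest monotone radial decay with a controllable width.  The composite's
  measured thermal conductivity (0.151 W/m·K) is recorded as metadata for a
  possible future PDE-based generator, which is an explicit non-goal now.

Pixels are synthesized by prescribing Cr per pixel and applying the inverse
color transform at a fixed operating point Y = 200, Cb = 0, chosen once so
the whole white→magenta Cr excursion (−6.26 to +3.8) plus noise and outliers
stays comfortably inside the RGB cube; gamut is verified at generation time
and violations raise.  Where the true maximum temperature never reached the
calibration floor, the synthetic Cr equals the curve's value at t_min — the
dye never switched — while the ground-truth field keeps the real sub-floor
temperature.

The noise model is additive in Cr space:

| parameter | default | meaning |
|---|---|---|
| `sigma_cr` | 1.0 Cr units | per-pixel Gaussian noise |
| `particle_fraction` | 0.005 | fraction of pixels replaced by outliers |
| `particle_amplitude` | 10 Cr units | outlier offset magnitude, random sign |
| `illumination_offset_amplitude` | 0 | per-image constant RGB offset |
| `seed` | 0 | master seed |

Defaults were chosen once so that full-frame averaging yields sub-0.1 °C
errors while single-pixel speckle remains visible — a plausible regime for a
microscope camera, documented as a toolkit default rather than a measured
camera property.  The outlier term stands in for dust (white, Cr-lowering)
and undispersed dye particles (magenta, Cr-raising), hence the random sign.
What the generator does **not** emulate: gamma encoding, Bayer demosaicing,
vignetting, spatially correlated illumination gradients, heat conduction in
the sheet, and surface texture.  Passing tests therefore demonstrate the
correctness of the analysis chain under a stated noise model, not the
field performance of any particular camera.

Every generator is a pure function of (parameters, seed): replicate images
in a calibration set get sub-seeds derived from the master seed via
`SeedSequence([master, index])`, and identical inputs give byte-identical
files.  A ground-truth field always accompanies an image.

## Numerical and design choices

* Fit: scaled-domain least squares (see above); degree a parameter, cubic
  default; at least degree+1 **distinct** temperatures required.
* Inversion tolerance: 1e-9 °C bracketing tolerance, far below the ~0.01 °C
  level at which the measurement itself is meaningful.
* Ties in the hottest-cell summary break row-major; an all-`clamped_low`
  map has no hottest cell and empty in-range statistics.
* Map rendering uses a fixed [t_min, t_max] → colormap mapping with
  `clamped_low` cells in neutral gray, so regenerated figures are stable
  given identical inputs.
* The CLI (`calibrate` / `map` / `simulate` / `resolution`) is a thin layer
  over the library; every run writes a manifest echoing the resolved
  configuration, and outputs round-trip through the package's own readers.

## Problem sizes

The test suite exercises unit behaviour on small frames (tens of pixels on a
side) and runs the end-to-end checks at the study scale: 480×720-pixel
frames, 13 temperatures × 4 replicates for calibration, 25×25-pixel
averaging for hotspot reconstruction.  The full suite completes in a few
seconds.

## Known limitations

* Single-dye, single-threshold calibration only; reversible dyes and
  multi-dye stacks are out of scope.
* The hotspot profile is geometric; absolute spatial accuracy claims about
  real heater experiments require a conduction model.
* Real cameras may gamma-encode; if so, the calibration absorbs the encoding
  only to the extent the calibration and measurement images share it.
* Temperatures below the calibration floor are censored ("≤ t_min"), which
  is intrinsic to an irreversible dye, not recoverable by software.
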