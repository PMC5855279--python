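# thermocr

Maximum-temperature measurement from photographs of irreversible
thermochromic material.

A PDMS phantom loaded with an irreversible thermochromic dye changes from
white to magenta as it heats and keeps the color of the **highest**
temperature it ever reached.  That makes a photograph of the material a
permanent record of the maximum-temperature field — useful for evaluating
thermal damage in surgical simulators (e.g. catheter ablation, which heats
tissue to ~80 °C) and for quantifying the performance of energy devices.
`thermocr` is for experimentalists who have such photographs (or want to
prototype the analysis before building samples): it turns 8-bit RGB images
into calibrated maximum-temperature maps.

## Method

RGB pixels are converted to the YCrCb space,

```
Y  =  0.299 R + 0.587 G + 0.114 B
Cr =  0.500 R − 0.419 G − 0.081 B
Cb = −0.169 R − 0.331 G + 0.500 B
```

and only the red color difference Cr is used: its coefficients sum to zero,
so it is invariant to additive illumination offsets.  Heated sheet samples at
known temperatures T give a cubic calibration curve

```
Cr(T) = a₃T³ + a₂T² + a₁T + a₀
```

fitted by ordinary least squares (the built-in reference calibration for the
75 °C magenta dye / PDMS composite is
`Cr = 5.43×10⁻⁵ T³ − 7.11×10⁻³ T² + 3.16×10⁻¹ T − 11.0`, valid on
40–100 °C).  A measured Cr is inverted through the monotone curve by
bracketed root finding to recover the maximum attained temperature; Cr at or
below the curve's value at the calibration floor means the dye never
activated and is reported as "≤ t_min", never as a point estimate.

Per-pixel Cr is noisy (dust, undispersed dye particles), so maps are computed
at a chosen block resolution: w×w tiles of Cr are averaged and the tile mean
is inverted.  For iid pixel noise the Cr standard deviation falls as σ/w —
the toolkit quantifies this measurement-error / spatial-resolution trade-off.

A seeded synthetic phantom generator (uniform sheets, wire-heater hot spots,
full calibration sets) with exact ground truth makes the whole pipeline
testable end to end without physical samples.

## Worked example

Simulate a calibration campaign (13 temperatures × 4 replicate 480×720
sheets), fit the curve, then reconstruct a simulated 80 °C wire-heater
hot spot:

```
$ thermocr simulate calibration-set --seed 1 --out-dir sim
$ thermocr calibrate --points sim/points.csv --out-dir cal
n_points: 52
coefficients: [-11.002731926431673, 0.31619870965970825, -0.007113862186714944, 5.43218807436338e-05]
t_min: 40.0
t_max: 100.0
max_abs_error_C: 0.5059880251825888
residual_sd_cr: 0.0021464061070913254
calibration_json: cal/calibration.json

$ thermocr simulate hotspot --temperature 80 --ambient 25 \
    --contact-radius 60 --sigma-falloff 40 --seed 7 --out-dir hot
$ thermocr map hot/hotspot.png --calibration cal/calibration.json \
    --window 25 --out-dir map
n_cells: 580
window: 25
fraction_clamped: 0.453448275862069
fraction_clamped_low: 0.453448275862069
fraction_clamped_high: 0.0
max_in_range: 80.52673765065397
min_in_range: 40.00544864739394
mean_in_range: 51.01825773460986
hottest_cell: (11, 14)
hottest_temperature: 80.52673765065397
```

The refit coefficients match the reference cubic to three significant
figures; the hottest 25×25-pixel block reads 80.5 °C against the 80 °C heater
set-point (the heater controller itself is only accurate to ±2 °C), and 45%
of the map is flagged `clamped_low` — the ambient 25 °C background never
activated the dye, so those cells mean only "≤ 40 °C".  `map/` also contains
the numeric grid (`temperature.csv`), the per-cell status grid
(`status.csv`) and a rendered false-color map (`temperature.png`).

The same operations are available as a library, sklearn-style:

```python
from thermocr import CrCalibration, TemperatureMapper, reference_curve

curve = reference_curve()                      # or CrCalibration(3).fit(T, cr)
tmap = TemperatureMapper(curve, window=25).transform(image)
```

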