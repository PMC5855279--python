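"""Synthetic phantom-image generator with known ground truth.

Emulates two kinds of observation of an irreversible thermochromic
dye/PDMS sheet:

* a uniform sheet held at a known temperature (the calibration protocol:
  oven-heated 1.6-mm sheets imaged under a microscope), and
* a local-heating experiment where a thin wire heater touches the sheet and
  leaves a hot spot recorded as a permanent color change.

Pixels are constructed by prescribing a Cr value per pixel and mapping it
back to RGB through the inverse color transform at a fixed (Y, Cb) operating
point.  Noise acts additively in Cr space: per-pixel Gaussian noise plus a
sparse random-sign outlier term standing in for dust and undispersed dye
particles.  Every generator is a pure function of (parameters, seed), and a
ground-truth temperature field always accompanies the image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint, CrCalibration
from .color import YCRCB_TO_RGB, cr_plane

#: Fixed synthesis operating point.  Eq-style chroma alone does not pin down
#: a pixel; Y and Cb are held at values for which the whole white->magenta Cr
#: excursion (plus noise and particle outliers) stays inside the RGB cube.
Y_OPERATING = 200.0
CB_OPERATING = 0.0

DEFAULT_SIZE = (480, 720)
#: mm per pixel implied by 480x720 px covering 7x9 mm.
DEFAULT_PIXEL_PITCH_MM = 9.0 / 720.0

#: Thermal conductivity of the dye/PDMS composite (W/m·K); recorded as
#: metadata only — the hotspot profile is a geometric model, not a heat
#: conduction solution.
COMPOSITE_THERMAL_CONDUCTIVITY_W_M_K = 0.151


class GamutError(ValueError):
    """A requested Cr field cannot be represented at the operating point."""


@dataclass(frozen=True)
class NoiseModel:
    """Per-pixel Cr noise model.

    sigma_cr: Gaussian noise sd in Cr units. Default 1.0, chosen so that
        full-frame averaging yields sub-0.1 °C errors while single-pixel
        speckle remains visible.
    particle_fraction: proportion of pixels replaced by outliers (dust /
        undispersed dye particles).
    particle_amplitude: |Cr| offset of an outlier pixel; the sign is random.
    illumination_offset_amplitude: max per-image constant additive RGB
        offset (uniform in +-amplitude). Cr is invariant to it by
        construction; it exists to exercise that invariance.
    seed: master seed; identical (parameters, seed) give identical output.
    """

    sigma_cr: float = 1.0
    particle_fraction: float = 0.005
    particle_amplitude: float = 10.0
    illumination_offset_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_cr < 0:
            raise ValueError("sigma_cr must be >= 0")
        if not 0.0 <= self.particle_fraction <= 1.0:
            raise ValueError("particle_fraction must lie in [0, 1]")

    def silent(self) -> "NoiseModel":
        """Copy with all noise terms switched off (seed preserved)."""
        return replace(
            self,
            sigma_cr=0.0,
            particle_fraction=0.0,
            illumination_offset_amplitude=0.0,
        )


@dataclass(frozen=True)
class HotspotSpec:
    """Geometry of a wire-heater hot spot.

    The ground-truth maximum-temperature field is ``heater_t`` inside the
    contact disk and decays as a radial Gaussian outside it:

        T(r) = ambient_t + (heater_t - ambient_t) *
               exp(-(r - contact_radius)^2 / (2 sigma_falloff^2)),  r > radius

    The default contact radius corresponds to a 2.4-mm-diameter wire heater
    at the default pixel pitch (1.2 mm ≈ 96 px).
    """

    ambient_t: float = 25.0
    heater_t: float = 80.0
    center: tuple[float, float] | None = None
    contact_radius: float = 96.0
    sigma_falloff: float = 40.0

    def __post_init__(self):
        if not self.heater_t > self.ambient_t:
            raise ValueError("heater_t must exceed ambient_t")
        if self.contact_radius < 0:
            raise ValueError("contact_radius must be >= 0")
        if not self.sigma_falloff > 0:
            raise ValueError("sigma_falloff must be > 0")

    def half_amplitude_radius(self) -> float:
        """Radius where the excess temperature falls to half of its peak."""
        return self.contact_radius + self.sigma_falloff * np.sqrt(2.0 * np.log(2.0))

    def truth_field(self, size: tuple[int, int]) -> np.ndarray:
        h, w = size
        center = self.center if self.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        rows = np.arange(h)[:, None] - center[0]
        cols = np.arange(w)[None, :] - center[1]
        r = np.hypot(rows, cols)
        excess = np.exp(
            -((r - self.contact_radius) ** 2) / (2.0 * self.sigma_falloff**2)
        )
        field = self.ambient_t + (self.heater_t - self.ambient_t) * excess
        field[r <= self.contact_radius] = self.heater_t
        return field


def _noisy_cr(target_cr: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    cr = np.asarray(target_cr, dtype=float).copy()
    if noise.sigma_cr > 0:
        cr += rng.normal(0.0, noise.sigma_cr, size=cr.shape)
    if noise.particle_fraction > 0 and noise.particle_amplitude != 0:
        mask = rng.random(cr.shape) < noise.particle_fraction
        signs = rng.choice([-1.0, 1.0], size=int(mask.sum()))
        cr[mask] += noise.particle_amplitude * signs
    return cr


def _image_from_cr(cr: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    base = YCRCB_TO_RGB @ np.array([Y_OPERATING, 0.0, CB_OPERATING])
    cr_direction = YCRCB_TO_RGB[:, 1]
    image = base[None, None, :] + cr[:, :, None] * cr_direction[None, None, :]
    if noise.illumination_offset_amplitude > 0:
        image = image + rng.uniform(
            -noise.illumination_offset_amplitude, noise.illumination_offset_amplitude
        )
    if image.min() < 0.0 or image.max() > 255.0:
        raise GamutError(
            "requested Cr field leaves the RGB gamut at the fixed operating "
            f"point (Y={Y_OPERATING}, Cb={CB_OPERATING}); channel range "
            f"[{image.min():.1f}, {image.max():.1f}]"
        )
    return image


def render_sheet(
    t: float,
    curve: CrCalibration,
    size: tuple[int, int] = DEFAULT_SIZE,
    noise: NoiseModel = NoiseModel(),
):
    """Render a uniform sheet heated to temperature ``t``.

    Returns ``(image, truth)``: an HxWx3 float image (0-255 scale, quantized
    only on file write) and the constant HxW ground-truth temperature field.
    Raises if ``t`` is outside the curve's validity range.
    """
    target_cr, out = curve.evaluate(float(t))
    if out:
        raise ValueError(
            f"temperature {t} °C outside calibration range "
            f"[{curve.t_min_}, {curve.t_max_}] °C"
        )
    rng = np.random.default_rng(noise.seed)
    cr = _noisy_cr(np.full(size, target_cr), noise, rng)
    image = _image_from_cr(cr, noise, rng)
    truth = np.full(size, float(t))
    return image, truth


def render_hotspot(
    spec: HotspotSpec,
    curve: CrCalibration,
    size: tuple[int, int] = DEFAULT_SIZE,
    noise: NoiseModel = NoiseModel(),
):
    """Render a wire-heater local-heating experiment.

    The ground truth is the full-resolution maximum-temperature field of
    :meth:`HotspotSpec.truth_field` (including sub-floor ambient values).
    The *color* record is floored at the unactivated dye color: anywhere the
    maximum temperature stayed below the calibration floor, the synthetic Cr
    equals the curve's value at ``t_min`` — the dye never switched.
    """
    _, out = curve.evaluate(float(spec.heater_t))
    if out:
        raise ValueError(
            f"heater temperature {spec.heater_t} °C outside calibration range "
            f"[{curve.t_min_}, {curve.t_max_}] °C"
        )
    truth = spec.truth_field(size)
    recorded = np.clip(truth, curve.t_min_, curve.t_max_)
    target_cr, _ = curve.evaluate(recorded)
    rng = np.random.default_rng(noise.seed)
    cr = _noisy_cr(target_cr, noise, rng)
    image = _image_from_cr(cr, noise, rng)
    return image, truth


def _subseed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % 2**31)


def make_calibration_set(
    temps: Sequence[float] = tuple(range(40, 101, 5)),
    reps: int = 4,
    curve: CrCalibration | None = None,
    size: tuple[int, int] = DEFAULT_SIZE,
    noise: NoiseModel = NoiseModel(),
):
    """Generate a full synthetic calibration set.

    Defaults mirror the physical protocol: 13 temperatures from 40 to 100 °C
    in 5 °C steps, four replicate sheets each.  Per-replicate seeds are
    derived deterministically from ``noise.seed``.

    Returns ``(images, points)`` where ``images`` is a list of
    ``(temperature, image)`` pairs and ``points`` a list of
    :class:`CalibrationPoint` with full-frame mean and sd of the Cr plane.
    """
    temps = list(temps)
    if not temps:
        raise ValueError("temps must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if curve is None:
        from .calibration import reference_curve

        curve = reference_curve()
    images: list[tuple[float, np.ndarray]] = []
    points: list[CalibrationPoint] = []
    index = 0
    for t in temps:
        for _ in range(reps):
            sub = replace(noise, seed=_subseed(noise.seed, index))
            image, _ = render_sheet(t, curve, size=size, noise=sub)
            cr = cr_plane(image)
            images.append((float(t), image))
            points.append(
                CalibrationPoint(
                    temperature=float(t),
                    mean_cr=float(cr.mean()),
                    sd_cr=float(cr.std(ddof=1)) if cr.size > 1 else 0.0,
                    n_pixels=int(cr.size),
                )
            )
            index += 1
    return images, points


def points_to_frame(points: Sequence[CalibrationPoint]) -> pd.DataFrame:
    """Calibration points as a DataFrame in the points-CSV column layout."""
    return pd.DataFrame(
        [
            {
                "temperature_C": p.temperature,
                "mean_cr": p.mean_cr,
                "sd_cr": p.sd_cr,
                "n_pixels": p.n_pixels,
            }
            for p in points
        ]
    )
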