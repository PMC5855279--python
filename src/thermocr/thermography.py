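"""Maximum-temperature maps and the error / spatial-resolution trade-off.

Because the dye is irreversible, every temperature in these maps is the
**maximum** temperature the corresponding region attained, not a snapshot.

The mapping order is average-then-invert: Cr values are block-averaged first
and the tile mean is inverted through the calibration curve, matching the
calibration procedure (which averages Cr over a region before converting to
temperature).  The alternative invert-then-average order is exposed for
sensitivity analysis; the two agree only where the curve is locally linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .calibration import (
    STATUS_CODES,
    STATUS_LABELS,
    STATUS_CLAMPED_LOW,
    STATUS_CLAMPED_HIGH,
    STATUS_IN_RANGE,
    CrCalibration,
)
from .color import block_average, cr_plane

IN_RANGE = STATUS_CODES[STATUS_IN_RANGE]
CLAMPED_LOW = STATUS_CODES[STATUS_CLAMPED_LOW]
CLAMPED_HIGH = STATUS_CODES[STATUS_CLAMPED_HIGH]


@dataclass
class TemperatureMap:
    """Block-resolution grid of maximum-attained temperatures.

    values: H'xW' temperatures in °C (clamped cells hold t_min / t_max).
    mask: parallel int8 status grid (0 in_range, 1 clamped_low,
        2 clamped_high).  A clamped_low cell means only "<= t_min": the dye
        never activated there.
    window: averaging window in pixels (H' = ceil(H/window)).
    pixel_pitch: optional mm/pixel of the *source* image for physical
        annotation.
    """

    values: np.ndarray
    mask: np.ndarray
    window: int
    pixel_pitch: float | None = None
    t_min: float = field(default=float("nan"))
    t_max: float = field(default=float("nan"))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def status_labels(self) -> np.ndarray:
        """Mask as an array of status strings."""
        lut = np.array(
            [STATUS_LABELS[0], STATUS_LABELS[1], STATUS_LABELS[2]], dtype=object
        )
        return lut[self.mask]


class TemperatureMapper(TransformerMixin, BaseEstimator):
    """Image -> TemperatureMap transformer.

    Parameters
    ----------
    calibration : CrCalibration
        A fitted, monotone calibration curve.
    window : int, default 1
        Block-averaging window in pixels.
    order : {"average_then_invert", "invert_then_average"}
        Whether the tile mean of Cr is inverted (default, matching the
        calibration procedure) or per-pixel temperatures are averaged.
    pixel_pitch : float or None
        mm/pixel carried through to the output map.
    """

    def __init__(
        self,
        calibration: CrCalibration | None = None,
        window: int = 1,
        order: str = "average_then_invert",
        pixel_pitch: float | None = None,
    ):
        self.calibration = calibration
        self.window = window
        self.order = order
        self.pixel_pitch = pixel_pitch

    def fit(self, X=None, y=None):
        if self.calibration is None:
            raise ValueError("a fitted CrCalibration must be supplied")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.order not in ("average_then_invert", "invert_then_average"):
            raise ValueError(f"unknown order {self.order!r}")
        if not self.calibration.monotone_on(
            self.calibration.t_min_, self.calibration.t_max_
        ):
            raise ValueError("calibration curve is not monotone; cannot invert")
        self.n_features_in_ = 3
        return self

    def transform(self, image) -> TemperatureMap:
        self.fit()
        curve = self.calibration
        cr = cr_plane(image)
        if self.order == "average_then_invert":
            cr_cells = block_average(cr, self.window)
            values, mask = curve.invert_array(cr_cells)
        else:
            t_px, status_px = curve.invert_array(cr)
            values = block_average(t_px, self.window)
            # Cell status: in_range only if every contributing pixel was;
            # otherwise the majority clamp direction.
            low = block_average((status_px == CLAMPED_LOW).astype(float), self.window)
            high = block_average((status_px == CLAMPED_HIGH).astype(float), self.window)
            mask = np.zeros(values.shape, dtype=np.int8)
            clamped = (low + high) > 0
            mask[clamped & (low >= high)] = CLAMPED_LOW
            mask[clamped & (high > low)] = CLAMPED_HIGH
        return TemperatureMap(
            values=values,
            mask=mask,
            window=int(self.window),
            pixel_pitch=self.pixel_pitch,
            t_min=curve.t_min_,
            t_max=curve.t_max_,
        )


def temperature_map(
    image,
    curve: CrCalibration,
    window: int = 1,
    order: str = "average_then_invert",
    pixel_pitch: float | None = None,
) -> TemperatureMap:
    """Maximum-temperature map of an image at the given block resolution."""
    return TemperatureMapper(
        calibration=curve, window=window, order=order, pixel_pitch=pixel_pitch
    ).transform(image)


def resolution_curve(images, curve: CrCalibration, windows) -> pd.DataFrame:
    """Noise-vs-resolution table for replicate images at one temperature.

    For each window the Cr planes of all images are block-averaged and the
    cells pooled; the table reports the pooled standard deviation of the Cr
    cells and of the corresponding inverted temperatures.  For iid pixel
    noise of sd sigma, sd_cr falls as sigma/window — the quantitative form of
    the error/resolution trade-off.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    windows = sorted(int(w) for w in windows)
    cr_planes = [cr_plane(img) for img in images]
    rows = []
    for w in windows:
        cells = np.concatenate([block_average(p, w).ravel() for p in cr_planes])
        temps, _ = curve.invert_array(cells)
        rows.append(
            {
                "window": w,
                "sd_cr": float(np.std(cells, ddof=1)) if cells.size > 1 else 0.0,
                "sd_temperature": float(np.std(temps, ddof=1)) if temps.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["window", "sd_cr", "sd_temperature"])


def summarize(tmap: TemperatureMap) -> dict:
    """Deterministic summary of a temperature map.

    Keys: max/min/mean over in-range cells (None when no cell is in range),
    fractions clamped, and the hottest-cell coordinates.  The hottest cell is
    the row-major argmax over cells that are in range or clamped high; an
    all-clamped-low map has no hottest cell.
    """
    values, mask = tmap.values, tmap.mask
    in_range = mask == IN_RANGE
    n = values.size
    summary = {
        "n_cells": int(n),
        "window": tmap.window,
        "fraction_clamped": float(np.count_nonzero(mask != IN_RANGE) / n),
        "fraction_clamped_low": float(np.count_nonzero(mask == CLAMPED_LOW) / n),
        "fraction_clamped_high": float(np.count_nonzero(mask == CLAMPED_HIGH) / n),
    }
    if in_range.any():
        vals = values[in_range]
        summary["max_in_range"] = float(vals.max())
        summary["min_in_range"] = float(vals.min())
        summary["mean_in_range"] = float(vals.mean())
    else:
        summary["max_in_range"] = None
        summary["min_in_range"] = None
        summary["mean_in_range"] = None
    eligible = mask != CLAMPED_LOW
    if eligible.any():
        masked = np.where(eligible, values, -np.inf)
        idx = np.unravel_index(int(np.argmax(masked)), values.shape)
        summary["hottest_cell"] = (int(idx[0]), int(idx[1]))
        summary["hottest_temperature"] = float(values[idx])
    else:
        summary["hottest_cell"] = None
        summary["hottest_temperature"] = None
    return summary
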