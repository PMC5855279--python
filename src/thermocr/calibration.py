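"""Temperature -> Cr calibration: fit, evaluate, invert, error tables.

The calibration model is an ordinary least-squares polynomial (cubic by
default) mapping heating temperature T (°C) to the mean Cr value of a heated
sheet sample.  Because the dye's color change is irreversible, inverting a
monotone calibration curve at a measured Cr recovers the **maximum**
temperature the material attained.

Cr values below the curve's value at the calibration floor carry no
information (the dye has simply not switched): inversion clamps to the
validity range and reports a status instead of extrapolating the cubic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, RegressorMixin

SCHEMA_VERSION = 1

# Inversion statuses.  String names are the public scalar API; the integer
# codes are used in status grids (see thermography.TemperatureMap.mask).
STATUS_IN_RANGE = "in_range"
STATUS_CLAMPED_LOW = "clamped_low"
STATUS_CLAMPED_HIGH = "clamped_high"
STATUS_CODES = {STATUS_IN_RANGE: 0, STATUS_CLAMPED_LOW: 1, STATUS_CLAMPED_HIGH: 2}
STATUS_LABELS = {v: k for k, v in STATUS_CODES.items()}

#: CSV header for calibration-point tables.
POINTS_CSV_COLUMNS = ["temperature_C", "mean_cr", "sd_cr", "n_pixels"]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: mean Cr over a stated region at a known T."""

    temperature: float
    mean_cr: float
    sd_cr: float = 0.0
    n_pixels: int = 1

    def __post_init__(self):
        if not np.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if self.sd_cr < 0:
            raise ValueError("sd_cr must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


class CrCalibration(RegressorMixin, BaseEstimator):
    """Polynomial temperature -> Cr calibration curve.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree.  The cubic default matches the standard
        calibration of the magenta irreversible dye / PDMS composite.

    Attributes (after :meth:`fit`)
    ------------------------------
    coefficients_ : ndarray, shape (degree + 1,)
        Ascending-order coefficients (a0, a1, ..., a_degree) of
        ``Cr = a0 + a1*T + ... + a_degree*T**degree``.
    t_min_, t_max_ : float
        Validity range (extreme calibration temperatures).
    monotone_ : bool
        Whether the derivative keeps one sign on [t_min_, t_max_].
    residuals_ : ndarray
        Per-point fit residuals ``mean_cr - predict(T)`` in Cr units.

    Notes
    -----
    The fit is unweighted ordinary least squares: per-point ``sd_cr`` is
    stored for reporting but does not enter the fit.  The fit is performed on
    a scaled domain and converted back to raw-power coefficients, which keeps
    the leading coefficient accurate to ~1e-12 relative even though raw
    T, T², T³ regressors are badly conditioned over 40-100 °C.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    # ------------------------------------------------------------------ fit

    def fit(self, temperatures, mean_cr=None, sd_cr=None, n_pixels=None):
        """Fit the curve.

        ``temperatures`` may be a sequence of :class:`CalibrationPoint`
        (with ``mean_cr=None``) or an array of temperatures paired with an
        array of mean Cr values.
        """
        if mean_cr is None:
            points = list(temperatures)
            if not points:
                raise ValueError("no calibration points")
            t = np.array([p.temperature for p in points], dtype=float)
            cr = np.array([p.mean_cr for p in points], dtype=float)
            sd = np.array([p.sd_cr for p in points], dtype=float)
            npx = np.array([p.n_pixels for p in points], dtype=int)
        else:
            t = np.asarray(temperatures, dtype=float).ravel()
            cr = np.asarray(mean_cr, dtype=float).ravel()
            sd = None if sd_cr is None else np.asarray(sd_cr, dtype=float).ravel()
            npx = None if n_pixels is None else np.asarray(n_pixels, dtype=int).ravel()
        if t.shape != cr.shape:
            raise ValueError("temperatures and mean_cr must have the same length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(cr))):
            raise ValueError("non-finite calibration data")
        n_distinct = np.unique(t).size
        if n_distinct < self.degree + 1:
            raise ValueError(
                f"need at least {self.degree + 1} distinct temperatures for a "
                f"degree-{self.degree} fit, got {n_distinct}"
            )
        poly = Polynomial.fit(t, cr, deg=self.degree).convert()
        coeffs = np.zeros(self.degree + 1)
        coeffs[: len(poly.coef)] = poly.coef
        self.coefficients_ = coeffs
        self.t_min_ = float(t.min())
        self.t_max_ = float(t.max())
        self.residuals_ = cr - self._poly(t)
        self.monotone_ = self.monotone_on(self.t_min_, self.t_max_)
        self.points_ = pd.DataFrame(
            {
                "temperature_C": t,
                "mean_cr": cr,
                "sd_cr": np.zeros_like(t) if sd is None else sd,
                "n_pixels": np.ones(t.size, dtype=int) if npx is None else npx,
            }
        )
        return self

    @classmethod
    def from_coefficients(
        cls, coefficients: Sequence[float], t_min: float, t_max: float
    ) -> "CrCalibration":
        """Build a pre-fitted curve from ascending-order coefficients."""
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.ndim != 1 or coefficients.size < 2:
            raise ValueError("coefficients must be a 1-D array of length >= 2")
        if not t_min < t_max:
            raise ValueError("t_min must be < t_max")
        curve = cls(degree=coefficients.size - 1)
        curve.coefficients_ = coefficients.copy()
        curve.t_min_ = float(t_min)
        curve.t_max_ = float(t_max)
        curve.residuals_ = np.zeros(0)
        curve.monotone_ = curve.monotone_on(t_min, t_max)
        curve.points_ = None
        return curve

    # ----------------------------------------------------------- evaluation

    def _check_fitted(self):
        if not hasattr(self, "coefficients_"):
            raise AttributeError("calibration curve is not fitted")

    def _poly(self, t):
        # Horner evaluation in ascending-coefficient convention.
        c = self.coefficients_
        result = np.full_like(np.asarray(t, dtype=float), c[-1])
        for a in c[-2::-1]:
            result = result * t + a
        return result

    def predict(self, T):
        """Predicted Cr at temperature(s) T (sklearn regressor surface)."""
        self._check_fitted()
        T = np.asarray(T, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:  # sklearn-style column vector
            return self._poly(T[:, 0])
        return self._poly(T)

    def evaluate(self, t):
        """Cr at temperature t, plus an out-of-range flag.

        Returns ``(cr, out_of_range)``; scalars in, scalars out.
        """
        self._check_fitted()
        t_arr = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t_arr)):
            raise ValueError("non-finite temperature")
        cr = self._poly(t_arr)
        out = (t_arr < self.t_min_) | (t_arr > self.t_max_)
        if t_arr.ndim == 0:
            return float(cr), bool(out)
        return cr, out

    def derivative_coefficients(self) -> np.ndarray:
        self._check_fitted()
        c = self.coefficients_
        return c[1:] * np.arange(1, c.size)

    def monotone_on(self, t_lo: float, t_hi: float) -> bool:
        """True iff the derivative keeps one (nonzero) sign on [t_lo, t_hi].

        Determined analytically from the real roots of the derivative
        polynomial; a derivative that is identically zero (constant curve) is
        not monotone for inversion purposes.
        """
        if not t_lo < t_hi:
            raise ValueError("t_lo must be < t_hi")
        d = self.derivative_coefficients()
        if not np.any(d):
            return False
        roots = Polynomial(d).roots()
        real = np.sort(
            [r.real for r in roots if abs(r.imag) < 1e-9 and t_lo < r.real < t_hi]
        )
        # Sign of the derivative on each subinterval between interior roots.
        knots = np.concatenate([[t_lo], real, [t_hi]])
        mids = 0.5 * (knots[:-1] + knots[1:])
        dpoly = Polynomial(d)
        signs = np.sign(dpoly(mids))
        signs = signs[signs != 0]
        if signs.size == 0:
            return False
        return bool(np.all(signs == signs[0]))

    # ------------------------------------------------------------ inversion

    def _range_cr(self):
        lo, _ = self.evaluate(self.t_min_)
        hi, _ = self.evaluate(self.t_max_)
        return lo, hi

    def invert(self, cr: float):
        """Temperature whose Cr equals ``cr``, by bracketed root finding.

        Returns ``(t, status)`` where status is ``in_range``, ``clamped_low``
        (Cr at or beyond the curve value at t_min -> t_min returned) or
        ``clamped_high``.  Requires a monotone curve.
        """
        self._check_fitted()
        if not self.monotone_on(self.t_min_, self.t_max_):
            raise ValueError(
                "calibration curve is not monotone on "
                f"[{self.t_min_}, {self.t_max_}]; it cannot be inverted"
            )
        cr = float(cr)
        cr_at_tmin, cr_at_tmax = self._range_cr()
        increasing = cr_at_tmax > cr_at_tmin
        lo, hi = sorted((cr_at_tmin, cr_at_tmax))
        if cr <= lo:
            t = self.t_min_ if increasing else self.t_max_
            return t, (STATUS_CLAMPED_LOW if increasing else STATUS_CLAMPED_HIGH)
        if cr >= hi:
            t = self.t_max_ if increasing else self.t_min_
            return t, (STATUS_CLAMPED_HIGH if increasing else STATUS_CLAMPED_LOW)
        t = brentq(
            lambda x: self._poly(x) - cr,
            self.t_min_,
            self.t_max_,
            xtol=1e-9,
            rtol=4 * np.finfo(float).eps,
        )
        return float(t), STATUS_IN_RANGE

    def invert_array(self, cr):
        """Vectorized inversion of a Cr array.

        Returns ``(t, status_codes)`` with integer codes per
        :data:`STATUS_CODES`.  Uses a dense monotone lookup grid followed by
        Newton polish, which agrees with the scalar bracketed inversion to
        well below 1e-6 °C.
        """
        self._check_fitted()
        if not self.monotone_on(self.t_min_, self.t_max_):
            raise ValueError("calibration curve is not monotone; cannot invert")
        cr = np.asarray(cr, dtype=float)
        cr_at_tmin, cr_at_tmax = self._range_cr()
        increasing = cr_at_tmax > cr_at_tmin
        lo, hi = sorted((cr_at_tmin, cr_at_tmax))

        grid_t = np.linspace(self.t_min_, self.t_max_, 4097)
        grid_cr = self._poly(grid_t)
        if not increasing:
            grid_cr = grid_cr[::-1]
            grid_t = grid_t[::-1]
        clipped = np.clip(cr, lo, hi)
        t = np.interp(clipped, grid_cr, grid_t)
        # Newton polish (derivative is bounded away from 0 on a monotone range
        # except possibly at isolated points; guard the step).
        dcoef = self.derivative_coefficients()
        dpoly = Polynomial(dcoef)
        for _ in range(3):
            slope = dpoly(t)
            step = np.where(np.abs(slope) > 1e-12, (self._poly(t) - clipped), 0.0)
            t = t - np.where(np.abs(slope) > 1e-12, step / np.where(slope == 0, 1, slope), 0.0)
            t = np.clip(t, self.t_min_, self.t_max_)

        status = np.zeros(cr.shape, dtype=np.int8)
        below, above = cr <= lo, cr >= hi
        if increasing:
            status[below] = STATUS_CODES[STATUS_CLAMPED_LOW]
            status[above] = STATUS_CODES[STATUS_CLAMPED_HIGH]
            t = np.where(below, self.t_min_, np.where(above, self.t_max_, t))
        else:
            status[below] = STATUS_CODES[STATUS_CLAMPED_HIGH]
            status[above] = STATUS_CODES[STATUS_CLAMPED_LOW]
            t = np.where(below, self.t_max_, np.where(above, self.t_min_, t))
        return t, status

    # -------------------------------------------------------- serialization

    def to_dict(self, provenance: dict | None = None) -> dict:
        self._check_fitted()
        return {
            "schema_version": SCHEMA_VERSION,
            "coefficients": list(self.coefficients_),
            "coefficient_order": "ascending (a0, a1, ..., an): Cr = sum a_k * T**k",
            "t_min": self.t_min_,
            "t_max": self.t_max_,
            "monotone": bool(self.monotone_),
            "residuals": list(np.asarray(self.residuals_, dtype=float)),
            "provenance": provenance or {},
        }

    def save(self, path, provenance: dict | None = None, timestamp: bool = True):
        d = self.to_dict(provenance=provenance)
        if timestamp:
            d["provenance"].setdefault(
                "created", datetime.now(timezone.utc).isoformat()
            )
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "CrCalibration":
        d = json.loads(Path(path).read_text())
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported calibration schema_version {d.get('schema_version')!r}"
            )
        curve = cls.from_coefficients(d["coefficients"], d["t_min"], d["t_max"])
        curve.residuals_ = np.asarray(d.get("residuals", []), dtype=float)
        return curve


def reference_curve() -> CrCalibration:
    """The published cubic calibration of the magenta irreversible dye/PDMS
    composite, valid on 40-100 °C:

        Cr = 5.43e-5 T^3 - 7.11e-3 T^2 + 3.16e-1 T - 11.0
    """
    return CrCalibration.from_coefficients(
        [-11.0, 3.16e-1, -7.11e-3, 5.43e-5], t_min=40.0, t_max=100.0
    )


# --------------------------------------------------------------------------
# Thin functional wrappers over the estimator, and CSV / table helpers.


def fit_curve(points: Sequence[CalibrationPoint], degree: int = 3) -> CrCalibration:
    """Ordinary least-squares polynomial fit of (temperature, mean_cr) points."""
    return CrCalibration(degree=degree).fit(points)


def evaluate(curve: CrCalibration, t):
    """Cr value of the curve at temperature t; returns (cr, out_of_range)."""
    return curve.evaluate(t)


def monotone_on(curve: CrCalibration, t_lo: float, t_hi: float) -> bool:
    return curve.monotone_on(t_lo, t_hi)


def invert(curve: CrCalibration, cr: float):
    """Invert the curve at a Cr value; returns (temperature, status)."""
    return curve.invert(cr)


def error_table(curve: CrCalibration, points: Sequence[CalibrationPoint]) -> pd.DataFrame:
    """Per-point measurement errors of the inverted calibration.

    Columns: true_temperature_C, estimated_temperature_C, error_C
    (estimated - true), status.  Empty input yields an empty table.
    """
    rows = []
    for p in points:
        t_est, status = curve.invert(p.mean_cr)
        rows.append(
            {
                "true_temperature_C": p.temperature,
                "estimated_temperature_C": t_est,
                "error_C": t_est - p.temperature,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["true_temperature_C", "estimated_temperature_C", "error_C", "status"],
    )


def max_abs_error(table: pd.DataFrame) -> float:
    """Maximum |error| of an error table (NaN for an empty table)."""
    if table.empty:
        return float("nan")
    return float(table["error_C"].abs().max())


def write_points_csv(points: Sequence[CalibrationPoint], path) -> None:
    df = pd.DataFrame(
        [
            {
                "temperature_C": p.temperature,
                "mean_cr": p.mean_cr,
                "sd_cr": p.sd_cr,
                "n_pixels": p.n_pixels,
            }
            for p in points
        ],
        columns=POINTS_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_points_csv(path) -> list[CalibrationPoint]:
    df = pd.read_csv(path)
    missing = set(POINTS_CSV_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"points CSV missing columns: {sorted(missing)}")
    if "sd_cr" not in df:
        df["sd_cr"] = 0.0
    if "n_pixels" not in df:
        df["n_pixels"] = 1
    return [
        CalibrationPoint(
            temperature=float(row.temperature_C),
            mean_cr=float(row.mean_cr),
            sd_cr=float(row.sd_cr),
            n_pixels=int(row.n_pixels),
        )
        for row in df.itertuples()
    ]
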