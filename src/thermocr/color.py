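"""RGB <-> YCrCb color transform and Cr-plane utilities.

The temperature-sensitive color coordinate is Cr, the red color difference of
the YCrCb space, computed directly on the 0-255 RGB scale with **no** +128
chroma offset and no gamma handling.  The Cr coefficient row sums to zero, so
Cr is invariant under additive illumination offsets applied equally to all
three channels — the reason this coordinate is used for calibration in the
first place.

All arithmetic is double precision; quantization to 8 bits happens only when
an image file is written (see :mod:`thermocr.io`).
"""

from __future__ import annotations

import operator

import numpy as np

#: Forward transform matrix, rows (Y, Cr, Cb), columns (R, G, B).
RGB_TO_YCRCB = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.5000, -0.419, -0.081],
        [-0.169, -0.331, 0.500],
    ]
)

#: Inverse transform, computed once at import.
YCRCB_TO_RGB = np.linalg.inv(RGB_TO_YCRCB)

#: Extremes of the Cr linear form over the 8-bit RGB cube.
CR_MIN = -127.5
CR_MAX = 127.5


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite value in color-transform input")


def rgb_to_ycrcb(r, g, b):
    """Convert RGB intensities (0-255 scale) to (Y, Cr, Cb).

    Accepts scalars or broadcastable arrays.  Values outside 0-255 are
    permitted (synthetic round trips need them); non-finite values are not.

    Returns
    -------
    (y, cr, cb) : float or ndarray
        Brightness, red color difference, blue color difference.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(r, g, b)
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cr = 0.5000 * r - 0.419 * g - 0.081 * b
    cb = -0.169 * r - 0.331 * g + 0.500 * b
    if y.ndim == 0:
        return float(y), float(cr), float(cb)
    return y, cr, cb


def ycrcb_to_rgb(y, cr, cb):
    """Invert the color transform.

    Returns
    -------
    (r, g, b, in_gamut)
        The unique RGB preimage, and a flag (scalar bool or bool array) that
        is true where all three channels lie in [0, 255].  Out-of-gamut is
        reported, never raised.
    """
    y = np.asarray(y, dtype=float)
    cr = np.asarray(cr, dtype=float)
    cb = np.asarray(cb, dtype=float)
    _check_finite(y, cr, cb)
    stacked = np.stack(np.broadcast_arrays(y, cr, cb), axis=-1)
    rgb = stacked @ YCRCB_TO_RGB.T
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    # tolerance absorbs round-off for pixels exactly on the cube boundary
    in_gamut = np.all((rgb >= -1e-9) & (rgb <= 255.0 + 1e-9), axis=-1)
    if r.ndim == 0:
        return float(r), float(g), float(b), bool(in_gamut)
    return r, g, b, in_gamut


def cr_plane(image) -> np.ndarray:
    """Extract the H x W Cr plane of an H x W x 3 RGB image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("empty image")
    _check_finite(image)
    return image @ RGB_TO_YCRCB[1]


def block_average(values, window: int) -> np.ndarray:
    """Average non-overlapping ``window x window`` tiles of a 2-D map.

    Trailing partial tiles at the right/bottom edges are averaged over the
    pixels they actually contain, so the output shape is
    ``(ceil(H/window), ceil(W/window))`` and no pixel is discarded.
    ``window=1`` is the identity; a window larger than both dimensions yields
    a single cell.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {values.shape}")
    if values.size == 0:
        raise ValueError("empty map")
    w = operator.index(window)
    if w < 1:
        raise ValueError(f"window must be >= 1, got {w}")
    if w == 1:
        return values.copy()
    h, width = values.shape
    row_idx = np.arange(0, h, w)
    col_idx = np.arange(0, width, w)
    sums = np.add.reduceat(np.add.reduceat(values, row_idx, axis=0), col_idx, axis=1)
    row_counts = np.minimum(row_idx + w, h) - row_idx
    col_counts = np.minimum(col_idx + w, width) - col_idx
    return sums / np.outer(row_counts, col_counts)
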