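"""File I/O: 8-bit PNG/TIFF images, temperature-map CSV pairs, rendered maps.

Images are held in memory as double-precision arrays on the 0-255 scale;
quantization to 8 bits happens only here, on write.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import STATUS_CODES
from .thermography import CLAMPED_LOW, TemperatureMap

_SUPPORTED = {".png", ".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB PNG/TIFF as a float HxWx3 array (0-255 scale).

    Alpha channels and non-8-bit data are rejected: the calibration is
    defined on plain 8-bit camera output.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format {path.suffix!r} (PNG/TIFF only)")
    data = iio.imread(path)
    if data.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image data, got dtype {data.dtype}")
    if data.ndim != 3 or data.shape[-1] != 3:
        if data.ndim == 3 and data.shape[-1] == 4:
            raise ValueError("image has an alpha channel; flatten it before use")
        raise ValueError(f"expected an HxWx3 RGB image, got shape {data.shape}")
    return data.astype(float)


def write_image(path, image: np.ndarray) -> None:
    """Quantize a float image (0-255 scale) to 8 bits and write PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format {path.suffix!r} (PNG/TIFF only)")
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    quantized = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    iio.imwrite(path, quantized)


def write_temperature_map(tmap: TemperatureMap, values_path, status_path) -> None:
    """Write a map as a numeric grid CSV plus a parallel status-label CSV."""
    pd.DataFrame(tmap.values).to_csv(values_path, index=False, header=False)
    pd.DataFrame(tmap.status_labels()).to_csv(status_path, index=False, header=False)


def read_temperature_map(
    values_path, status_path, window: int, t_min: float = float("nan"),
    t_max: float = float("nan"),
) -> TemperatureMap:
    values = pd.read_csv(values_path, header=None).to_numpy(dtype=float)
    labels = pd.read_csv(status_path, header=None).to_numpy(dtype=object)
    mask = np.vectorize(STATUS_CODES.__getitem__)(labels).astype(np.int8)
    return TemperatureMap(
        values=values, mask=mask, window=window, t_min=t_min, t_max=t_max
    )


def render_map_png(tmap: TemperatureMap, path, cmap: str = "inferno") -> None:
    """Render a temperature map to PNG with a color bar.

    The color ramp is a fixed mapping of [t_min, t_max] so regenerated
    figures are stable given identical inputs; clamped-low cells ("<= t_min",
    dye never activated) are drawn in neutral gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    masked = np.ma.masked_where(tmap.mask == CLAMPED_LOW, tmap.values)
    colormap = plt.get_cmap(cmap).copy()
    colormap.set_bad("0.7")
    fig, ax = plt.subplots(figsize=(6, 4.5), dpi=120)
    im = ax.imshow(
        masked, cmap=colormap, vmin=tmap.t_min, vmax=tmap.t_max,
        interpolation="nearest",
    )
    label = "Maximum temperature (°C)"
    fig.colorbar(im, ax=ax, label=label)
    title = f"window = {tmap.window} px"
    if tmap.pixel_pitch:
        title += f" ({tmap.window * tmap.pixel_pitch:.2f} mm)"
    ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
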