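"""Assemble three saturation fields into one RGB raster.

Each channel of a pixel carries one variable's saturation, so a pixel's hue
encodes the ratio of the three variables and its brightness their overall
magnitude: white = all three at maximum, black = all depleted, pure red =
only the red-channel variable present.  The raster keeps float saturations
plus a validity mask; :func:`quantize` produces the 8-bit image.

Quantization rounds half away from zero (``floor(255*s + 0.5)``), so a
saturation of exactly 0.5 maps to 128.  This rule is fixed to make golden
image comparisons bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CoRegistrationError, DataError
from .transform import SaturationField

#: Default render color for invalid pixels (land / sea floor / outside the
#: sample hull): light gray, distinguishable from both black and white data.
DEFAULT_FILL = (0.85, 0.85, 0.85)


@dataclass
class RGBRaster:
    """Composed image: per-pixel (r, g, b) saturations in [0, 1] + mask."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    mask: np.ndarray
    fill_color: tuple[float, float, float] = DEFAULT_FILL
    x_axis: np.ndarray | None = None
    y_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {self.r.shape, self.g.shape, self.b.shape, self.mask.shape}
        if len(shapes) != 1:
            raise DataError(f"channel/mask shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


def compose(
    red: SaturationField,
    green: SaturationField,
    blue: SaturationField,
    fill_color: tuple[float, float, float] = DEFAULT_FILL,
    lenient: bool = False,
) -> RGBRaster:
    """Stack three co-registered saturation fields into an RGB raster.

    The output mask is the AND of the three input masks: a pixel missing any
    channel is invalid (``lenient=True`` instead treats a missing channel as
    zero saturation and keeps the pixel — off by default because it
    fabricates color from absent data).
    """
    fields = (red, green, blue)
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise CoRegistrationError(f"fields not co-registered: shapes {shapes}")
    for a, b_ in ((red, green), (red, blue)):
        for axis in ("x_axis", "y_axis"):
            ax_a, ax_b = getattr(a, axis), getattr(b_, axis)
            if ax_a is not None and ax_b is not None and not np.array_equal(ax_a, ax_b):
                raise CoRegistrationError(f"fields not co-registered: {axis} differs")
    if lenient:
        mask = red.mask | green.mask | blue.mask
        chans = [np.where(f.mask, f.values, 0.0) for f in fields]
    else:
        mask = red.mask & green.mask & blue.mask
        chans = [f.values.copy() for f in fields]
    for c in chans:
        c[~mask] = 0.0
    return RGBRaster(
        r=chans[0],
        g=chans[1],
        b=chans[2],
        mask=mask,
        fill_color=fill_color,
        x_axis=None if red.x_axis is None else red.x_axis.copy(),
        y_axis=None if red.y_axis is None else red.y_axis.copy(),
    )


def quantize(raster: RGBRaster) -> np.ndarray:
    """8-bit image array, shape (ny, nx, 3), dtype uint8.

    Valid pixels: ``floor(255*s + 0.5)`` per channel (round half away from
    zero; quantization error <= 0.5/255).  Invalid pixels take the raster's
    fill color, quantized the same way.
    """
    out = np.empty(raster.shape + (3,), dtype=np.uint8)
    for k, chan in enumerate((raster.r, raster.g, raster.b)):
        q = np.floor(np.clip(chan, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        fill = np.uint8(np.floor(np.clip(raster.fill_color[k], 0.0, 1.0) * 255.0 + 0.5))
        out[..., k] = np.where(raster.mask, q, fill)
    return out


def dequantize(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map an 8-bit (ny, nx, 3) image back to float channels in [0, 1]."""
    img = np.asarray(image, dtype=float) / 255.0
    return img[..., 0], img[..., 1], img[..., 2]
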