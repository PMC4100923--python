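"""Physical concentration <-> color saturation transforms.

For a resolved channel spec with bounds ``[c_min, c_max]`` and exponent
``gamma`` in (0, 1]::

    s = ((c - c_min) / (c_max - c_min)) ** gamma

Nutrient mode uses ``c_min = 0`` and ``gamma = 0.5`` (square root), which
stretches low concentrations and so gives a more detailed view of the
nutrient-depleted photic zone; count mode uses the observed range with
``gamma = 1.0``.  The inverse,

    c = c_min + (c_max - c_min) * s ** (1 / gamma)

is exact on ``[c_min, c_max]`` and drives legend tick labels and the
color -> concentration lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, UsageError
from .fields import ChannelSpec, GriddedField


@dataclass
class SaturationField:
    """A field mapped to [0, 1] saturations, carrying the spec that made it.

    ``x_axis``/``y_axis`` are copied from the source field so downstream
    composition can check co-registration.
    """

    values: np.ndarray
    mask: np.ndarray
    spec: ChannelSpec
    x_axis: np.ndarray | None = None
    y_axis: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def to_saturation(field: GriddedField, spec: ChannelSpec) -> SaturationField:
    """Map a physical field to saturations in [0, 1].

    Requires a resolved spec (numeric ``c_min < c_max``).  Values outside
    the stated bounds clip to 0 or 1 — possible only with user-stated
    bounds, since derived bounds span the data.  The mask propagates
    unchanged.
    """
    if not spec.is_resolved:
        raise UsageError(
            f"channel '{spec.channel}': spec not resolved (c_min/c_max still 'derive')"
        )
    vals = field.values
    if not np.all(np.isfinite(vals[field.mask])):
        raise DataError(f"field '{field.name}': non-finite valid values")
    c_min, c_max = float(spec.c_min), float(spec.c_max)
    with np.errstate(invalid="ignore"):
        norm = (vals - c_min) / (c_max - c_min)
        norm = np.clip(norm, 0.0, 1.0)
        sat = np.power(norm, spec.gamma)
    sat = np.where(field.mask, sat, 0.0)
    return SaturationField(
        values=sat,
        mask=field.mask.copy(),
        spec=spec,
        x_axis=field.x_axis.copy(),
        y_axis=field.y_axis.copy(),
    )


def from_saturation(s, spec: ChannelSpec):
    """Invert :func:`to_saturation`: saturation(s) -> physical concentration.

    Accepts a scalar or array in [0, 1]; returns the same shape.
    """
    if not spec.is_resolved:
        raise UsageError(
            f"channel '{spec.channel}': spec not resolved (c_min/c_max still 'derive')"
        )
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0) | (s_arr > 1) | ~np.isfinite(s_arr)):
        raise UsageError("saturation outside [0, 1]")
    c_min, c_max = float(spec.c_min), float(spec.c_max)
    c = c_min + (c_max - c_min) * np.power(s_arr, 1.0 / spec.gamma)
    return float(c) if np.isscalar(s) or s_arr.ndim == 0 else c
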