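"""Core domain types: gridded fields, scattered sample tables, channel specs.

A :class:`GriddedField` holds one physical scalar (a nutrient concentration
in µmol/L, or an interpolated cell concentration in cells/mL) on a regular
2-D grid whose axes are distance-along-transect (km) or time (days) on X and
depth (m, positive downward, stored increasing) on Y.  Rendering flips the Y
axis so the surface appears at the top.

A :class:`ChannelSpec` binds one such field to one RGB channel and records
how it is normalized to a saturation in [0, 1]:

* ``zero_to_max`` — nutrient mode: assume a minimal concentration of zero
  and divide by the channel maximum (default gamma 0.5, i.e. square root,
  which boosts contrast in the nutrient-depleted photic zone);
* ``min_to_max`` — count mode: scale the observed range onto [0, 1]
  (default gamma 1.0, linear).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Union

import numpy as np

from .exceptions import DataError, DegenerateRangeError, EmptyFieldError, UsageError

Channel = Literal["red", "green", "blue"]
NormPolicy = Literal["zero_to_max", "min_to_max"]

#: Sentinel for a bound that must be derived from the data.
DERIVE = "derive"


@dataclass
class GriddedField:
    """A 2-D scalar field with coordinate axes and a validity mask.

    Parameters
    ----------
    values
        2-D array, shape ``(len(y_axis), len(x_axis))``, physical units.
    x_axis, y_axis
        Strictly increasing 1-D coordinate vectors.  ``y_axis`` is depth in
        metres, positive downward.
    units, name
        Metadata carried through to legends and output files.
    mask
        Boolean array, same shape as ``values``; ``True`` marks valid cells.
        Defaults to all-valid.  Non-finite values are masked automatically.
    """

    values: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    units: str = ""
    name: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"field '{self.name}': values must be 2-D")
        if self.values.shape != (self.y_axis.size, self.x_axis.size):
            raise DataError(
                f"field '{self.name}': shape {self.values.shape} does not match "
                f"axes ({self.y_axis.size}, {self.x_axis.size})"
            )
        for ax_name, ax in (("x_axis", self.x_axis), ("y_axis", self.y_axis)):
            if ax.ndim != 1 or ax.size < 1:
                raise DataError(f"field '{self.name}': {ax_name} must be 1-D")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise DataError(f"field '{self.name}': {ax_name} not strictly increasing")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError(f"field '{self.name}': mask shape mismatch")
        # non-finite cells can never be valid
        self.mask = self.mask & np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """Values at valid cells, as a flat array."""
        return self.values[self.mask]

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.x_axis, other.x_axis)
            and np.array_equal(self.y_axis, other.y_axis)
        )


@dataclass
class SampleTable:
    """Scattered observations ``(t, z, value)`` for one taxon/channel.

    ``t`` is time in fractional days since ``t_origin`` (an ISO date string,
    or None when times were already numeric); ``z`` is depth in metres.
    Values are non-negative concentrations.
    """

    t: np.ndarray
    z: np.ndarray
    value: np.ndarray
    taxon: str = ""
    units: str = ""
    t_origin: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not (self.t.shape == self.z.shape == self.value.shape) or self.t.ndim != 1:
            raise DataError(f"samples '{self.taxon}': t, z, value must be equal-length 1-D")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.z)):
            raise DataError(f"samples '{self.taxon}': non-finite coordinates")
        if np.any(self.value < 0):
            raise DataError(f"samples '{self.taxon}': negative concentrations")

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_records(
        cls,
        t,
        z,
        value,
        taxon: str = "",
        units: str = "",
        t_origin: str | None = None,
        on_duplicate: Literal["error", "mean"] = "error",
    ) -> "SampleTable":
        """Build a table, resolving duplicate ``(t, z)`` positions.

        Duplicates are an error by default; ``on_duplicate='mean'`` averages
        the values observed at each repeated position.
        """
        t = np.asarray(t, dtype=float)
        z = np.asarray(z, dtype=float)
        value = np.asarray(value, dtype=float)
        pts = np.column_stack([t, z])
        uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            if on_duplicate == "error":
                dup = uniq[counts > 1][0]
                raise DataError(
                    f"samples '{taxon}': duplicate (t, z) pair ({dup[0]:g}, {dup[1]:g})"
                )
            sums = np.zeros(uniq.shape[0])
            np.add.at(sums, inverse, value)
            value = sums / counts
            t, z = uniq[:, 0], uniq[:, 1]
        return cls(t=t, z=z, value=value, taxon=taxon, units=units, t_origin=t_origin)


@dataclass(frozen=True)
class ChannelSpec:
    """Binding of one field to one color channel.

    ``c_min``/``c_max`` may be the string ``"derive"`` (resolved from data by
    :func:`derive_stats`) or stated numbers, in which case out-of-range
    concentrations clip to the saturation bounds.
    """

    channel: Channel
    source_name: str = ""
    norm_policy: NormPolicy = "zero_to_max"
    gamma: float = 0.5
    c_min: Union[float, str] = DERIVE
    c_max: Union[float, str] = DERIVE
    units: str = ""

    def __post_init__(self) -> None:
        if self.channel not in ("red", "green", "blue"):
            raise UsageError(f"unknown channel '{self.channel}'")
        if self.norm_policy not in ("zero_to_max", "min_to_max"):
            raise UsageError(f"unknown norm policy '{self.norm_policy}'")
        if not (0.0 < self.gamma <= 1.0):
            raise UsageError(f"gamma must be in (0, 1], got {self.gamma}")
        for bound in (self.c_min, self.c_max):
            if isinstance(bound, str) and bound != DERIVE:
                raise UsageError(f"bound must be a number or 'derive', got {bound!r}")
        if self.is_resolved and not (float(self.c_min) < float(self.c_max)):
            raise UsageError(
                f"channel '{self.channel}': c_min ({self.c_min}) must be < c_max ({self.c_max})"
            )

    @property
    def is_resolved(self) -> bool:
        return not isinstance(self.c_min, str) and not isinstance(self.c_max, str)

    def resolve(self, field: GriddedField) -> "ChannelSpec":
        """Return a spec with concrete bounds derived from ``field``."""
        c_min, c_max = derive_stats(field, self)
        return replace(self, c_min=c_min, c_max=c_max)


def derive_stats(field: GriddedField, spec: ChannelSpec) -> tuple[float, float]:
    """Resolve the normalization bounds for ``field`` under ``spec``.

    Under ``zero_to_max`` the minimum is exactly 0 regardless of the data;
    the maximum (when not stated) is the maximum over valid cells.  Under
    ``min_to_max`` both bounds come from the valid-cell range.  Stated
    numeric bounds pass through unchanged.  Masked cells never influence
    the result.
    """
    vals = field.valid_values()
    if vals.size == 0:
        raise EmptyFieldError(f"empty field '{field.name}'")
    if isinstance(spec.c_max, str):
        c_max = float(vals.max())
    else:
        c_max = float(spec.c_max)
    if isinstance(spec.c_min, str):
        c_min = 0.0 if spec.norm_policy == "zero_to_max" else float(vals.min())
    else:
        c_min = float(spec.c_min)
    if c_min >= c_max:
        raise DegenerateRangeError(
            f"degenerate range for field '{field.name}': c_min={c_min:g}, c_max={c_max:g}"
        )
    return c_min, c_max
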