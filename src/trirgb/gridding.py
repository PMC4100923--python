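"""Scattered (t, z, value) samples -> regular Cartesian grid.

Sampled vertical profiles arrive at irregular times and depths; before they
can be composed into an RGB raster they are linearly interpolated onto a
regular time x depth grid.  Interpolation is piecewise linear on a Delaunay
triangulation of the sample points (scipy/Qhull); grid nodes outside the
convex hull of the samples have no data support and are masked invalid
(optionally filled with the nearest sample value instead).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .exceptions import DataError, TriangulationError, UsageError
from .fields import GriddedField, SampleTable


def make_grid(
    samples: SampleTable,
    nx: int,
    ny: int,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build evenly spaced axes spanning the samples (or stated bounds).

    ``bounds`` is ``(t_min, t_max, z_min, z_max)``; when omitted the sample
    bounding box is used.  Returns ``(x_axis, y_axis)``.
    """
    if nx < 2 or ny < 2:
        raise UsageError(f"grid must be at least 2x2, got {nx}x{ny}")
    if len(samples) == 0:
        raise DataError("no samples")
    if bounds is None:
        t_min, t_max = float(samples.t.min()), float(samples.t.max())
        z_min, z_max = float(samples.z.min()), float(samples.z.max())
    else:
        t_min, t_max, z_min, z_max = map(float, bounds)
    if t_min >= t_max or z_min >= z_max:
        raise DataError(
            f"degenerate extent: t in [{t_min:g}, {t_max:g}], z in [{z_min:g}, {z_max:g}]"
        )
    return np.linspace(t_min, t_max, nx), np.linspace(z_min, z_max, ny)


def interpolate_to_grid(
    samples: SampleTable,
    x_axis: np.ndarray,
    y_axis: np.ndarray,
    fill_nearest: bool = False,
) -> GriddedField:
    """Piecewise-linear interpolation of samples onto the grid.

    Nodes outside the convex hull are masked (``fill_nearest=True`` fills
    them with the nearest sample's value and leaves them valid).  A node
    coincident with a sample point reproduces that sample's value exactly.
    Sample points are sorted by (t, z) before triangulation so the
    triangulation — and hence any tie-break among cocircular points — is
    deterministic.
    """
    if len(samples) < 3:
        raise TriangulationError(
            f"cannot triangulate: {len(samples)} sample(s), need at least 3"
        )
    order = np.lexsort((samples.z, samples.t))
    pts = np.column_stack([samples.t[order], samples.z[order]])
    vals = samples.value[order]
    try:
        interp = LinearNDInterpolator(pts, vals)
    except QhullError as exc:
        raise TriangulationError(f"cannot triangulate: {exc}") from exc
    xx, yy = np.meshgrid(np.asarray(x_axis, float), np.asarray(y_axis, float))
    grid = interp(xx, yy)
    mask = np.isfinite(grid)
    if not mask.any():
        raise TriangulationError("cannot triangulate: all grid nodes outside convex hull")
    if fill_nearest:
        nearest = NearestNDInterpolator(pts, vals)
        grid = np.where(mask, grid, nearest(xx, yy))
        mask = np.ones_like(mask)
    else:
        grid = np.where(mask, grid, np.nan)
    return GriddedField(
        values=grid,
        x_axis=x_axis,
        y_axis=y_axis,
        units=samples.units,
        name=samples.taxon,
        mask=mask,
    )
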