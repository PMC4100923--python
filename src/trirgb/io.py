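"""Readers and writers for the formats the tool touches.

Grids travel as NetCDF (classic format through the scipy backend of xarray:
one 2-D variable with two coordinate variables and ``units`` attributes) or
as a CSV matrix whose header row holds the X coordinates and first column
the Y coordinates.  Scattered samples travel as tidy CSV with ``time`` and
``depth`` columns followed by one column per taxon.  Rasters are written as
8-bit RGB PNG.

CSV dialect is fixed: comma-separated, UTF-8, header required, "." decimal.
"""

from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from PIL import Image

from .compose import RGBRaster, quantize
from .exceptions import DataError
from .fields import GriddedField, SampleTable


# ---------------------------------------------------------------- grids

def read_grid(path, variable_name: str | None = None) -> GriddedField:
    """Load a 2-D field from NetCDF (``.nc``) or CSV matrix (anything else).

    NaN cells (or the variable's ``_FillValue``) become masked.  For NetCDF
    the variable is found by name, or taken as the single 2-D variable when
    ``variable_name`` is omitted.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if path.suffix.lower() == ".nc":
        return _read_grid_netcdf(path, variable_name)
    return _read_grid_csv(path, variable_name)


def _read_grid_netcdf(path: Path, variable_name: str | None) -> GriddedField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable_name is None:
            two_d = [v for v in ds.data_vars if ds[v].ndim == 2]
            if len(two_d) != 1:
                raise DataError(
                    f"{path}: specify a variable; found 2-D variables {two_d}"
                )
            variable_name = two_d[0]
        if variable_name not in ds:
            raise DataError(f"{path}: variable '{variable_name}' not present")
        var = ds[variable_name]
        if var.ndim != 2:
            raise DataError(f"{path}: variable '{variable_name}' is not 2-D")
        ydim, xdim = var.dims
        for dim in (ydim, xdim):
            if dim not in ds.coords:
                raise DataError(f"{path}: missing coordinate variable '{dim}'")
        y = np.asarray(ds.coords[ydim].values, dtype=float)
        x = np.asarray(ds.coords[xdim].values, dtype=float)
        vals = np.asarray(var.values, dtype=float)
        units = str(var.attrs.get("units", ""))
    return _grid_from_arrays(vals, x, y, units, variable_name, path)


def _read_grid_csv(path: Path, variable_name: str | None) -> GriddedField:
    try:
        raw = pd.read_csv(path, header=None, dtype=str)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise DataError(f"{path}: CSV matrix needs a header row and column")
    try:
        x = raw.iloc[0, 1:].astype(float).to_numpy()
        y = raw.iloc[1:, 0].astype(float).to_numpy()
        vals = raw.iloc[1:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric coordinate or cell ({exc})") from exc
    name = variable_name or path.stem
    return _grid_from_arrays(vals, x, y, "", name, path)


def _grid_from_arrays(vals, x, y, units, name, path) -> GriddedField:
    for label, ax in (("x", x), ("y", y)):
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise DataError(f"{path}: {label} coordinates not strictly increasing")
    if vals.shape != (y.size, x.size):
        raise DataError(
            f"{path}: value shape {vals.shape} does not match axes ({y.size}, {x.size})"
        )
    mask = np.isfinite(vals)
    return GriddedField(values=vals, x_axis=x, y_axis=y, units=units, name=name, mask=mask)


def write_grid(field: GriddedField, path) -> None:
    """Write a field to NetCDF (``.nc``) or CSV matrix; masked cells -> NaN."""
    path = Path(path)
    vals = np.where(field.mask, field.values, np.nan)
    if path.suffix.lower() == ".nc":
        da = xr.DataArray(
            vals,
            dims=("depth", "x"),
            coords={"depth": field.y_axis, "x": field.x_axis},
            name=field.name or "field",
            attrs={"units": field.units},
        )
        da.coords["depth"].attrs["units"] = "m"
        da.to_netcdf(path, engine="scipy")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(field.name + "," + ",".join(repr(float(v)) for v in field.x_axis) + "\n")
            for yi, row in zip(field.y_axis, vals):
                fh.write(repr(float(yi)) + "," + ",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------- samples

def _parse_time(token: str, row: int):
    """A time cell is either numeric (days) or an ISO-8601 date."""
    token = token.strip()
    try:
        return float(token), None
    except ValueError:
        pass
    try:
        dt = _dt.datetime.fromisoformat(token)
    except ValueError as exc:
        raise DataError(f"row {row}: unparseable time '{token}'") from exc
    return dt, dt


def read_samples(path, on_duplicate: str = "error") -> dict[str, SampleTable]:
    """Load tidy sample CSV -> one :class:`SampleTable` per taxon column.

    Expected header: ``time,depth,<taxon>[,<taxon>...]``.  ISO dates are
    converted to fractional days since the earliest sample (the origin date
    is kept on each table for axis labeling); blank cells are skipped
    per-taxon.  Errors cite the 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    if len(cols) < 3 or cols[0].lower() != "time" or cols[1].lower() != "depth":
        raise DataError(f"{path}: header must be time,depth,<taxon>,...")
    taxa = cols[2:]

    times, dates = [], []
    depths = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        t_parsed, date = _parse_time(str(row[0]), i)
        times.append(t_parsed)
        dates.append(date)
        try:
            z = float(row[1])
        except (TypeError, ValueError) as exc:
            raise DataError(f"row {i}: unparseable depth '{row[1]}'") from exc
        if z < 0 or not math.isfinite(z):
            raise DataError(f"row {i}: negative or non-finite depth {z}")
        depths.append(z)

    t_origin = None
    if any(d is not None for d in dates):
        if not all(d is not None for d in dates):
            raise DataError(f"{path}: mixed numeric and date times")
        origin = min(dates)
        t_origin = origin.date().isoformat()
        times = [(d - origin).total_seconds() / 86400.0 for d in dates]
    t_arr = np.asarray(times, dtype=float)
    z_arr = np.asarray(depths, dtype=float)

    tables: dict[str, SampleTable] = {}
    for j, taxon in enumerate(taxa):
        col = df.iloc[:, 2 + j]
        keep = col.notna() & (col.astype(str).str.strip() != "")
        try:
            vals = col[keep].astype(float).to_numpy()
        except ValueError as exc:
            bad = int(np.flatnonzero(keep)[0]) + 1
            raise DataError(f"column '{taxon}': non-numeric value near row {bad}") from exc
        tables[taxon] = SampleTable.from_records(
            t=t_arr[keep.to_numpy()],
            z=z_arr[keep.to_numpy()],
            value=vals,
            taxon=taxon,
            units="cells/mL",
            t_origin=t_origin,
            on_duplicate=on_duplicate,
        )
    return tables


def write_samples(tables: dict[str, SampleTable], path) -> None:
    """Write sample tables sharing (t, z) positions to tidy CSV."""
    items = list(tables.items())
    first = items[0][1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time,depth," + ",".join(name for name, _ in items) + "\n")
        for k in range(len(first)):
            cells = [repr(float(first.t[k])), repr(float(first.z[k]))]
            for _, tab in items:
                cells.append(repr(float(tab.value[k])))
            fh.write(",".join(cells) + "\n")


# ---------------------------------------------------------------- rasters

def write_png(raster: RGBRaster, path) -> None:
    """Quantize to 8-bit RGB and write a PNG (row 0 = shallowest depth)."""
    Image.fromarray(quantize(raster), mode="RGB").save(path, format="PNG")


def read_png(path) -> np.ndarray:
    """Read a PNG back as a uint8 (ny, nx, 3) array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
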