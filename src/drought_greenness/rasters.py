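"""Planar grid definition, monthly raster stacks and TIFF-based raster I/O.

Grids are regular, planar and cell-center registered.  Rasters are written as
single-band TIFF files (float32 for continuous fields, int16 for categorical
masks) with the grid geometry carried in a ``grid.json`` sidecar per directory,
and acquisition dates encoded in filenames as ``YYYYMMDD``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "MonthlyStack",
    "read_raster",
    "write_raster",
    "read_grid_spec",
    "write_grid_spec",
    "read_dated_rasters",
    "write_dated_rasters",
]

_DATE_RE = re.compile(r"(\d{8})")


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: ``nrows`` x ``ncols`` cells of ``cell_size`` metres.

    ``x0, y0`` are the coordinates of the center of the upper-left cell; rows
    increase southward (decreasing y), columns eastward (increasing x).
    """

    nrows: int
    ncols: int
    cell_size: float = 250.0
    x0: float = 0.0
    y0: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) coordinate arrays of shape (nrows, ncols)."""
        x = self.x0 + np.arange(self.ncols) * self.cell_size
        y = self.y0 - np.arange(self.nrows) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class MonthlyStack:
    """A gridded monthly time series on a shared :class:`GridSpec`.

    ``values`` has shape ``(n_months, nrows, ncols)`` with NaN for missing
    cells.  ``months`` is a contiguous monthly :class:`pandas.PeriodIndex`.
    """

    values: np.ndarray
    months: pd.PeriodIndex
    grid: GridSpec
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not isinstance(self.months, pd.PeriodIndex):
            self.months = pd.PeriodIndex(self.months, freq="M")
        if self.values.ndim != 3:
            raise ValueError("MonthlyStack values must be (time, rows, cols)")
        if self.values.shape[0] != len(self.months):
            raise ValueError(
                f"{self.values.shape[0]} layers but {len(self.months)} months"
            )
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape[1:]} != grid {self.grid.shape}"
            )

    def layer(self, month) -> np.ndarray:
        """2-D layer for a calendar month (anything PeriodIndex can locate)."""
        return self.values[self.months.get_loc(pd.Period(month, freq="M"))]

    def regional_mean(self) -> pd.Series:
        """Equal-weight mean over valid cells, per month."""
        flat = self.values.reshape(len(self.months), -1)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(flat, axis=1)
        return pd.Series(means, index=self.months, name=self.name)


def write_grid_spec(directory: Path | str, grid: GridSpec) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "grid.json"
    path.write_text(json.dumps(asdict(grid), indent=2))
    return path


def read_grid_spec(directory: Path | str) -> GridSpec:
    path = Path(directory) / "grid.json"
    if not path.exists():
        raise FileNotFoundError(f"no grid.json sidecar in {directory}")
    return GridSpec(**json.loads(path.read_text()))


def write_raster(path: Path | str, array: np.ndarray, dtype: str = "float32") -> None:
    tifffile.imwrite(str(path), np.asarray(array).astype(dtype))


def read_raster(path: Path | str) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_dated_rasters(
    directory: Path | str,
    arrays,
    dates,
    grid: GridSpec,
    prefix: str = "ndvi",
) -> list[Path]:
    """Write one TIFF per (date, 2-D array), date encoded as YYYYMMDD."""
    directory = Path(directory)
    write_grid_spec(directory, grid)
    paths = []
    for arr, date in zip(arrays, dates):
        ts = pd.Timestamp(date)
        p = directory / f"{prefix}_{ts.strftime('%Y%m%d')}.tif"
        write_raster(p, arr)
        paths.append(p)
    return paths


def read_dated_rasters(directory: Path | str, prefix: str | None = None):
    """Read all dated TIFFs in a directory.

    Returns ``(arrays, dates, grid)`` sorted by date; filenames must contain a
    YYYYMMDD date token.
    """
    directory = Path(directory)
    grid = read_grid_spec(directory)
    items = []
    for p in sorted(directory.glob("*.tif")):
        if prefix is not None and not p.stem.startswith(prefix):
            continue
        m = _DATE_RE.search(p.stem)
        if m is None:
            raise ValueError(f"no YYYYMMDD date in raster filename {p.name}")
        items.append((pd.Timestamp(m.group(1)), read_raster(p)))
    items.sort(key=lambda t: t[0])
    dates = [d for d, _ in items]
    arrays = [a for _, a in items]
    for a in arrays:
        if a.shape != grid.shape:
            raise ValueError(f"raster shape {a.shape} != grid {grid.shape}")
    return arrays, dates, grid
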