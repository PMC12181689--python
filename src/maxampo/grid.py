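"""Raster grids, layer stacks and occurrence points.

Conventions used throughout the package:

* Grids are axis-aligned, square-celled and metric (projected coordinates in
  metres).  ``origin`` is the (x, y) of the *outer* corner of the top-left
  cell; rows run north→south, columns west→east.
* Cell registration is at cell centres.  A point maps to the cell whose
  half-open interval ``[x0 + c*s, x0 + (c+1)*s)`` horizontally and
  ``(y0 - (r+1)*s, y0 - r*s]`` vertically contains it, so a point lies in at
  most one cell.
* In memory, missing data (sea, masked cells) is ``NaN`` in float arrays; the
  ``nodata`` sentinel only appears on disk.
* On disk, single-band rasters are plain-text ESRI ASCII grids (``.asc``) —
  human-diffable and dependency-free.  The CRS identifier travels in a small
  ``.crs`` sidecar next to each raster.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "EnvStack",
    "OccurrenceSet",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry shared by all layers of a raster stack."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- extent ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_min(self) -> float:
        return self.origin[0]

    @property
    def x_max(self) -> float:
        return self.origin[0] + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin[1]

    @property
    def y_min(self) -> float:
        return self.origin[1] - self.n_rows * self.cell_size

    @property
    def is_geographic(self) -> bool:
        """Heuristic flag for degree-unit grids (declared via ``crs_id``)."""
        cid = self.crs_id.lower()
        return "4326" in cid or "deg" in cid or "wgs84" in cid

    # -- coordinate transforms -----------------------------------------
    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinate vectors for columns and rows."""
        s = self.cell_size
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin[1] - (np.arange(self.n_rows) + 0.5) * s
        return xs, ys

    def cell_centre(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention.

        Out-of-extent points get index -1 in the offending dimension.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        # d = y0 - y; floor(d/s) makes the vertical interval (y0-(r+1)s, y0-rs]
        # with the top edge of each row inclusive
        d = self.origin[1] - y
        row = np.floor(d / self.cell_size).astype(int)
        col = np.where((col < 0) | (col >= self.n_cols), -1, col)
        row = np.where((row < 0) | (row >= self.n_rows), -1, row)
        return row, col

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def aggregate(self, factor: int) -> "Grid":
        """Coarser grid covering the same origin with ``factor``× larger cells.

        Trailing rows/columns that do not fill a block are dropped.
        """
        if factor < 1:
            raise ValueError("aggregation factor must be >= 1")
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            cell_size=self.cell_size * factor,
        )


# ----------------------------------------------------------------------
# ASCII grid I/O


def write_ascii_grid(path, values: np.ndarray, grid: Grid) -> None:
    """Write one float32 band as an ESRI ASCII grid (+ ``.crs`` sidecar)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), grid.nodata, values).astype(np.float32)
    buf = io.StringIO()
    buf.write(f"ncols {grid.n_cols}\n")
    buf.write(f"nrows {grid.n_rows}\n")
    buf.write(f"xllcorner {grid.x_min!r}\n")
    buf.write(f"yllcorner {grid.y_min!r}\n")
    buf.write(f"cellsize {grid.cell_size!r}\n")
    buf.write(f"NODATA_value {grid.nodata!r}\n")
    np.savetxt(buf, out, fmt="%.6g")
    path.write_text(buf.getvalue())
    path.with_suffix(path.suffix + ".crs").write_text(grid.crs_id + "\n")


def read_ascii_grid(path, crs_id: str | None = None) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; nodata becomes NaN."""
    path = Path(path)
    with path.open() as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if crs_id is None:
        sidecar = path.with_suffix(path.suffix + ".crs")
        crs_id = sidecar.read_text().strip() if sidecar.exists() else "local-metric"
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin=(header["xllcorner"], header["yllcorner"] + n_rows * cell),
        crs_id=crs_id,
        nodata=nodata,
    )
    values = values.reshape(grid.shape).astype(float)
    values[np.isclose(values, nodata)] = np.nan
    return values, grid


# ----------------------------------------------------------------------
# Layer stacks


@dataclass
class EnvStack:
    """Ordered, named raster layers sharing one :class:`Grid`.

    The common nodata mask is the union of per-layer masks: a cell is "land"
    only where every layer is finite.
    """

    grid: Grid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self.layers[name] = self._check(name, arr)

    def _check(self, name: str, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
            )
        return arr

    # -- mapping interface ---------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __setitem__(self, name: str, arr: np.ndarray) -> None:
        self.layers[name] = self._check(name, arr)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, {k: v.copy() for k, v in self.layers.items()})

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names})

    def merged(self, other: "EnvStack") -> "EnvStack":
        """New stack with ``other``'s layers appended (grids must match)."""
        if not self.grid.same_geometry(other.grid):
            raise ValueError("cannot merge stacks on different grids")
        out = self.copy()
        for n in other.names:
            out[n] = other[n]
        return out

    # -- masks and tables ----------------------------------------------
    def land_mask(self) -> np.ndarray:
        """Boolean mask of cells finite in *every* layer."""
        if not self.layers:
            raise ValueError("empty stack has no mask")
        mask = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def values_table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Layer values over masked cells; index = flat cell index."""
        if mask is None:
            mask = self.land_mask()
        flat = np.flatnonzero(mask.ravel())
        data = {n: self.layers[n].ravel()[flat] for n in self.layers}
        return pd.DataFrame(data, index=flat)

    def values_at(self, x, y) -> pd.DataFrame:
        """Layer values at the cells containing the given points.

        Off-grid points yield NaN rows.
        """
        row, col = self.grid.point_to_cell(x, y)
        ok = (row >= 0) & (col >= 0)
        out = {}
        for n, arr in self.layers.items():
            v = np.full(row.shape, np.nan)
            v[ok] = arr[row[ok], col[ok]]
            out[n] = v
        return pd.DataFrame(out)

    # -- I/O -------------------------------------------------------------
    def write_dir(self, directory) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, arr in self.layers.items():
            p = directory / f"{name}.asc"
            write_ascii_grid(p, arr, self.grid)
            written.append(p)
        return written

    @classmethod
    def read_dir(cls, directory, names: list[str]) -> "EnvStack":
        directory = Path(directory)
        layers = {}
        grid = None
        for name in names:
            arr, g = read_ascii_grid(directory / f"{name}.asc")
            if grid is None:
                grid = g
            elif not grid.same_geometry(g):
                raise ValueError(f"layer {name!r} grid differs from first layer")
            layers[name] = arr
        assert grid is not None
        return cls(grid, layers)


# ----------------------------------------------------------------------
# Occurrence points


@dataclass
class OccurrenceSet:
    """Point records (projected metres) with source tags and dates."""

    x: np.ndarray
    y: np.ndarray
    source: np.ndarray
    date: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        self.date = np.asarray(self.date, dtype=object)
        n = len(self.x)
        if not (len(self.y) == len(self.source) == len(self.date) == n):
            raise ValueError("occurrence columns must have equal length")
        if n and not np.all(np.isfinite(self.x) & np.isfinite(self.y)):
            raise ValueError("occurrence coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_arrays(cls, x, y, source="unknown", date="") -> "OccurrenceSet":
        x = np.asarray(x, dtype=float)
        src = np.full(x.shape, source, dtype=object) if np.isscalar(source) else source
        dt = np.full(x.shape, date, dtype=object) if np.isscalar(date) else date
        return cls(x=x, y=np.asarray(y, dtype=float), source=src, date=dt)

    def subset(self, idx) -> "OccurrenceSet":
        idx = np.asarray(idx)
        return OccurrenceSet(
            x=self.x[idx], y=self.y[idx], source=self.source[idx], date=self.date[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": self.x, "lat": self.y, "source": self.source, "date": self.date}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        return cls(
            x=df["lon"].to_numpy(float),
            y=df["lat"].to_numpy(float),
            source=df["source"].to_numpy(object),
            date=df["date"].to_numpy(object),
        )

    def cells_on(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        return grid.point_to_cell(self.x, self.y)
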