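"""Georeferenced 2-D value grids and plain-text raster I/O.

A :class:`RasterGrid` is the substrate of every spatial step: a rectangular
array of cell values with a cell size, a lower-left origin, and a nodata
marker.  Row 0 is the *top* row of the map (north), matching the usual raster
convention; the cell centre of ``values[i, j]`` is at::

    x = origin_x + (j + 0.5) * cell_size
    y = origin_y + (n_rows - i - 0.5) * cell_size

Grids are written and read as ESRI ASCII grid (``.asc``), a plain-text format
understood by standard GIS tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "ElevationGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """Rectangular grid of float values with an affine placement contract."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells holding data (not nodata, not NaN)."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 + (self.n_rows - row - 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, shape = grid shape."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same placement but different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("shape mismatch")
        return replace(self, values=values)


# A DEM is just a grid whose values are elevations in metres.
ElevationGrid = RasterGrid


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a grid as ESRI ASCII (.asc)."""
    vals = np.where(grid.mask_valid(), grid.values, grid.nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII (.asc) grid."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    nodata = header.get("nodata_value", -9999.0)
    grid = RasterGrid(
        values=np.atleast_2d(values),
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=nodata,
    )
    grid.values[grid.values == nodata] = np.nan
    return grid
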