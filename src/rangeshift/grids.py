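"""Minimal planar-km raster container and plain-text (Esri ASCII grid) I/O.

All rasters in this package live on axis-aligned grids in a planar km
coordinate system.  Row index increases northward (row 0 is the southernmost
row), column index increases eastward.  Cell registration is by center:
the center of cell (row, col) is at
``(x0 + (col + 0.5) * cell, y0 + (row + 0.5) * cell)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Raster:
    """A single-band raster on a planar km grid.

    Parameters
    ----------
    data:
        2-D array, shape ``(ny, nx)``; row 0 is the southernmost row.
    x0, y0:
        Coordinates (km) of the south-west corner of the grid (cell edge,
        not cell center).
    cell:
        Cell edge length in km.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        object.__setattr__(self, "data", d)

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell,
            self.y0 + self.ny * self.cell,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-center coordinates, shape (ny, nx)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.cell == other.cell
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.x0) / self.cell))
        row = int(np.floor((y - self.y0) / self.cell))
        if not (0 <= row < self.ny and 0 <= col < self.nx):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col


def aggregate_fraction(fine: Raster, values, coarse_cell: float) -> Raster:
    """Fractional cover of ``values`` in ``fine`` aggregated to ``coarse_cell``.

    The coarse grid shares the fine grid's origin.  The coarse cell size must
    be an integer multiple of the fine cell size and divide the extent
    exactly, so every coarse cell is the mean of a full block of fine cells
    and total class area is conserved to machine precision.
    """
    ratio = coarse_cell / fine.cell
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("coarse cell must be an integer multiple of fine cell")
    if fine.ny % k or fine.nx % k:
        raise ValueError("coarse cell must tile the raster exactly")
    member = np.isin(fine.data, np.atleast_1d(values)).astype(np.float64)
    ny, nx = fine.ny // k, fine.nx // k
    frac = member.reshape(ny, k, nx, k).mean(axis=(1, 3))
    return Raster(frac, fine.x0, fine.y0, coarse_cell)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a raster as an Esri ASCII grid (plain text, row 0 = north)."""
    path = Path(path)
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.x0}\n"
        f"yllcorner {raster.y0}\n"
        f"cellsize {raster.cell}\n"
        f"NODATA_value -9999\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data[::-1], fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    return Raster(
        data,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
    )
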