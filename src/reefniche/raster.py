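"""Geo-referenced grid containers.

All spatial stages exchange :class:`RasterGrid` objects: 2-D, north-up,
row-major grids on a projected planar kilometre coordinate system. The
origin sits at the top-left corner of the grid; ``x`` increases eastward
(column direction) and ``y`` increases southward (row direction), so a
point ``(x, y)`` in km falls in cell ``(floor(y / cell), floor(x / cell))``
(half-open cell intervals). Cell centers are at ``(col + 0.5) * cell_size``,
``(row + 0.5) * cell_size``.

Rasters are persisted as ESRI ASCII grids (plain text), the lowest common
denominator raster exchange format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band north-up raster on a planar km grid."""

    data: np.ndarray
    cell_size_km: float = 1.0
    nodata: float = NODATA
    crs: str = "local-km"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and np.isclose(
            self.cell_size_km, other.cell_size_km
        )

    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.data, self.nodata) & ~np.isnan(self.data)

    def masked(self) -> np.ndarray:
        """Data with nodata cells replaced by NaN."""
        out = self.data.astype(float).copy()
        out[~self.valid_mask()] = np.nan
        return out

    def with_data(self, data: np.ndarray) -> "RasterGrid":
        return replace(self, data=np.asarray(data, dtype=float))

    def full_like(self, value: float) -> "RasterGrid":
        return self.with_data(np.full(self.shape, value, dtype=float))

    # -- coordinates ---------------------------------------------------
    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map projected (x, y) km to (row, col); may fall outside the grid."""
        col = np.floor(np.asarray(x) / self.cell_size_km).astype(int)
        row = np.floor(np.asarray(y) / self.cell_size_km).astype(int)
        return row, col

    def in_bounds(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped like the grid."""
        cs = self.cell_size_km
        x = (np.arange(self.ncols) + 0.5) * cs
        y = (np.arange(self.nrows) + 0.5) * cs
        return np.meshgrid(x, y)

    # -- I/O -----------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            "xllcorner 0.0\n"
            f"yllcorner {-self.nrows * self.cell_size_km}\n"
            f"cellsize {self.cell_size_km}\n"
            f"NODATA_value {self.nodata}\n"
        )
        body = "\n".join(
            " ".join(f"{v:.6g}" for v in row) for row in self.data
        )
        path.write_text(header + body + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        lines = Path(path).read_text().splitlines()
        hdr = {}
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            key, val = lines[i].split()[:2]
            hdr[key.lower()] = float(val)
            i += 1
        data = np.loadtxt(lines[i:], dtype=float)
        data = np.atleast_2d(data)
        if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
            raise ValueError("ASCII grid body does not match header shape")
        return cls(
            data=data,
            cell_size_km=hdr.get("cellsize", 1.0),
            nodata=hdr.get("nodata_value", NODATA),
        )


@dataclass
class RasterStack:
    """A stack of co-registered rasters (e.g. one per day)."""

    data: np.ndarray  # (n, nrows, ncols)
    cell_size_km: float = 1.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("RasterStack data must be 3-D (n, rows, cols)")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def grid(self, i: int) -> RasterGrid:
        return RasterGrid(self.data[i], self.cell_size_km, self.nodata)

    def masked(self) -> np.ndarray:
        out = self.data.astype(float).copy()
        out[np.isclose(out, self.nodata)] = np.nan
        return out

    @classmethod
    def from_grids(cls, grids: list[RasterGrid]) -> "RasterStack":
        if not grids:
            raise ValueError("empty stack")
        g0 = grids[0]
        for g in grids[1:]:
            if not g0.same_geometry(g):
                raise ValueError("stack members must share geometry")
        return cls(
            data=np.stack([g.data for g in grids]),
            cell_size_km=g0.cell_size_km,
            nodata=g0.nodata,
        )
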