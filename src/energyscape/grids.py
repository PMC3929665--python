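"""Gridded raster container and plain-text raster I/O.

A :class:`GridRaster` is a single-band grid in a projected equal-area
frame: a 2-D float array plus cell size and lower-left origin. Row 0 is
the *top* row (image convention); the y coordinate of a cell therefore
decreases with row index. Rasters are serialized as ESRI ASCII grids
(``.asc``), a plain-text interchange format readable by every GIS.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GridRaster",
    "PresenceSet",
    "WatershedSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "sample_stack",
]


@dataclasses.dataclass
class GridRaster:
    """Single-band georeferenced grid.

    Parameters
    ----------
    data:
        2-D array of cell values; NaN encodes nodata.
    cell_size:
        Cell edge length in meters (cells are square).
    origin:
        (x, y) of the lower-left corner of the grid.
    """

    data: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("GridRaster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_cells(self) -> int:
        return self.data.size

    @property
    def cell_area(self) -> float:
        """Cell area in square meters."""
        return self.cell_size**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + cols * self.cell_size, y0 + rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x, y) of every cell center, shaped like ``data``."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 + (rows - np.arange(rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows = self.shape[0]
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows = self.shape[0]
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = rows - 1 - np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        return row, col

    # -- alignment ----------------------------------------------------
    def aligned_with(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, other: "GridRaster", name: str = "raster") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"{name} is not aligned with the reference grid")

    def like(self, data: np.ndarray) -> "GridRaster":
        """New raster on this grid's frame carrying ``data``."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        return GridRaster(data, self.cell_size, self.origin)

    def copy(self) -> "GridRaster":
        return GridRaster(self.data.copy(), self.cell_size, self.origin)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(repr((self.shape, self.cell_size, self.origin)).encode())
        return h.hexdigest()


def write_ascii_grid(raster: GridRaster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    path = Path(path)
    rows, cols = raster.shape
    data = np.where(np.isnan(raster.data), nodata, raster.data)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return GridRaster(
        data,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


@dataclasses.dataclass
class PresenceSet:
    """Point locations of known or simulated development.

    Backed by a DataFrame with at least ``x`` and ``y`` columns; any
    additional columns (probability, watershed id, ...) ride along.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"x", "y"} - set(self.table.columns)
        if missing:
            raise ValueError(f"PresenceSet table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_xy(cls, x: Iterable[float], y: Iterable[float], **attrs) -> "PresenceSet":
        return cls(pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), **attrs}))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return self.table[["x", "y"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PresenceSet":
        return cls(pd.read_csv(path))

    def sample(self, raster: GridRaster) -> np.ndarray:
        """Raster values at each point's cell."""
        row, col = raster.xy_to_rowcol(self.table["x"].to_numpy(), self.table["y"].to_numpy())
        rows, cols = raster.shape
        if np.any((row < 0) | (row >= rows) | (col < 0) | (col >= cols)):
            raise ValueError("point outside raster extent")
        return raster.data[row, col]

    def to_geojson(self, path: str | Path) -> None:
        features = []
        attr_cols = [c for c in self.table.columns if c not in ("x", "y")]
        for _, row in self.table.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                    "properties": {c: row[c] for c in attr_cols},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def sample_stack(stack: dict[str, "GridRaster"], xy: np.ndarray) -> pd.DataFrame:
    """Covariate values at point locations, one column per raster."""
    xy = np.asarray(xy, dtype=float)
    pts = PresenceSet.from_xy(xy[:, 0], xy[:, 1])
    return pd.DataFrame({name: pts.sample(r) for name, r in stack.items()})


@dataclasses.dataclass
class WatershedSet:
    """Nested basin/subwatershed zonal units on a grid.

    ``labels`` assigns every cell a subwatershed id (the grid partition
    stands in for polygon geometry); ``table`` carries one row per
    subwatershed: watershed_id, basin_id, importance (relative water
    importance index in [0, 1]) and area_ha.
    """

    labels: GridRaster
    table: pd.DataFrame

    _REQUIRED = ("watershed_id", "basin_id", "importance")

    def __post_init__(self) -> None:
        missing = set(self._REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"WatershedSet table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if "area_ha" not in self.table.columns:
            counts = np.bincount(
                self.labels.data.astype(int).ravel(), minlength=len(self.table)
            )
            self.table["area_ha"] = counts * self.labels.cell_area / 1e4

    @property
    def n_subwatersheds(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["watershed_id"].to_numpy()

    def cell_counts(self) -> np.ndarray:
        return np.bincount(self.labels.data.astype(int).ravel(), minlength=len(self.table))

    def watershed_of_points(self, xy: np.ndarray) -> np.ndarray:
        """Subwatershed id containing each point."""
        pts = PresenceSet.from_xy(np.asarray(xy)[:, 0], np.asarray(xy)[:, 1])
        return pts.sample(self.labels).astype(int)

    def to_files(self, label_path: str | Path, table_path: str | Path) -> None:
        write_ascii_grid(self.labels, label_path)
        self.table.to_csv(table_path, index=False)

    @classmethod
    def from_files(cls, label_path: str | Path, table_path: str | Path) -> "WatershedSet":
        return cls(read_ascii_grid(label_path), pd.read_csv(table_path))
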