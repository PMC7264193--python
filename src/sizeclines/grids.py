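"""Regular lat-lon raster stacks indexed by year or decade.

A :class:`RasterStack` is the in-memory form of the gridded covariate
surfaces the pipeline consumes: mean annual temperature (degC), mean annual
precipitation (mm), and decadal human population density (persons/km^2).
All time steps of a stack share one grid geometry.  On disk a stack is a
set of ESRI ASCII grid files (one per time step) plus a JSON index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "RasterStack"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic grid. Row 0 is the southernmost row."""

    west: float
    south: float
    cell_size: float  # degrees
    n_rows: int
    n_cols: int

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.cell_size

    def index_of(self, lon, lat):
        """Row/col of the cell containing each point.

        Cells are half-open intervals [west_edge, east_edge) x
        [south_edge, north_edge), so every interior point maps to exactly
        one cell.  Points outside the grid get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row = np.floor((lat - self.south) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_centers(self):
        """(lon, lat) 2-D arrays of cell-center coordinates."""
        lons = self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lats = self.south + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lons, lats)


@dataclass
class RasterStack:
    """Time-indexed stack of value matrices on one grid geometry."""

    variable: str
    units: str
    geometry: GridGeometry
    data: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, arr in self.data.items():
            if arr.shape != (self.geometry.n_rows, self.geometry.n_cols):
                raise ValueError(
                    f"layer {t} shape {arr.shape} does not match grid "
                    f"({self.geometry.n_rows}, {self.geometry.n_cols})"
                )

    @property
    def times(self) -> list[int]:
        return sorted(self.data)

    def layer(self, time: int) -> np.ndarray:
        return self.data[time]

    def nearest_time(self, time: int) -> int:
        """Closest available time step (ties break to the earlier one)."""
        times = self.times
        if not times:
            raise ValueError("empty stack")
        return min(times, key=lambda t: (abs(t - time), t))

    def sample(self, lon, lat, time: int, nearest: bool = False):
        """Value of the cell containing each point, from one time layer.

        Out-of-extent points yield NaN.  ``nearest=True`` snaps ``time`` to
        the closest available layer instead of raising KeyError.
        """
        if nearest:
            time = self.nearest_time(time)
        arr = self.data[time]
        row, col = self.geometry.index_of(lon, lat)
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = row >= 0
        out[ok] = arr[row[ok], col[ok]]
        return out

    # ---- serialization (text formats only) ------------------------------

    def write(self, directory: str | Path) -> Path:
        """Write one ASCII grid per time step plus an index JSON.

        Returns the path of the index file.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        g = self.geometry
        index = {
            "variable": self.variable,
            "units": self.units,
            "grid": {
                "west": g.west,
                "south": g.south,
                "cell_size": g.cell_size,
                "n_rows": g.n_rows,
                "n_cols": g.n_cols,
            },
            "layers": {},
        }
        for t in self.times:
            name = f"{self.variable}_{t}.asc"
            _write_ascii_grid(directory / name, self.data[t], g)
            index["layers"][str(t)] = name
        index_path = directory / f"{self.variable}_index.json"
        index_path.write_text(json.dumps(index, indent=2))
        return index_path

    @classmethod
    def read(cls, index_path: str | Path) -> "RasterStack":
        index_path = Path(index_path)
        index = json.loads(index_path.read_text())
        g = GridGeometry(**index["grid"])
        data = {
            int(t): _read_ascii_grid(index_path.parent / name)
            for t, name in index["layers"].items()
        }
        return cls(index["variable"], index["units"], g, data)


def _write_ascii_grid(path: Path, arr: np.ndarray, g: GridGeometry) -> None:
    # ESRI ASCII grids are stored north-to-south; our row 0 is south.
    header = (
        f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
        f"xllcorner {g.west!r}\nyllcorner {g.south!r}\n"
        f"cellsize {g.cell_size!r}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr[::-1], fmt="%.6g")


def _read_ascii_grid(path: Path) -> np.ndarray:
    with open(path) as fh:
        for _ in range(6):
            fh.readline()
        arr = np.loadtxt(fh)
    return np.atleast_2d(arr)[::-1].copy()


def aggregate_blocks(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block mean over factor x factor windows; partial edge blocks are
    averaged over the pixels they actually contain."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return arr.copy()
    nr, nc = arr.shape
    if factor > max(nr, nc):
        raise ValueError("aggregation factor exceeds raster dimensions")
    out_r = math.ceil(nr / factor)
    out_c = math.ceil(nc / factor)
    out = np.empty((out_r, out_c), dtype=float)
    for i in range(out_r):
        for j in range(out_c):
            block = arr[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            out[i, j] = block.mean()
    return out
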