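"""Raster containers and plain-text grid I/O.

Grids are plain 2-D numpy arrays with a three-number geotransform
``(xll, yll, cell_size)`` — the coordinates of the lower-left corner of the
lower-left cell and the (square) cell size in metres.  Row 0 of the array is
the northernmost row, matching the ESRI ASCII grid layout used for I/O.

Point-in-pixel convention: a pixel with upper-left corner ``(x, y)`` covers
the half-open box ``[x, x + d) × (y − d, y]`` — left edge and top edge belong
to the pixel.  :meth:`Grid.point_to_index` implements this and is shared by
the extraction and sampling code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import AlignmentError

Transform = tuple[float, float, float]

_TRANSFORM_TOL = 1e-6


@dataclass
class Grid:
    """A single-band continuous raster."""

    values: np.ndarray
    transform: Transform = (0.0, 0.0, 250.0)
    nodata: float = -9999.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.transform[2] <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return float(self.transform[2])

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a real value."""
        with np.errstate(invalid="ignore"):
            return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, **kw) -> "Grid":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    # -- georeferencing ----------------------------------------------------

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrows, ncols = self.shape
        xll, yll, cs = self.transform
        return (xll, yll, xll + ncols * cs, yll + nrows * cs)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        xll, yll, cs = self.transform
        ytop = yll + self.shape[0] * cs
        return (xll + (col + 0.5) * cs, ytop - (row + 0.5) * cs)

    def point_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to (row, col) under the half-open pixel convention."""
        nrows, ncols = self.shape
        xll, yll, cs = self.transform
        ytop = yll + nrows * cs
        col = int(np.floor((x - xll) / cs))
        row = int(np.floor((ytop - y) / cs))
        # top edge of the grid belongs to row 0
        if y == ytop:
            row = 0
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid extent {self.extent}")
        return row, col

    def is_aligned(self, other: "Grid | CategoricalGrid") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= _TRANSFORM_TOL * max(1.0, abs(a))
            for a, b in zip(self.transform, other.transform)
        )


@dataclass
class CategoricalGrid:
    """A single-band raster of integer class codes with a legend."""

    codes: np.ndarray
    legend: dict[int, str]
    transform: Transform = (0.0, 0.0, 250.0)
    nodata: int = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise ValueError("grid codes must be 2-D")
        present = set(np.unique(self.codes[self.codes != self.nodata]).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes {sorted(missing)} missing from legend")

    shape = Grid.shape
    cell_size = Grid.cell_size
    extent = Grid.extent
    cell_center = Grid.cell_center
    point_to_index = Grid.point_to_index
    is_aligned = Grid.is_aligned

    @property
    def values(self) -> np.ndarray:  # lets geometry helpers above work unchanged
        return self.codes

    @property
    def mask(self) -> np.ndarray:
        return self.codes != self.nodata

    def labels(self) -> np.ndarray:
        """Object array of labels (None where nodata)."""
        out = np.full(self.shape, None, dtype=object)
        for code, label in self.legend.items():
            out[self.codes == code] = label
        return out


def check_aligned(grids: Mapping[str, Grid | CategoricalGrid] | Iterable) -> None:
    """Raise :class:`AlignmentError` unless all grids share shape and transform."""
    if isinstance(grids, Mapping):
        items = list(grids.items())
    else:
        items = [(f"grid[{i}]", g) for i, g in enumerate(grids)]
    if len(items) < 2:
        return
    name0, ref = items[0]
    for name, g in items[1:]:
        if not ref.is_aligned(g):
            raise AlignmentError(
                f"{name} (shape {g.shape}, transform {g.transform}) is not aligned "
                f"with {name0} (shape {ref.shape}, transform {ref.transform})"
            )


# -- ESRI ASCII grid I/O ---------------------------------------------------


def write_ascii(grid: Grid, path: str | Path, fmt: str = "%.6g") -> Path:
    path = Path(path)
    nrows, ncols = grid.shape
    xll, yll, cs = grid.transform
    vals = np.where(grid.mask, grid.values, grid.nodata)
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {xll:.6f}\nyllcorner {yll:.6f}\n"
        f"cellsize {cs:.6f}\nNODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    return path


def read_ascii(path: str | Path, units: str = "") -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: body shape {values.shape} != header ({nrows}, {ncols})")
    return Grid(
        values,
        transform=(header["xllcorner"], header["yllcorner"], header["cellsize"]),
        nodata=header.get("nodata_value", -9999.0),
        units=units,
    )


def write_categorical(grid: CategoricalGrid, path: str | Path) -> Path:
    """Write codes as .asc plus a ``<path>.legend.json`` sidecar."""
    path = Path(path)
    as_grid = Grid(grid.codes.astype(float), grid.transform, nodata=float(grid.nodata))
    write_ascii(as_grid, path, fmt="%d")
    sidecar = path.with_suffix(path.suffix + ".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in grid.legend.items()}, indent=1))
    return path


def read_categorical(path: str | Path, legend: dict[int, str] | None = None) -> CategoricalGrid:
    path = Path(path)
    g = read_ascii(path)
    if legend is None:
        sidecar = path.with_suffix(path.suffix + ".legend.json")
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return CategoricalGrid(
        g.values.astype(np.int32), legend, transform=g.transform, nodata=int(g.nodata)
    )
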