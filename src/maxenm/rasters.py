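"""Raster containers and ESRI ASCII grid I/O.

Environmental layers are co-registered single-band grids on a regular
geographic (WGS84) lattice. A :class:`RasterStack` holds any number of
co-registered layers as 2-D float arrays with ``NaN`` marking nodata, plus
the shared :class:`GridSpec`. Grids are written as ESRI ASCII (``.asc``) —
a plain-text format that round-trips values exactly when written at full
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "RasterStack", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid (WGS84, cell registration).

    ``xllcorner``/``yllcorner`` are the outer corner of the lower-left
    cell; row 0 of the arrays is the northernmost row, as in the ESRI
    ASCII convention.
    """

    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape (nrows, ncols) of cell centres."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lon = self.xllcorner + (cols + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(lon, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            lat[:, None], (self.nrows, self.ncols)
        ).copy()

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; -1 where outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col


class RasterStack:
    """Ordered collection of co-registered single-band grids.

    Layers are stored as float64 arrays with ``NaN`` for nodata. The valid
    mask of the stack is the conjunction of the per-layer masks.
    """

    def __init__(self, grid: GridSpec, layers: dict[str, np.ndarray]):
        if not layers:
            raise ValueError("stack requires at least one layer")
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (grid.nrows, grid.ncols):
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {(grid.nrows, grid.ncols)}"
                )
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Boolean grid, true where every layer has data."""
        mask = np.ones((self.grid.nrows, self.grid.ncols), dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def subset(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack(self.grid, {n: self.layers[n] for n in names})

    def table(
        self, names: list[str] | None = None, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (cells x layers) over the valid (optionally masked) cells.

        Returns ``(values, flat_index)`` where ``flat_index`` maps table
        rows back to ``row * ncols + col`` positions.
        """
        names = names or self.layer_names
        valid = self.valid_mask()
        if mask is not None:
            valid &= mask
        idx = np.flatnonzero(valid.ravel())
        vals = np.column_stack([self.layers[n].ravel()[idx] for n in names])
        return vals, idx

    def write_dir(self, path: str | Path) -> None:
        """Write one ``<layer>.asc`` per layer into ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(path / f"{name}.asc", self.grid, arr)

    @classmethod
    def read_dir(cls, path: str | Path, names: list[str] | None = None) -> "RasterStack":
        """Read every ``.asc`` in ``path`` (or the named subset) into a stack."""
        path = Path(path)
        files = (
            [path / f"{n}.asc" for n in names]
            if names
            else sorted(path.glob("*.asc"))
        )
        if not files:
            raise FileNotFoundError(f"no .asc grids under {path}")
        grid = None
        layers: dict[str, np.ndarray] = {}
        for f in files:
            g, arr = read_ascii_grid(f)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"grid of {f.name} does not match the stack")
            layers[f.stem] = arr
        assert grid is not None
        return cls(grid, layers)


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.nrows, grid.ncols):
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing header field {req} in {path}")
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    arr = np.array(rows, dtype=float)
    if arr.shape != (grid.nrows, grid.ncols):
        raise ValueError(f"data shape {arr.shape} does not match header in {path}")
    nodata = header.get("nodata_value", _NODATA)
    arr[arr == nodata] = np.nan
    return grid, arr


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on the sphere of mean radius 6371.0088 km."""
    r = 6371.0088
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def arc_degrees(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle separation expressed in degrees of arc."""
    r = 6371.0088
    return np.degrees(haversine_km(lon1, lat1, lon2, lat2) / r)
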