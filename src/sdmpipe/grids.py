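"""Georeferenced grid geometry and raster containers.

All layers in a study share one :class:`GridSpec`: a north-up grid of square
cells in geographic (WGS84 longitude/latitude) coordinates, addressed by
``(row, col)`` with row 0 at the top. Missing data is represented as NaN in
memory and as a sentinel value on disk.

Rasters are stored on disk as ESRI ASCII grids (``.asc``), a plain-text,
GIS-standard single-band format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "GridSpec",
    "EnvironmentalStack",
    "SuitabilityMap",
    "LandCoverGrid",
    "haversine_km",
    "local_xy_km",
    "read_ascii_grid",
    "write_ascii_grid",
    "EARTH_RADIUS_KM",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up lat/lon raster grid.

    Parameters
    ----------
    origin_lon, origin_lat : float
        Coordinates of the *top-left corner* of the top-left cell, degrees.
    cell_size : float
        Cell edge length in degrees (square cells).
    n_rows, n_cols : int
        Grid dimensions.
    crs : str
        Coordinate reference identifier; fixed to WGS84 geographic.
    nodata : float
        Sentinel written to disk for missing cells.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        top = self.origin_lat - self.cell_size / 2.0
        bottom = self.origin_lat - (self.n_rows - 0.5) * self.cell_size
        if abs(top) >= 90.0 or abs(bottom) >= 90.0:
            raise ValueError("all cell centers must satisfy |lat| < 90")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the grid footprint."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def cell_center(self, row, col):
        """Longitude/latitude of cell center(s); accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Map points to (row, col) by containment.

        Points on interior cell edges belong to the cell to the
        right/below; points on the outer boundary of the grid are pulled
        into the nearest edge cell (closed extent convention).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        inside = self.contains(lon, lat)
        col = np.where(inside, np.clip(col, 0, self.n_cols - 1), col)
        row = np.where(inside, np.clip(row, 0, self.n_rows - 1), row)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col

    def contains(self, lon, lat):
        """True for points inside or on the boundary of the grid footprint."""
        min_lon, min_lat, max_lon, max_lat = self.bounds
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= min_lon) & (lon <= max_lon) & (lat >= min_lat) & (lat <= max_lat)

    def to_dict(self) -> dict:
        return {
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs": self.crs,
            "nodata": self.nodata,
        }


def _check_conformal(spec: GridSpec, grid: np.ndarray, name: str = "layer") -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.shape != spec.shape:
        raise ValueError(
            f"{name} has shape {grid.shape}, expected {spec.shape} from GridSpec"
        )
    return grid


class EnvironmentalStack:
    """Ordered set of named, co-registered real-valued predictor layers.

    Layers are 2-D float arrays with NaN for nodata; nodata cells coincide
    across layers (the shared land mask).
    """

    def __init__(self, spec: GridSpec, layers: dict[str, np.ndarray]):
        self.spec = spec
        self.layers: dict[str, np.ndarray] = {}
        mask = None
        for name, grid in layers.items():
            grid = _check_conformal(spec, grid, name)
            m = np.isnan(grid)
            if mask is None:
                mask = m
            elif not np.array_equal(mask, m):
                raise ValueError(
                    f"nodata cells of layer {name!r} do not coincide with the stack mask"
                )
            self.layers[name] = grid
        self._nodata_mask = mask if mask is not None else np.zeros(spec.shape, bool)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where cells are nodata in every layer."""
        return self._nodata_mask

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"layer {name!r} not in stack (have {self.layer_names})")
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str]) -> "EnvironmentalStack":
        return EnvironmentalStack(self.spec, {n: self[n] for n in names})

    def to_frame(self) -> pd.DataFrame:
        """Non-nodata cells as rows: columns row, col, lon, lat, <layers>."""
        rows, cols = np.nonzero(~self._nodata_mask)
        lon, lat = self.spec.cell_center(rows, cols)
        data = {"row": rows, "col": cols, "lon": lon, "lat": lat}
        for name, grid in self.layers.items():
            data[name] = grid[rows, cols]
        return pd.DataFrame(data)

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", grid, self.spec)

    @classmethod
    def read_dir(cls, directory, names: list[str] | None = None) -> "EnvironmentalStack":
        directory = Path(directory)
        if names is None:
            names = sorted(p.stem for p in directory.glob("*.asc"))
        layers = {}
        spec = None
        for name in names:
            grid, s = read_ascii_grid(directory / f"{name}.asc")
            if spec is None:
                spec = s
            elif s != spec:
                raise ValueError(f"layer {name!r} grid geometry differs from the stack")
            layers[name] = grid
        if spec is None:
            raise ValueError(f"no .asc layers found in {directory}")
        return cls(spec, layers)


@dataclass
class SuitabilityMap:
    """Per-cell suitability/probability surface in [0, 1], NaN for nodata."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_conformal(self.spec, self.values, "suitability")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def at_points(self, lon, lat) -> np.ndarray:
        row, col = self.spec.cell_of(lon, lat)
        return self.values[row, col]

    def write(self, path) -> None:
        write_ascii_grid(path, self.values, self.spec)

    @classmethod
    def read(cls, path) -> "SuitabilityMap":
        grid, spec = read_ascii_grid(path)
        return cls(spec, grid)


@dataclass
class LandCoverGrid:
    """Categorical land-cover codes plus a code -> category mapping.

    Categories are ``anthropogenic``, ``natural`` and ``other``. Codes are
    integers; nodata cells carry a negative sentinel (-1).
    """

    spec: GridSpec
    codes: np.ndarray
    mapping: dict[int, str] = field(default_factory=dict)

    VALID_CATEGORIES = ("anthropogenic", "natural", "other")

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.spec.shape:
            raise ValueError("codes grid does not conform to GridSpec")
        for code, cat in self.mapping.items():
            if cat not in self.VALID_CATEGORIES:
                raise ValueError(f"category {cat!r} for code {code} is not recognised")
        present = np.unique(self.codes[self.codes >= 0])
        missing = [int(c) for c in present if int(c) not in self.mapping]
        if missing:
            raise ValueError(f"land-cover codes without category mapping: {missing}")

    def category_grid(self) -> np.ndarray:
        """Object array of category names ('' where nodata)."""
        out = np.full(self.spec.shape, "", dtype=object)
        for code, cat in self.mapping.items():
            out[self.codes == code] = cat
        return out


# -- distance and local projection ------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_xy_km(lon, lat, lon0: float | None = None, lat0: float | None = None):
    """Project points to planar km via a local azimuthal equidistant mapping.

    Distances from the reference point (default: the centroid of the input)
    are exact great-circle distances; adequate for laying out spatial blocks
    at the few-hundred-km scale.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


# -- ESRI ASCII grid I/O ------------------------------------------------------

def write_ascii_grid(path, grid: np.ndarray, spec: GridSpec) -> None:
    """Write one layer as an ESRI ASCII grid (NaN -> nodata sentinel)."""
    grid = _check_conformal(spec, grid)
    path = Path(path)
    min_lon, min_lat, _, _ = spec.bounds
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {min_lon!r}\n"
        f"yllcorner {min_lat!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    out = np.where(np.isnan(grid), spec.nodata, grid)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (grid with NaN nodata, GridSpec)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    spec = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata=header.get("nodata_value", -9999.0),
    )
    data = data.reshape(spec.shape)
    data = np.where(data == spec.nodata, np.nan, data)
    return data, spec
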