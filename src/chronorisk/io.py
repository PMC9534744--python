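"""Readers and writers for the pipeline's file formats.

Occurrence tables are plain CSV (``id,lon,lat,year,source``), raster layers
are ESRI ASCII grids (text, one file per layer and time slice), and range
polygons are GeoJSON.  All coordinates are WGS84 decimal degrees.

Internally raster arrays are indexed ``[slice, iy, ix]`` with ``iy = 0`` the
southernmost row, matching :class:`~chronorisk.grids.GridSpec`; the
north-up orientation of the ASCII format is flipped on read/write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec

__all__ = [
    "OccurrenceRecord",
    "CovariateStack",
    "FormatError",
    "AlignmentError",
    "read_occurrences",
    "write_occurrences",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
    "write_raster_stack",
    "read_range_polygon",
    "write_range_polygon",
]

OCCURRENCE_COLUMNS = ["id", "lon", "lat", "year", "source"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AlignmentError(ValueError):
    """Raster layers do not share a common grid."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated, georeferenced sighting."""

    id: int
    lon: float
    lat: float
    year: int
    source: str  # "historical" or "extant"


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Parse an occurrence CSV, rejecting malformed rows with their indices.

    Raises :class:`FormatError` naming missing columns, or listing the
    0-based row indices (and reasons) of rows with unparseable years or
    out-of-range coordinates.  Nothing is silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"occurrence CSV {path} missing columns {missing}")
    errors: list[str] = []
    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rid = int(row.id)
            lon = float(row.lon)
            lat = float(row.lat)
            year = int(float(row.year))
        except (TypeError, ValueError):
            errors.append(f"row {i}: unparseable numeric field")
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            errors.append(f"row {i}: coordinates ({lon},{lat}) out of range")
            continue
        records.append(OccurrenceRecord(rid, lon, lat, year, str(row.source)))
    if errors:
        raise FormatError(f"invalid rows in {path}: " + "; ".join(errors))
    return records


def write_occurrences(records: list[OccurrenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.id, r.lon, r.lat, r.year, r.source) for r in records],
        columns=OCCURRENCE_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")


def occurrences_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.id, r.lon, r.lat, r.year, r.source) for r in records],
        columns=OCCURRENCE_COLUMNS,
    )


@dataclass
class CovariateStack:
    """Named raster layers on a common grid, optionally over time slices.

    ``layers[name]`` has shape ``(n_slices, n_y, n_x)``; static stacks have a
    single slice.  ``valid`` is the per-cell validity mask: the complement of
    the union of the layers' nodata cells.
    """

    grid: GridSpec
    years: np.ndarray  # start year of each time slice, ascending
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    valid: np.ndarray | None = None  # (n_y, n_x) bool

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        ny, nx = self.grid.n_y, self.grid.n_x
        for name, arr in self.layers.items():
            if arr.shape != (len(self.years), ny, nx):
                raise AlignmentError(
                    f"layer '{name}' has shape {arr.shape}, expected {(len(self.years), ny, nx)}"
                )
        if self.valid is None:
            self.valid = np.ones((ny, nx), dtype=bool)
            for arr in self.layers.values():
                self.valid &= np.isfinite(arr).all(axis=0)

    @property
    def n_slices(self) -> int:
        return len(self.years)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def slice_for_year(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year, side="right") - 1)
        if idx < 0 or idx >= self.n_slices:
            raise KeyError(f"no time slice covers year {year}")
        return idx

    def values_at_cells(self, name: str, cell_ids, slice_index: int = 0) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"unknown layer '{name}'; have {self.names}")
        cell_ids = np.asarray(cell_ids)
        iy, ix = cell_ids // self.grid.n_x, cell_ids % self.grid.n_x
        return self.layers[name][slice_index, iy, ix]

    def valid_cell_ids(self) -> np.ndarray:
        iy, ix = np.nonzero(self.valid)
        return np.sort(iy * self.grid.n_x + ix)

    def env_matrix(self, cell_ids, names: list[str] | None = None, slice_index: int = 0) -> pd.DataFrame:
        """Environment table (cells x variables) at one time slice."""
        names = names if names is not None else self.names
        data = {n: self.values_at_cells(n, cell_ids, slice_index) for n in names}
        return pd.DataFrame(data, index=np.asarray(cell_ids))


# --- ESRI ASCII grid -------------------------------------------------------

def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read one ESRI ASCII grid; returns (array[iy, ix] south-up, grid, nodata).

    Nodata cells come back as NaN.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ESRI ASCII header field '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != (nrows, ncols):
        raise FormatError(f"{path}: data shape {data.shape} != header ({nrows},{ncols})")
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    grid = GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"], ncols, nrows)
    return data[::-1], grid, nodata  # flip to south-up


def write_ascii_grid(arr: np.ndarray, grid: GridSpec, path: str | Path, nodata: float = -9999.0) -> None:
    out = np.where(np.isfinite(arr), arr, nodata)[::-1]  # north-up on disk
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.n_x}\nnrows {grid.n_y}\n"
            f"xllcorner {grid.origin_lon:.10g}\nyllcorner {grid.origin_lat:.10g}\n"
            f"cellsize {grid.cell_degrees:.10g}\nNODATA_value {nodata:.10g}\n"
        )
        np.savetxt(fh, out, fmt="%.8g")


def read_raster_stack(paths: dict[str, list[str | Path]], years: list[int]) -> CovariateStack:
    """Assemble aligned ASCII layers into a stack.

    ``paths[name]`` lists one file per time slice, ordered as ``years``.
    All layers must share shape, origin and cell size; the stack's validity
    mask is the complement of the union of all layers' nodata cells.
    """
    ref_grid: GridSpec | None = None
    ref_name = ""
    layers: dict[str, np.ndarray] = {}
    for name, files in paths.items():
        if len(files) != len(years):
            raise AlignmentError(f"layer '{name}': {len(files)} files for {len(years)} slices")
        slices = []
        for f in files:
            arr, grid, _ = read_ascii_grid(f)
            if ref_grid is None:
                ref_grid, ref_name = grid, name
            elif grid != ref_grid:
                raise AlignmentError(
                    f"layer '{name}' ({f}) grid {grid} does not match layer '{ref_name}' grid {ref_grid}"
                )
            slices.append(arr)
        layers[name] = np.stack(slices)
    if ref_grid is None:
        raise FormatError("empty raster stack")
    return CovariateStack(ref_grid, np.asarray(years), layers)


def write_raster_stack(stack: CovariateStack, out_dir: str | Path) -> dict[str, list[str]]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {}
    for name, arr in stack.layers.items():
        written[name] = []
        for k, year in enumerate(stack.years):
            layer = np.where(stack.valid, arr[k], np.nan)
            path = out_dir / f"{name}_{year}.asc"
            write_ascii_grid(layer, stack.grid, path)
            written[name].append(str(path))
    return written


# --- GeoJSON range polygon -------------------------------------------------

def read_range_polygon(path: str | Path) -> BaseGeometry:
    """Read a Polygon/MultiPolygon from a GeoJSON geometry or Feature."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    elif obj.get("type") == "FeatureCollection":
        feats = obj["features"]
        if len(feats) != 1:
            raise FormatError(f"{path}: expected exactly one feature, got {len(feats)}")
        obj = feats[0]["geometry"]
    geom = shape(obj)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise FormatError(f"{path}: expected (Multi)Polygon, got {geom.geom_type}")
    if not geom.is_valid and not geom.is_empty:
        raise FormatError(f"{path}: invalid polygon geometry")
    return geom


def write_range_polygon(geom: BaseGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"type": "Feature", "properties": {}, "geometry": mapping(geom)}))
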