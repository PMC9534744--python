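"""Spatial grid and temporal period definitions.

Cells and periods are half-open: a cell covers [west, east) x [south, north)
and a period covers [start, start + length) years.  Points on the east or
north edge of the whole domain are assigned to the last cell so the grid
tiles the closed domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "PeriodSpec", "OutOfDomainError"]


class OutOfDomainError(ValueError):
    """A point or year falls outside the gridded study domain."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid in decimal degrees (WGS84).

    Cell ids are row-major: ``cell_id = iy * n_x + ix`` with ix counting
    eastward from ``origin_lon`` and iy northward from ``origin_lat``.
    """

    origin_lon: float
    origin_lat: float
    cell_degrees: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.cell_degrees <= 0:
            raise ValueError("cell_degrees must be > 0")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def east(self) -> float:
        return self.origin_lon + self.n_x * self.cell_degrees

    @property
    def north(self) -> float:
        return self.origin_lat + self.n_y * self.cell_degrees

    def assign_xy(self, lon, lat):
        """Vectorised (ix, iy) for points; raises OutOfDomainError outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        bad = (lon < self.origin_lon) | (lon > self.east) | (lat < self.origin_lat) | (lat > self.north)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))
            raise OutOfDomainError(f"points outside grid domain at positions {idx.tolist()}")
        ix = np.floor((lon - self.origin_lon) / self.cell_degrees).astype(int)
        iy = np.floor((lat - self.origin_lat) / self.cell_degrees).astype(int)
        # closed east/north domain edge folds into the last cell
        ix = np.minimum(ix, self.n_x - 1)
        iy = np.minimum(iy, self.n_y - 1)
        return ix, iy

    def cell_id(self, ix, iy):
        return np.asarray(iy) * self.n_x + np.asarray(ix)

    def cell_center(self, cell_id):
        cell_id = np.asarray(cell_id)
        ix = cell_id % self.n_x
        iy = cell_id // self.n_x
        lon = self.origin_lon + (ix + 0.5) * self.cell_degrees
        lat = self.origin_lat + (iy + 0.5) * self.cell_degrees
        return lon, lat

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of one cell."""
        ix = cell_id % self.n_x
        iy = cell_id // self.n_x
        w = self.origin_lon + ix * self.cell_degrees
        s = self.origin_lat + iy * self.cell_degrees
        return w, s, w + self.cell_degrees, s + self.cell_degrees


@dataclass(frozen=True)
class PeriodSpec:
    """Consecutive half-open periods tiling the study window."""

    start_year: int
    length_years: int
    n_periods: int

    def __post_init__(self) -> None:
        if self.length_years < 1 or self.n_periods < 1:
            raise ValueError("length_years and n_periods must be >= 1")

    @property
    def end_year(self) -> int:
        return self.start_year + self.length_years * self.n_periods

    def bin_year(self, year):
        """Period index of the half-open period containing ``year``."""
        year = np.asarray(year)
        out = (year < self.start_year) | (year >= self.end_year)
        if np.any(out):
            idx = np.flatnonzero(np.atleast_1d(out))
            raise OutOfDomainError(
                f"years outside study window [{self.start_year},{self.end_year}) "
                f"at positions {idx.tolist()}"
            )
        return ((year - self.start_year) // self.length_years).astype(int)

    def period_years(self, index: int) -> tuple[int, int]:
        """[start, end) years of one period."""
        s = self.start_year + index * self.length_years
        return s, s + self.length_years
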