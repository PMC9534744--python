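"""Extinction-record screening: range/buffer tests, rarefaction, Ripley's K.

A historical record from the screening window counts as a local-extinction
occurrence when it lies outside the current range polygon AND farther than
the buffer radius from every extant record.  Both marginal counts (outside
range; outside all buffers) are reported alongside the intersection, since
range-map and buffer screens overlap.

All distances are great-circle (haversine) kilometres on a sphere of radius
6371.0088 km; coordinates are WGS84 decimal degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "pairwise_haversine_km",
    "screen_extinctions",
    "rarefy",
    "ripley_k",
    "KFunctionResult",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lon_a, lat_a, lon_b, lat_b) -> np.ndarray:
    """(len(a), len(b)) distance matrix in km."""
    lon_a, lat_a = np.atleast_1d(lon_a), np.atleast_1d(lat_a)
    lon_b, lat_b = np.atleast_1d(lon_b), np.atleast_1d(lat_b)
    return haversine_km(lon_a[:, None], lat_a[:, None], lon_b[None, :], lat_b[None, :])


def screen_extinctions(
    historical: pd.DataFrame,
    extant: pd.DataFrame,
    range_polygon: BaseGeometry,
    buffer_km: float,
    year_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag extinction records among historical occurrences.

    Parameters
    ----------
    historical, extant : occurrence tables (``id, lon, lat, year, source``).
    range_polygon : current distribution range; may be empty, in which case
        every record is outside it.
    buffer_km : radius of the circular buffer around each extant record.
    year_range : optional half-open (start, end) filter applied to
        ``historical['year']`` before screening.

    Returns the screened table (input columns plus ``outside_range``,
    ``outside_buffers``, ``is_extinction``) and a count dictionary with the
    two marginal bins and the final intersection.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be > 0")
    if range_polygon is not None and not range_polygon.is_empty and not range_polygon.is_valid:
        raise ValueError("invalid range polygon geometry")
    df = historical.copy()
    if year_range is not None:
        df = df[(df["year"] >= year_range[0]) & (df["year"] < year_range[1])].reset_index(drop=True)

    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    if range_polygon is None or range_polygon.is_empty:
        inside = np.zeros(len(df), dtype=bool)
    else:
        inside = shapely.contains_xy(range_polygon, lon, lat)
    df["outside_range"] = ~inside

    if len(extant) == 0:
        df["outside_buffers"] = True  # vacuously outside all (zero) buffers
    else:
        d = pairwise_haversine_km(lon, lat, extant["lon"].to_numpy(), extant["lat"].to_numpy())
        df["outside_buffers"] = d.min(axis=1) > buffer_km if len(df) else np.zeros(0, bool)

    df["is_extinction"] = df["outside_range"] & df["outside_buffers"]
    counts = {
        "n_screened": int(len(df)),
        "outside_range": int(df["outside_range"].sum()),
        "outside_buffers": int(df["outside_buffers"].sum()),
        "total_extinction": int(df["is_extinction"].sum()),
    }
    return df, counts


def rarefy(records: pd.DataFrame, min_km: float, cell_arcmin: float = 5.0) -> pd.DataFrame:
    """Spatially thin records: greedy minimum-distance pass, then one per cell.

    Records are visited in ascending ``id`` order; a record is kept iff it
    lies at least ``min_km`` from every already-kept record.  A second pass
    enforces at most one record per ``cell_arcmin`` grid cell (lowest id
    wins).  Fully deterministic.
    """
    if min_km <= 0:
        raise ValueError("min_km must be > 0")
    df = records.sort_values("id", kind="stable").reset_index(drop=True)
    if len(df) == 0:
        return df
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if np.min(d) >= min_km:
            kept.append(i)
    out = df.iloc[kept]
    cell_deg = cell_arcmin / 60.0
    cx = np.floor(out["lon"].to_numpy() / cell_deg).astype(int)
    cy = np.floor(out["lat"].to_numpy() / cell_deg).astype(int)
    out = out.assign(_cx=cx, _cy=cy).drop_duplicates(["_cx", "_cy"], keep="first")
    return out.drop(columns=["_cx", "_cy"]).reset_index(drop=True)


@dataclass
class KFunctionResult:
    """Ripley's K of a point set plus a Monte-Carlo CSR envelope."""

    radii_km: np.ndarray
    k_hat: np.ndarray  # km^2
    csr: np.ndarray  # pi r^2
    l_minus_r: np.ndarray  # km
    envelope_low: np.ndarray | None = None
    envelope_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"radius_km": self.radii_km, "k_hat": self.k_hat,
                           "csr_pi_r2": self.csr, "l_minus_r": self.l_minus_r})
        if self.envelope_low is not None:
            df["envelope_low"] = self.envelope_low
            df["envelope_high"] = self.envelope_high
        return df


def _k_estimate(lon, lat, radii, area_km2) -> np.ndarray:
    n = len(lon)
    d = pairwise_haversine_km(lon, lat, lon, lat)
    iu = ~np.eye(n, dtype=bool)
    pair_d = d[iu]
    counts = np.array([(pair_d <= r).sum() for r in radii], dtype=float)
    return area_km2 * counts / (n * n)


def ripley_k(
    records: pd.DataFrame,
    radii_km: np.ndarray,
    bbox: tuple[float, float, float, float],
    n_sims: int = 99,
    rng: np.random.Generator | None = None,
) -> KFunctionResult:
    """Ripley's K-hat (no edge correction) with a CSR simulation envelope.

    K-hat(r) = (A / n^2) * sum_{i != j} 1[d_ij <= r], with A the bounding-box
    area in km^2 (computed on the sphere).  The envelope is the pointwise
    min/max of ``n_sims`` uniform point sets of the same size in the box.
    Under complete spatial randomness K(r) = pi r^2.
    """
    if len(records) < 2:
        raise ValueError("ripley_k needs at least 2 records")
    radii = np.asarray(radii_km, dtype=float)
    w, s, e, n_ = bbox
    # spherical area of the lon/lat box
    area = (
        EARTH_RADIUS_KM**2 * np.radians(e - w)
        * (np.sin(np.radians(n_)) - np.sin(np.radians(s)))
    )
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    k_hat = _k_estimate(lon, lat, radii, area)
    csr = np.pi * radii**2
    l_minus_r = np.sqrt(np.maximum(k_hat, 0.0) / np.pi) - radii

    lo = hi = None
    if n_sims > 0:
        rng = rng or np.random.default_rng()
        sims = np.empty((n_sims, len(radii)))
        for i in range(n_sims):
            u = rng.random(len(lon))
            # uniform on the sphere within the box: lat via inverse-CDF of sin
            slat = np.degrees(np.arcsin(
                np.sin(np.radians(s)) + u * (np.sin(np.radians(n_)) - np.sin(np.radians(s)))
            ))
            slon = w + rng.random(len(lon)) * (e - w)
            sims[i] = _k_estimate(slon, slat, radii, area)
        lo, hi = sims.min(axis=0), sims.max(axis=0)
    return KFunctionResult(radii, k_hat, csr, l_minus_r, lo, hi)
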