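"""Synthetic chronicle generator with known extinction ground truth.

Emulates the inputs of a chronicle-based extinction analysis: decadal
covariate rasters over a 0.5-degree grid (human population and land use,
a rising holistic temperature proxy, regional temperature, bioclim-style
layers), dated occurrence records produced by imperfect detection of
occupied cells, an extant record set for the final period, and a current
range polygon.

The data-generating model is a discrete-time hazard: a cell occupied in
period *p* goes locally extinct entering period *p+1* with probability

    logistic(beta0 + beta_temp * z_temp + beta_pop * z_logpop + s(lon, lat))

where z_temp is the standardized temperature proxy, z_logpop the
standardized log population count, and s a smooth low-frequency spatial
surface (two sinusoids).  There is no recolonization.  Detection of an
occupied cell in a period is Bernoulli(detection_prob); each detection
yields a record dated uniformly within the period and placed uniformly
within the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec, PeriodSpec
from .io import CovariateStack

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_covariates",
    "simulate_chronicles",
    "simulate_extant_and_range",
    "simulate_all",
]

KM2_PER_CELL = 2500.0  # nominal area of a 0.5-degree cell at mid latitudes


@dataclass
class SimulationParams:
    """Knobs of the synthetic chronicle world.

    Defaults mirror the study conditions: a 66 x 66 grid of 0.5-degree cells
    spanning a China-sized domain (97-130 E, 18-51 N), ten 30-year periods
    over 1700-2000 with decadal covariate slices, and hazard coefficients
    (log-odds per standard deviation) that produce a realistic mid-range
    extinction fraction with a dominant temperature trend.
    """

    n_cells_x: int = 66
    n_cells_y: int = 66
    origin_lon: float = 97.0
    origin_lat: float = 18.0
    cell_degrees: float = 0.5
    study_start: int = 1700
    period_years: int = 30
    n_periods: int = 10
    slice_years: int = 10
    beta0: float = -2.0
    beta_temp: float = 1.0
    beta_pop: float = 0.75
    spatial_effect_amplitude: float = 0.75
    detection_prob: float = 0.7
    temp_trend: float = 0.2
    temp_noise_sd: float = 0.3
    initial_occupancy: float = 1.0
    n_extant: int = 159
    range_erosion_cells: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in [0,1]")
        if not 0.0 <= self.initial_occupancy <= 1.0:
            raise ValueError("initial_occupancy must lie in [0,1]")
        if self.n_periods < 2:
            raise ValueError("n_periods must be >= 2")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin_lon, self.origin_lat, self.cell_degrees, self.n_cells_x, self.n_cells_y)

    @property
    def periods(self) -> PeriodSpec:
        return PeriodSpec(self.study_start, self.period_years, self.n_periods)

    def rng(self, stream: int) -> np.random.Generator:
        # fixed per-stage sub-streams so each stage is independently reproducible
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """What actually happened: occupancy, extinction periods, coefficients."""

    occupancy: np.ndarray  # (n_periods, n_cells) bool
    first_extinct: np.ndarray  # (n_cells,) period index of first absence, -1 = never
    betas: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        n_periods, n_cells = self.occupancy.shape
        df = pd.DataFrame({"cell_id": np.arange(n_cells), "first_extinct": self.first_extinct})
        for p in range(n_periods):
            df[f"occ_{p}"] = self.occupancy[p].astype(int)
        return df


def _spatial_field(grid: GridSpec, amplitude: float, phase: float = 0.0) -> np.ndarray:
    """Smooth low-frequency surface: sum of two sinusoids in lon and lat."""
    lon, lat = grid.cell_center(np.arange(grid.n_cells))
    u = 2 * np.pi * (lon - grid.origin_lon) / (grid.east - grid.origin_lon)
    v = 2 * np.pi * (lat - grid.origin_lat) / (grid.north - grid.origin_lat)
    s = np.sin(u + phase) + np.cos(v + 0.5 * phase)
    return (amplitude * s / 2.0).reshape(grid.n_y, grid.n_x)


def simulate_covariates(params: SimulationParams) -> CovariateStack:
    """Generate decadal covariate layers over the study window.

    The temperature proxy rises linearly by ``temp_trend`` per 30-year
    period (plus slice-level noise shared across cells, like a holistic
    series); population layers grow roughly exponentially in expectation;
    land-use fractions stay in [0, 1]; bioclim-style layers are static
    spatial fields with small slice-level noise.
    """
    grid = params.grid
    rng = params.rng(1)
    years = np.arange(params.study_start, params.study_start + params.n_periods * params.period_years,
                      params.slice_years)
    n_s = len(years)
    ny, nx = grid.n_y, grid.n_x
    lon, lat = grid.cell_center(np.arange(grid.n_cells))
    lat2 = lat.reshape(ny, nx)

    t_frac = (years - params.study_start) / params.period_years  # in periods
    # holistic temperature proxy (d18O-like, per mil): one value per slice
    temp_series = -10.0 + params.temp_trend * t_frac + rng.normal(0, params.temp_noise_sd, n_s)
    temperature = np.broadcast_to(temp_series[:, None, None], (n_s, ny, nx)).copy()

    regional = (
        26.0 - 0.55 * (lat2 - grid.origin_lat)[None] + 0.5 * params.temp_trend * t_frac[:, None, None]
        + rng.normal(0, 0.3, (n_s, ny, nx))
    )

    s_pop = _spatial_field(grid, 1.0, phase=1.3)  # where people live, in [-1, 1]
    growth = np.exp(0.0072 * (years - params.study_start))  # ~8.6x over 300 y
    popd_base = 4.0 * np.exp(1.6 * (s_pop + 1.0))
    popd = popd_base[None] * growth[:, None, None] * np.exp(rng.normal(0, 0.05, (n_s, ny, nx)))
    popc = popd * KM2_PER_CELL

    sat = popd / (popd + 150.0)  # land-use saturates with density
    cropland = np.clip(0.85 * sat + rng.normal(0, 0.02, (n_s, ny, nx)), 0.0, 1.0)
    sat_g = popd / (popd + 400.0)  # pasture expands with population, more slowly than cropland
    grazing = np.clip(0.5 * sat_g * (0.5 - 0.3 * s_pop[None]) + rng.normal(0, 0.02, (n_s, ny, nx)), 0.0, 1.0)
    uopp = np.clip(0.05 * sat ** 2 + rng.normal(0, 0.003, (n_s, ny, nx)), 0.0, 1.0)

    def static(base, amp, phase, noise):
        f = base + amp * _spatial_field(grid, 1.0, phase=phase)
        return np.clip(f[None] + rng.normal(0, noise, (n_s, ny, nx)), 0.0, None)

    layers = {
        "popd": popd,
        "popc": popc,
        "cropland": cropland,
        "grazing": grazing,
        "uopp": uopp,
        "temperature": temperature,
        "regional_temperature": regional,
        "bio3": static(40.0, 10.0, 2.1, 0.5),
        "bio7": static(30.0, 8.0, 0.7, 0.4),
        "bio8": np.clip(24.0 - 0.45 * (lat2 - grid.origin_lat)[None] + rng.normal(0, 0.4, (n_s, ny, nx)), -5, None),
        "bio14": static(20.0, 15.0, 4.0, 1.0),
    }
    return CovariateStack(grid, years, layers)


def _period_mean(stack: CovariateStack, name: str, periods: PeriodSpec) -> np.ndarray:
    """(n_periods, n_cells) period-averaged layer values."""
    out = np.empty((periods.n_periods, stack.grid.n_cells))
    arr = stack.layers[name]
    for p in range(periods.n_periods):
        s, e = periods.period_years(p)
        idx = (stack.years >= s) & (stack.years < e)
        out[p] = arr[idx].mean(axis=0).ravel()
    return out


def hazard_logits(params: SimulationParams, stack: CovariateStack) -> np.ndarray:
    """(n_periods, n_cells) extinction log-odds of failing to persist through each period.

    Row p holds the log-odds that a cell occupied in period p-1 is extinct in
    period p, as a function of period-p covariates (the conditions the
    population failed to survive).  Row 0 is unused.
    """
    periods = params.periods
    temp = _period_mean(stack, "temperature", periods)
    logpop = np.log1p(_period_mean(stack, "popc", periods))
    z_temp = (temp - temp.mean()) / (temp.std() or 1.0)
    z_pop = (logpop - logpop.mean()) / (logpop.std() or 1.0)
    spatial = _spatial_field(params.grid, params.spatial_effect_amplitude).ravel()
    return params.beta0 + params.beta_temp * z_temp + params.beta_pop * z_pop + spatial[None]


def simulate_chronicles(
    params: SimulationParams, stack: CovariateStack
) -> tuple[pd.DataFrame, GroundTruth]:
    """Run the occupancy/extinction process and the detection process.

    Returns the historical occurrence table (occurrence-CSV schema, source
    ``historical``) and the :class:`GroundTruth`.
    """
    grid, periods = params.grid, params.periods
    if stack.n_slices * params.slice_years < periods.n_periods * periods.length_years:
        raise ValueError("covariate stack does not cover all periods")
    rng = params.rng(2)
    n_cells = grid.n_cells
    eta = hazard_logits(params, stack)
    hazard = 1.0 / (1.0 + np.exp(-eta))

    occ = np.zeros((periods.n_periods, n_cells), dtype=bool)
    occ[0] = rng.random(n_cells) < params.initial_occupancy
    first_extinct = np.full(n_cells, -1, dtype=int)
    for p in range(periods.n_periods - 1):
        die = occ[p] & (rng.random(n_cells) < hazard[p + 1])
        occ[p + 1] = occ[p] & ~die
        first_extinct[die & (first_extinct < 0)] = p + 1

    detected = occ & (rng.random(occ.shape) < params.detection_prob)
    per, cid = np.nonzero(detected)
    lon_w = grid.origin_lon + (cid % grid.n_x) * grid.cell_degrees
    lat_s = grid.origin_lat + (cid // grid.n_x) * grid.cell_degrees
    records = pd.DataFrame(
        {
            "id": np.arange(len(cid)),
            "lon": lon_w + rng.random(len(cid)) * grid.cell_degrees,
            "lat": lat_s + rng.random(len(cid)) * grid.cell_degrees,
            "year": periods.start_year + per * periods.length_years
            + rng.integers(0, periods.length_years, len(cid)),
            "source": "historical",
        }
    ).sort_values(["year", "id"], kind="stable").reset_index(drop=True)
    records["id"] = np.arange(len(records))
    truth = GroundTruth(occ, first_extinct, {
        "beta0": params.beta0, "beta_temp": params.beta_temp,
        "beta_pop": params.beta_pop, "spatial_amplitude": params.spatial_effect_amplitude,
    })
    return records, truth


def simulate_extant_and_range(
    truth: GroundTruth, params: SimulationParams
) -> tuple[pd.DataFrame, BaseGeometry]:
    """Sample extant-period records and build the current range polygon.

    Extant records are drawn from cells occupied in the final period, dated
    2000-2020.  The polygon is the union of final-period occupied cells,
    eroded by ``range_erosion_cells`` cell widths so that some surviving
    records fall outside it (as real expert range maps under-cover records).
    """
    grid = params.grid
    rng = params.rng(3)
    alive = np.flatnonzero(truth.occupancy[-1])
    if len(alive) == 0:
        empty = pd.DataFrame(columns=["id", "lon", "lat", "year", "source"])
        return empty, shapely.MultiPolygon([])
    cells = rng.choice(alive, size=min(params.n_extant, 10 * len(alive)), replace=True)
    lon_w = grid.origin_lon + (cells % grid.n_x) * grid.cell_degrees
    lat_s = grid.origin_lat + (cells // grid.n_x) * grid.cell_degrees
    extant = pd.DataFrame(
        {
            "id": np.arange(len(cells)),
            "lon": lon_w + rng.random(len(cells)) * grid.cell_degrees,
            "lat": lat_s + rng.random(len(cells)) * grid.cell_degrees,
            "year": rng.integers(2000, 2021, len(cells)),
            "source": "extant",
        }
    )
    boxes = [box(*grid.cell_bounds(int(c))) for c in alive]
    poly = shapely.unary_union(boxes)
    erosion = params.range_erosion_cells
    while erosion > 1e-3:
        eroded = poly.buffer(-erosion * grid.cell_degrees)
        if not eroded.is_empty:
            return extant, eroded
        erosion /= 2.0  # small occupied areas cannot absorb the full erosion
    return extant, poly


def simulate_all(params: SimulationParams):
    """Convenience: covariates, chronicles, extant set and range polygon."""
    stack = simulate_covariates(params)
    records, truth = simulate_chronicles(params, stack)
    extant, poly = simulate_extant_and_range(truth, params)
    return stack, records, truth, extant, poly
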