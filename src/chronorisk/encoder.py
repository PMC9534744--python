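"""Chronicle encoding: dated sightings -> gridded fate rows.

A *fate row* is the observation unit of the extinction model: one grid cell
in one period, coded 0 (presence) or 1 (absence after presence).  The coding
rule follows the chronicle convention: a cell's record of detections ends at
its last detection period, which is coded 0; if the species is never
detected in that cell again and the window has a following period, that next
period is coded 1.  Each local extinction event therefore contributes
exactly one 0-row and one 1-row; cells whose last detection falls in the
final period are right-censored and contribute only the 0-row.

Re-detection after a gap cancels any intervening absence (the rule keys on
the *last* detection, so interior gaps never produce 1-rows).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridSpec, PeriodSpec
from .io import CovariateStack

__all__ = ["assign_cell", "bin_period", "encode_fates", "attach_covariates", "CoverageError"]

FATE_COLUMNS = ["cell_id", "period", "fate", "lon", "lat"]


class CoverageError(ValueError):
    """The covariate stack does not cover a required period."""


def assign_cell(lon, lat, grid: GridSpec):
    """Cell id(s) containing the point(s); half-open cell convention."""
    ix, iy = grid.assign_xy(lon, lat)
    return grid.cell_id(ix, iy)


def bin_period(year, periods: PeriodSpec):
    """Period index(es) of the half-open period containing ``year``."""
    return periods.bin_year(year)


def encode_fates(
    records: pd.DataFrame,
    grid: GridSpec,
    periods: PeriodSpec,
    presence_rows: str = "last",
) -> pd.DataFrame:
    """Encode occurrence records into fate rows (covariates not yet attached).

    Parameters
    ----------
    records : DataFrame with columns ``lon``, ``lat``, ``year`` (the
        occurrence-CSV schema).  An empty frame yields an empty result.
    presence_rows : ``"last"`` places the single 0-row at the last detection
        period (the default, consistent with one 0-row plus one 1-row per
        extinction event); ``"all"`` emits a 0-row for every detected period
        (sensitivity-analysis variant).

    Returns a DataFrame with columns ``cell_id, period, fate, lon, lat``
    (lon/lat are cell centers), sorted by (cell_id, period, fate).
    """
    if presence_rows not in ("last", "all"):
        raise ValueError("presence_rows must be 'last' or 'all'")
    if len(records) == 0:
        return pd.DataFrame(columns=FATE_COLUMNS).astype(
            {"cell_id": int, "period": int, "fate": int, "lon": float, "lat": float}
        )
    cell = assign_cell(records["lon"].to_numpy(), records["lat"].to_numpy(), grid)
    period = bin_period(records["year"].to_numpy(), periods)
    det = pd.DataFrame({"cell_id": cell, "period": period}).drop_duplicates()

    rows: list[tuple[int, int, int]] = []
    for cid, grp in det.groupby("cell_id"):
        ps = np.sort(grp["period"].to_numpy())
        last = int(ps[-1])
        if presence_rows == "all":
            rows.extend((int(cid), int(p), 0) for p in ps)
        else:
            rows.append((int(cid), last, 0))
        if last < periods.n_periods - 1:
            rows.append((int(cid), last + 1, 1))

    out = pd.DataFrame(rows, columns=["cell_id", "period", "fate"])
    lon, lat = grid.cell_center(out["cell_id"].to_numpy())
    out["lon"], out["lat"] = lon, lat
    return out.sort_values(["cell_id", "period", "fate"]).reset_index(drop=True)


def attach_covariates(
    fates: pd.DataFrame,
    stack: CovariateStack,
    periods: PeriodSpec,
    names: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Attach period-averaged covariates to fate rows.

    The stack's time slices (e.g. decadal) are averaged arithmetically over
    each row's period.  Rows over nodata cells are dropped; the number
    dropped is returned alongside the table.

    Raises :class:`CoverageError` if any period has no covering time slice.
    """
    names = names if names is not None else stack.names
    if len(fates) == 0:
        out = fates.copy()
        for n in names:
            out[n] = np.nan
        return out, 0

    slice_sets: dict[int, np.ndarray] = {}
    for p in sorted(fates["period"].unique()):
        s, e = periods.period_years(int(p))
        idx = np.flatnonzero((stack.years >= s) & (stack.years < e))
        if len(idx) == 0:
            raise CoverageError(f"no covariate slice covers period {p} ({s}-{e})")
        slice_sets[int(p)] = idx

    out = fates.copy()
    cells = out["cell_id"].to_numpy()
    iy, ix = cells // stack.grid.n_x, cells % stack.grid.n_x
    per = out["period"].to_numpy()
    for n in names:
        arr = stack.layers[n]
        col = np.empty(len(out))
        for p, idx in slice_sets.items():
            sel = per == p
            col[sel] = arr[idx][:, iy[sel], ix[sel]].mean(axis=0)
        out[n] = col

    ok = stack.valid[iy, ix] & np.isfinite(out[names].to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    return out.loc[ok].reset_index(drop=True), n_dropped
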