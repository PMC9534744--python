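"""Grid/period binning and the chronicle fate-encoding rule."""

import numpy as np
import pandas as pd
import pytest

from chronorisk.encoder import assign_cell, attach_covariates, bin_period, encode_fates
from chronorisk.grids import GridSpec, OutOfDomainError, PeriodSpec

from conftest import make_stack


def encode_fates_oracle(detections: dict[int, set[int]], n_periods: int) -> set[tuple[int, int, int]]:
    """Literal restatement of the coding rule, cell by cell.

    The last detected period is a presence (0); the next period is an
    absence (1) unless the last detection sits in the final period.
    """
    rows = set()
    for cell, ps in detections.items():
        if not ps:
            continue
        last = max(ps)
        rows.add((cell, last, 0))
        if last < n_periods - 1:
            rows.add((cell, last + 1, 1))
    return rows


def frame_from_detections(detections, grid, periods):
    rows = []
    i = 0
    for cell, ps in detections.items():
        lon, lat = grid.cell_center(cell)
        for p in sorted(ps):
            rows.append({"id": i, "lon": float(lon), "lat": float(lat),
                         "year": periods.start_year + p * periods.length_years + 3,
                         "source": "historical"})
            i += 1
    return pd.DataFrame(rows)


class TestAssignCell:
    def test_interior_point(self):
        grid = GridSpec(100.0, 20.0, 0.5, 10, 10)
        assert assign_cell(100.25, 20.25, grid) == 0

    def test_interior_boundary_goes_east(self):
        grid = GridSpec(100.0, 20.0, 0.5, 10, 10)
        # lon exactly on the boundary between columns 0 and 1
        assert assign_cell(100.5, 20.25, grid) == 1

    def test_domain_edge_folds_into_last_cell(self):
        grid = GridSpec(100.0, 20.0, 0.5, 10, 10)
        assert assign_cell(105.0, 25.0, grid) == 99

    def test_outside_domain_raises(self):
        grid = GridSpec(100.0, 20.0, 0.5, 10, 10)
        with pytest.raises(OutOfDomainError):
            assign_cell(99.0, 20.5, grid)

    def test_agrees_with_bounding_box_scan(self):
        grid = GridSpec(100.0, 20.0, 0.5, 7, 5)
        rng = np.random.default_rng(3)
        lon = 100.0 + rng.random(1000) * 3.5
        lat = 20.0 + rng.random(1000) * 2.5
        got = assign_cell(lon, lat, grid)
        for i in range(len(lon)):
            hits = [
                c for c in range(grid.n_cells)
                if (lambda w, s, e, n: w <= lon[i] < e and s <= lat[i] < n)(*grid.cell_bounds(c))
            ]
            assert hits == [got[i]]


class TestBinPeriod:
    @pytest.mark.parametrize("year,expected", [(1700, 0), (1730, 1), (1999, 9), (1729, 0)])
    def test_half_open_binning(self, year, expected, periods10):
        assert bin_period(year, periods10) == expected

    @pytest.mark.parametrize("year", [1699, 2000])
    def test_outside_window_raises(self, year, periods10):
        with pytest.raises(OutOfDomainError):
            bin_period(year, periods10)


class TestEncodeFates:
    def test_detections_in_periods_0_and_2(self, grid10, periods10):
        # last detection period 2 -> presence row there, absence row at 3
        df = frame_from_detections({5: {0, 2}}, grid10, periods10)
        out = encode_fates(df, grid10, periods10)
        assert list(map(tuple, out[["cell_id", "period", "fate"]].to_numpy())) == [(5, 2, 0), (5, 3, 1)]

    def test_final_period_detection_is_right_censored(self, grid10, periods10):
        df = frame_from_detections({4: {9}}, grid10, periods10)
        out = encode_fates(df, grid10, periods10)
        assert list(map(tuple, out[["cell_id", "period", "fate"]].to_numpy())) == [(4, 9, 0)]

    def test_empty_input_gives_empty_output(self, grid10, periods10):
        out = encode_fates(pd.DataFrame(columns=["id", "lon", "lat", "year", "source"]), grid10, periods10)
        assert len(out) == 0

    def test_presence_rows_all_variant(self, grid10, periods10):
        df = frame_from_detections({5: {0, 2}}, grid10, periods10)
        out = encode_fates(df, grid10, periods10, presence_rows="all")
        assert list(map(tuple, out[["cell_id", "period", "fate"]].to_numpy())) == [
            (5, 0, 0), (5, 2, 0), (5, 3, 1)]

    def test_matches_enumeration_oracle_on_random_patterns(self):
        grid = GridSpec(100.0, 20.0, 0.5, 5, 4)
        periods = PeriodSpec(1700, 30, 5)
        rng = np.random.default_rng(11)
        for _ in range(100):
            detections = {
                c: set(np.flatnonzero(rng.random(5) < 0.4).tolist())
                for c in rng.choice(20, size=rng.integers(1, 20), replace=False)
            }
            detections = {c: ps for c, ps in detections.items() if ps}
            df = frame_from_detections(detections, grid, periods)
            if len(df) == 0:
                continue
            out = encode_fates(df, grid, periods)
            got = set(map(tuple, out[["cell_id", "period", "fate"]].to_numpy()))
            assert got == encode_fates_oracle(detections, 5)

    def test_row_pairing_invariant(self, small_world, small_params):
        _, records, truth, _, _ = small_world
        out = encode_fates(records, small_params.grid, small_params.periods)
        ones = out[out["fate"] == 1]
        zeros = out[out["fate"] == 0]
        assert len(ones) <= out["cell_id"].nunique()
        # every absence row has its presence row one period earlier, same cell
        merged = ones.merge(zeros, on="cell_id", suffixes=("_1", "_0"))
        assert (merged.groupby("cell_id").apply(
            lambda g: ((g["period_0"] == g["period_1"] - 1)).any(), include_groups=False
        )).all()
        # uncensored cells contribute exactly a (0,1) pair: rows = 2 x events
        uncensored = out[out["cell_id"].isin(ones["cell_id"])]
        assert len(uncensored) == 2 * len(ones)

    def test_record_order_permutation_invariance(self, small_world, small_params):
        _, records, _, _, _ = small_world
        out1 = encode_fates(records, small_params.grid, small_params.periods)
        shuffled = records.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out2 = encode_fates(shuffled, small_params.grid, small_params.periods)
        pd.testing.assert_frame_equal(out1, out2)


class TestAttachCovariates:
    def test_period_mean_of_slices(self, grid10, periods10):
        # slices valued 1,2,3 in period 0 -> mean 2.0
        stack = make_stack(grid10, [1700, 1710, 1720], {"v": lambda k, iy, ix: np.full(iy.shape, k + 1.0)})
        fates = pd.DataFrame({"cell_id": [0], "period": [0], "fate": [0], "lon": [100.25], "lat": [20.25]})
        out, dropped = attach_covariates(fates, stack, PeriodSpec(1700, 30, 1), ["v"])
        assert dropped == 0
        assert out["v"].tolist() == [2.0]

    def test_constant_layer_attaches_constant(self, grid10, periods10):
        years = np.arange(1700, 2000, 10)
        stack = make_stack(grid10, years, {"v": lambda k, iy, ix: np.full(iy.shape, 7.5)})
        fates = pd.DataFrame({"cell_id": [3, 42], "period": [1, 8], "fate": [0, 1],
                              "lon": [0.0, 0.0], "lat": [0.0, 0.0]})
        out, _ = attach_covariates(fates, stack, periods10, ["v"])
        assert (out["v"] == 7.5).all()

    def test_nodata_cell_rows_dropped_and_counted(self, grid10, periods10):
        years = np.arange(1700, 2000, 10)
        stack = make_stack(grid10, years, {"v": lambda k, iy, ix: np.ones(iy.shape)})
        stack.layers["v"][:, 0, 0] = np.nan
        stack.valid[0, 0] = False
        fates = pd.DataFrame({"cell_id": [0, 5], "period": [1, 1], "fate": [0, 0],
                              "lon": [0.0, 0.0], "lat": [0.0, 0.0]})
        out, dropped = attach_covariates(fates, stack, periods10, ["v"])
        assert dropped == 1
        assert out["cell_id"].tolist() == [5]

    def test_missing_slice_coverage_error(self, grid10):
        stack = make_stack(grid10, [1700, 1710, 1720], {"v": lambda k, iy, ix: np.ones(iy.shape)})
        fates = pd.DataFrame({"cell_id": [0], "period": [5], "fate": [0], "lon": [0.0], "lat": [0.0]})
        from chronorisk.encoder import CoverageError
        with pytest.raises(CoverageError):
            attach_covariates(fates, stack, PeriodSpec(1700, 30, 10), ["v"])
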