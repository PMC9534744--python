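"""Distance screening, spatial rarefaction and Ripley's K."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from chronorisk.screening import (
    EARTH_RADIUS_KM,
    haversine_km,
    pairwise_haversine_km,
    rarefy,
    ripley_k,
    screen_extinctions,
)


def occ(rows):
    return pd.DataFrame(rows, columns=["id", "lon", "lat", "year", "source"])


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(100.0, 20.0, 100.0, 20.0) == 0.0

    def test_one_degree_meridian_arc(self):
        # closed form: pi * R / 180
        expected = np.pi * EARTH_RADIUS_KM / 180.0
        assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(expected, abs=0.01)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        a = rng.uniform([-180, -90], [180, 90], (100, 2))
        b = rng.uniform([-180, -90], [180, 90], (100, 2))
        d1 = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d1, d2, rtol=1e-12)


class TestScreenExtinctions:
    POLY = box(100.0, 20.0, 102.0, 22.0)

    def test_record_coincident_with_extant_is_not_extinction(self):
        hist = occ([(0, 99.0, 19.0, 1980, "historical")])
        ext = occ([(0, 99.0, 19.0, 2010, "extant")])
        df, counts = screen_extinctions(hist, ext, self.POLY, 50.0)
        assert counts["total_extinction"] == 0
        assert bool(df["outside_range"].iloc[0]) is True

    def test_record_just_beyond_buffer_and_outside_range_is_extinction(self):
        # 0.459 degrees of latitude ~ 51 km > 50 km buffer
        hist = occ([(0, 99.0, 19.459, 1980, "historical")])
        ext = occ([(0, 99.0, 19.0, 2010, "extant")])
        assert haversine_km(99.0, 19.459, 99.0, 19.0) > 50.0
        _, counts = screen_extinctions(hist, ext, self.POLY, 50.0)
        assert counts["total_extinction"] == 1

    def test_bin_counts_match_hand_built_fixture(self):
        # 3 outside polygon only (inside buffer), 5 outside buffers only
        # (inside polygon), 2 outside both
        ext = occ([(0, 99.0, 19.0, 2010, "extant")])
        rows = []
        rid = 0
        for _ in range(3):  # outside polygon, within 50 km of the extant point
            rows.append((rid, 99.1, 19.1, 1980, "historical")); rid += 1
        for _ in range(5):  # inside polygon, far from the extant point
            rows.append((rid, 101.5, 21.5, 1980, "historical")); rid += 1
        for _ in range(2):  # outside both
            rows.append((rid, 104.0, 24.0, 1980, "historical")); rid += 1
        df, counts = screen_extinctions(occ(rows), ext, self.POLY, 50.0)
        assert counts["outside_range"] == 5  # 3 near + 2 far
        assert counts["outside_buffers"] == 7  # 5 inside polygon + 2 far
        assert counts["total_extinction"] == 2

    def test_buffer_enlargement_never_increases_extinctions(self, uniform_records):
        ext = occ([(0, 102.0, 22.0, 2010, "extant"), (1, 104.0, 24.0, 2012, "extant")])
        prev = None
        for buffer_km in (10.0, 50.0, 150.0, 400.0):
            _, counts = screen_extinctions(uniform_records, ext, self.POLY, buffer_km)
            if prev is not None:
                assert counts["total_extinction"] <= prev
            prev = counts["total_extinction"]

    def test_no_extant_records_makes_buffers_vacuous(self, uniform_records):
        empty = occ([])
        df, counts = screen_extinctions(uniform_records, empty, self.POLY, 50.0)
        assert (df["outside_buffers"]).all()
        assert counts["total_extinction"] == counts["outside_range"]

    def test_year_window_filter(self, uniform_records):
        df, counts = screen_extinctions(uniform_records, occ([]), self.POLY, 50.0, (1970, 2000))
        assert counts["n_screened"] == ((uniform_records["year"] >= 1970)
                                        & (uniform_records["year"] < 2000)).sum()


class TestRarefy:
    def test_close_pair_thins_to_one(self):
        df = occ([(0, 100.0, 20.0, 1980, "h"), (1, 100.0, 20.045, 1980, "h")])  # ~5 km
        assert len(rarefy(df, 10.0)) == 1

    def test_distant_pair_in_distinct_cells_both_kept(self):
        df = occ([(0, 100.0, 20.0, 1980, "h"), (1, 100.0, 20.135, 1980, "h")])  # ~15 km
        assert len(rarefy(df, 10.0)) == 2

    def test_min_distance_property_brute_force(self):
        rng = np.random.default_rng(1)
        df = occ([(i, 100 + rng.random() * 2, 20 + rng.random() * 2, 1980, "h") for i in range(200)])
        kept = rarefy(df, 10.0)
        d = pairwise_haversine_km(kept["lon"], kept["lat"], kept["lon"], kept["lat"])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        df = occ([(i, 100 + rng.random() * 2, 20 + rng.random() * 2, 1980, "h") for i in range(150)])
        once = rarefy(df, 10.0)
        twice = rarefy(once, 10.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_one_record_per_five_arcmin_cell(self):
        # >10 km apart but same 5-arcmin cell is impossible at 5'; use a
        # coarse cell size to exercise the per-cell uniqueness pass
        df = occ([(0, 100.01, 20.01, 1980, "h"), (1, 100.40, 20.40, 1980, "h")])
        kept = rarefy(df, 10.0, cell_arcmin=60.0)
        assert kept["id"].tolist() == [0]


class TestRipleyK:
    def test_two_points_radius_below_distance(self):
        df = occ([(0, 100.0, 20.0, 1980, "h"), (1, 100.0, 21.0, 1980, "h")])
        kf = ripley_k(df, [50.0], (99.5, 19.5, 100.5, 21.5), n_sims=0)
        assert kf.k_hat[0] == 0.0

    def test_two_points_radius_above_distance_equals_half_area(self):
        # K = A * 2 / 4 = A/2 when both ordered pairs are within r
        df = occ([(0, 100.0, 20.0, 1980, "h"), (1, 100.0, 21.0, 1980, "h")])
        bbox = (99.5, 19.5, 100.5, 21.5)
        kf = ripley_k(df, [150.0], bbox, n_sims=0)
        area = (EARTH_RADIUS_KM**2 * np.radians(1.0)
                * (np.sin(np.radians(21.5)) - np.sin(np.radians(19.5))))
        assert kf.k_hat[0] == pytest.approx(area / 2.0, rel=1e-9)

    def test_k_is_nondecreasing_in_radius(self):
        rng = np.random.default_rng(3)
        df = occ([(i, 100 + rng.random() * 3, 20 + rng.random() * 3, 1980, "h") for i in range(100)])
        kf = ripley_k(df, np.linspace(10, 300, 12), (100, 20, 103, 23), n_sims=0)
        assert (np.diff(kf.k_hat) >= 0).all()

    def test_fewer_than_two_points_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            ripley_k(occ([(0, 100.0, 20.0, 1980, "h")]), [10.0], (99, 19, 101, 21))

    def test_csr_points_inside_envelope(self):
        rng = np.random.default_rng(17)
        df = occ([(i, 100 + rng.random() * 5, 20 + rng.random() * 5, 1980, "h") for i in range(300)])
        kf = ripley_k(df, [50.0, 120.0], (100, 20, 105, 25), n_sims=99, rng=rng)
        assert ((kf.k_hat >= kf.envelope_low) & (kf.k_hat <= kf.envelope_high)).all()
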