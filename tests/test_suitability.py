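"""Envelopes, CON masks, suitability conjunction, change-map algebra."""

import numpy as np
import pandas as pd
import pytest

from isoclim.suitability import (
    CHANGE_CODES,
    build_envelope,
    change_map,
    con_mask,
    render_characterisation,
    suitability_map,
    summarize_change,
    summarize_envelope,
)
from isoclim.surfaces import GridSpec, RasterLayer


@pytest.fixture
def grid():
    return GridSpec(west=-121.0, north=40.0, cell=0.1, n_cols=10, n_rows=8)


def binary(grid, mask):
    return RasterLayer(grid, mask.astype(float), semantics="categorical")


class TestEnvelope:
    def test_quartiles_linear_interpolation(self):
        df = pd.DataFrame({"tavg": [3.0, 5.0, 7.0, 9.0]})
        env = build_envelope(df, "sp")
        # linear interpolation of order statistics: Q1 at position 0.75,
        # Q3 at position 2.25 of the sorted sample
        assert env.variables["tavg"] == (3.0, 4.5, 7.5, 9.0)

    def test_degenerate_identical_points(self):
        df = pd.DataFrame({"tavg": [5.0] * 6})
        env = build_envelope(df, "sp")
        mn, q1, q3, mx = env.variables["tavg"]
        assert mn == q1 == q3 == mx == 5.0

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match=">=4"):
            build_envelope(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), "sp")

    def test_rows_with_missing_values_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan]})
        env = build_envelope(df, "sp")
        assert env.n_occurrences == 4

    def test_envelope_converges_to_truth_box(self, rng):
        lo, hi = -2.0, 3.0
        widths = []
        for n in (20, 2000):
            df = pd.DataFrame({"x": rng.uniform(lo, hi, n)})
            env = build_envelope(df, "sp")
            mn, _, _, mx = env.variables["x"]
            assert lo <= mn and mx <= hi
            widths.append((mn - lo) + (hi - mx))
        assert widths[1] < widths[0]

    def test_soil_orders_collected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "soil_order": [1, 1, 3, 3]})
        env = build_envelope(df, "sp")
        assert env.soil_orders == frozenset({1, 3})


class TestConMask:
    def test_bounds_inclusive(self, grid):
        vals = np.full((8, 10), 5.0)
        vals[0, 0], vals[0, 1] = 1.0, 9.0
        layer = RasterLayer(grid, vals)
        m = con_mask(layer, 1.0, 9.0)
        assert m.values[0, 0] == 1 and m.values[0, 1] == 1

    def test_missing_maps_to_absence(self, grid):
        vals = np.full((8, 10), 5.0)
        vals[2, 2] = np.nan
        m = con_mask(RasterLayer(grid, vals), 0, 10)
        assert m.values[2, 2] == 0

    def test_matches_cell_loop_oracle(self, grid, rng):
        vals = rng.normal(0, 1, (8, 10))
        lo, hi = -0.5, 0.8
        m = con_mask(RasterLayer(grid, vals), lo, hi)
        for r in range(8):
            for c in range(10):
                assert m.values[r, c] == (1.0 if lo <= vals[r, c] <= hi else 0.0)


class TestSuitabilityMap:
    def _layers(self, grid):
        lon, lat = grid.cell_centers()
        return {"a": RasterLayer(grid, lon), "b": RasterLayer(grid, lat)}

    def test_and_semantics(self, grid):
        layers = self._layers(grid)
        env = build_envelope(
            pd.DataFrame({"a": [-120.9, -120.8, -120.7, -120.6],
                          "b": [39.2, 39.4, 39.6, 39.8]}), "sp")
        suit = suitability_map(env, layers, "suitable")
        a, b = layers["a"].values, layers["b"].values
        expected = ((a >= -120.9) & (a <= -120.6) & (b >= 39.2) & (b <= 39.8))
        assert np.array_equal(suit.values.astype(bool), expected)

    def test_optimal_subset_of_suitable(self, grid, rng):
        layers = self._layers(grid)
        df = pd.DataFrame({"a": rng.uniform(-121, -120, 30),
                           "b": rng.uniform(39.2, 40, 30)})
        env = build_envelope(df, "sp")
        s = suitability_map(env, layers, "suitable").values.astype(bool)
        o = suitability_map(env, layers, "optimal").values.astype(bool)
        assert np.all(~o | s)

    def test_widening_interval_is_monotone(self, grid):
        layers = self._layers(grid)
        df = pd.DataFrame({"a": [-120.9, -120.8, -120.7, -120.6],
                           "b": [39.2, 39.4, 39.6, 39.8]})
        env1 = build_envelope(df, "sp")
        env2 = build_envelope(pd.DataFrame({"a": [-121.0, -120.8, -120.7, -120.2],
                                            "b": [39.0, 39.4, 39.6, 40.0]}), "sp")
        s1 = suitability_map(env1, layers).values.astype(bool)
        s2 = suitability_map(env2, layers).values.astype(bool)
        assert np.all(~s1 | s2)

    def test_soil_membership_is_hard_and(self, grid):
        layers = self._layers(grid)
        soil = RasterLayer(grid, np.ones((8, 10)), semantics="categorical")
        soil.values[:, :5] = 2.0
        df = pd.DataFrame({"a": [-121.0, -120.5, -120.3, -120.0],
                           "b": [39.0, 39.4, 39.6, 40.0],
                           "soil_order": [1, 1, 1, 1]})
        env = build_envelope(df, "sp")
        s = suitability_map(env, layers, soil_layer=soil)
        assert s.values[:, :5].sum() == 0

    def test_grid_mismatch_raises(self, grid):
        other = GridSpec(west=-121.0, north=40.0, cell=0.1, n_cols=9, n_rows=8)
        layers = {"a": RasterLayer(grid, np.zeros((8, 10))),
                  "b": RasterLayer(other, np.zeros((8, 9)))}
        env = build_envelope(pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [0.0, 1, 2, 3]}), "sp")
        with pytest.raises(ValueError, match="grid"):
            suitability_map(env, layers)


class TestChangeMap:
    def test_four_category_mapping(self, grid):
        cur = np.zeros((8, 10), bool)
        fut = np.zeros((8, 10), bool)
        cur[0, 0] = True            # unstable
        fut[0, 1] = True            # gain
        cur[0, 2] = fut[0, 2] = True  # stable
        ch = change_map(binary(grid, cur), binary(grid, fut))
        assert ch.codes[0, 0] == CHANGE_CODES["unstable"]
        assert ch.codes[0, 1] == CHANGE_CODES["gain"]
        assert ch.codes[0, 2] == CHANGE_CODES["stable"]
        assert ch.codes[5, 5] == CHANGE_CODES["never"]

    def test_partition_laws_random_pairs(self, grid, rng):
        for _ in range(100):
            cur = rng.random((8, 10)) < 0.4
            fut = rng.random((8, 10)) < 0.4
            ch = change_map(binary(grid, cur), binary(grid, fut))
            gain = ch.codes == CHANGE_CODES["gain"]
            stable = ch.codes == CHANGE_CODES["stable"]
            unstable = ch.codes == CHANGE_CODES["unstable"]
            never = ch.codes == CHANGE_CODES["never"]
            assert np.array_equal(gain | stable, fut)
            assert np.array_equal(unstable | stable, cur)
            assert np.all(gain.astype(int) + stable + unstable + never == 1)

    def test_percentages_vs_count_oracle(self, grid, rng):
        for _ in range(20):
            cur = rng.random((8, 10)) < 0.5
            fut = rng.random((8, 10)) < 0.5
            if not cur.any():
                continue
            ch = change_map(binary(grid, cur), binary(grid, fut))
            pct = summarize_change(ch)
            n_cur = cur.sum()
            assert pct["stable"] == pytest.approx(100 * (cur & fut).sum() / n_cur)
            assert pct["unstable"] == pytest.approx(100 * (cur & ~fut).sum() / n_cur)
            assert pct["gain"] == pytest.approx(100 * (~cur & fut).sum() / n_cur)
            assert pct["stable"] + pct["unstable"] == pytest.approx(100.0)

    def test_identical_maps_fully_stable(self, grid, rng):
        cur = rng.random((8, 10)) < 0.5
        ch = change_map(binary(grid, cur), binary(grid, cur))
        pct = summarize_change(ch)
        assert pct == {"gain": 0.0, "unstable": 0.0, "stable": 100.0}

    def test_zero_current_area_is_undefined(self, grid):
        ch = change_map(binary(grid, np.zeros((8, 10), bool)),
                        binary(grid, np.zeros((8, 10), bool)))
        assert all(np.isnan(v) for v in summarize_change(ch).values())


class TestCharacterisationTables:
    def _env(self):
        df = pd.DataFrame({
            "tavg": [7.23, 9.0, 11.0, 13.44], "tmin": [0.0, 1, 2, 3],
            "tmax": [15.0, 16, 17, 18], "pavg": [600.0, 700, 800, 900],
            "pp": [600.0, 690, 780, 870], "it": [100.0, 120, 140, 160],
            "itc": [100.0, 120, 140, 160], "tp": [1000.0, 1100, 1200, 1300],
            "ic": [12.0, 13, 14, 15], "io": [4.0, 5, 6, 7],
            "ios2": [0.2, 0.3, 0.4, 0.5], "ios3": [0.3, 0.4, 0.5, 0.6],
            "ios4": [0.5, 0.6, 0.7, 0.8],
        })
        return build_envelope(df, "Demo species")

    def test_table_order_and_rounding(self):
        table = summarize_envelope(self._env())
        assert list(table["variable"]) == [
            "Tavg", "Tmin", "Tmax", "Pavg", "Pp", "It", "Itc", "Tp", "Ic",
            "Io", "Ios2", "Ios3", "Ios4",
        ]
        assert table.iloc[0]["min"] == 7.2 and table.iloc[0]["max"] == 13.4

    def test_collapsed_quartiles_render_single_value(self):
        df = pd.DataFrame({"ic": [22.5, 23.1, 23.1, 23.1, 23.1, 27.3]})
        env = build_envelope(df, "sp")
        text = render_characterisation(env)
        assert "Ic: 22.5 (23.1) 27.3" in text

    def test_rendered_numbers_parse_back_within_rounding(self):
        text = render_characterisation(self._env())
        line = [l for l in text.splitlines() if l.strip().startswith("Tavg")][0]
        nums = [float(x) for x in
                line.replace("(", " ").replace(")", " ").replace("-", " ").split()[1:]]
        assert abs(nums[0] - 7.23) <= 0.05 and abs(nums[-1] - 13.44) <= 0.05
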