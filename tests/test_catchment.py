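import numpy as np
import pytest

from lakemp.catchment import (
    D8_CODES,
    NEIGHBOR_OFFSETS,
    OUTLET_CODE,
    UNDEFINED_CODE,
    d8_flow_direction,
    delineate_watershed,
    downstream_cell,
    fill_depressions,
    find_pour_point,
    flow_accumulation,
    sum_wwtw_load,
    summarize_landcover,
)
from lakemp.rasters import Raster, read_ascii_grid, write_ascii_grid


def raster(values, **kw):
    return Raster(values=np.asarray(values, dtype=float), **kw)


def brute_force_accumulation(direction):
    """Oracle: count, per cell, the paths (including its own) passing through."""
    nrows, ncols = direction.shape
    acc = np.zeros((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            if direction[r, c] == UNDEFINED_CODE:
                acc[r, c] = np.nan
                continue
            cell = (r, c)
            seen = set()
            while cell is not None and cell not in seen:
                seen.add(cell)
                acc[cell] += 1
                cell = downstream_cell(direction, *cell)
    return acc


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        r = raster(np.arange(12).reshape(3, 4), cell_size_m=25.0, origin=(100.0, 200.0))
        path = tmp_path / "grid.asc"
        write_ascii_grid(r, path)
        back = read_ascii_grid(path)
        np.testing.assert_allclose(back.values, r.values)
        assert back.cell_size_m == 25.0
        assert back.origin == (100.0, 200.0)

    def test_point_in_cell_half_open(self):
        r = raster(np.zeros((3, 3)), cell_size_m=10.0)
        assert r.cell_of_point(0.0, 0.0) == (2, 0)  # lower-left corner cell
        assert r.cell_of_point(10.0, 0.0) == (2, 1)  # boundary belongs to next cell
        assert r.cell_of_point(29.9, 29.9) == (0, 2)
        assert r.cell_of_point(30.0, 0.0) is None


class TestFillDepressions:
    def test_drained_dem_unchanged(self):
        east = np.tile(np.arange(5, 0, -1.0), (5, 1))
        filled = fill_depressions(raster(east))
        np.testing.assert_allclose(filled.values, east)

    def test_single_pit_raised_to_spill_level(self):
        dem = np.full((5, 5), 5.0)
        dem[0, :] = 4.0  # edge row drains; spill level for interior
        dem[2, 2] = 1.0  # pit
        filled = fill_depressions(raster(dem))
        # pit must rise to the lowest elevation on any path to the edge: 5
        assert filled.values[2, 2] == 5.0
        assert (filled.values >= dem).all()

    def test_idempotent(self, rng):
        dem = raster(rng.uniform(0, 10, (8, 8)))
        once = fill_depressions(dem)
        twice = fill_depressions(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_every_cell_drains_after_fill(self, rng):
        for seed in range(5):
            dem = raster(np.random.default_rng(seed).uniform(0, 10, (8, 8)))
            filled = fill_depressions(dem)
            direction = d8_flow_direction(filled)
            for r in range(8):
                for c in range(8):
                    cell, seen = (r, c), set()
                    while cell is not None:
                        assert cell not in seen
                        seen.add(cell)
                        nxt = downstream_cell(direction, *cell)
                        if nxt is not None:
                            assert filled.values[nxt] <= filled.values[cell]
                        cell = nxt

    def test_all_nodata_rejected(self):
        r = Raster(values=np.full((3, 3), -9999.0), nodata=-9999.0)
        with pytest.raises(ValueError):
            fill_depressions(r)


class TestD8Direction:
    def test_east_sloping_plane_points_east(self):
        dem = raster(np.tile(np.arange(6, 0, -1.0), (4, 1)))
        direction = d8_flow_direction(dem)
        assert (direction[:, :-1] == 1).all()  # E code
        assert (direction[:, -1] == OUTLET_CODE).all()

    def test_steepest_cardinal_drop_wins(self):
        # centre 5; the lowest neighbour (1) sits due south: drop 4 beats
        # any diagonal drop scaled by 1/sqrt(2)
        dem = raster([[9.0, 9.0, 9.0], [8.0, 5.0, 8.0], [7.0, 1.0, 2.0]])
        direction = d8_flow_direction(dem)
        assert direction[1, 1] == 4  # S

    def test_tie_broken_by_neighbour_order(self):
        # E and S neighbours tie at the same drop; E comes first in the order
        dem = raster([[9.0, 9.0, 9.0], [9.0, 5.0, 4.0], [9.0, 4.0, 9.0]])
        direction = d8_flow_direction(dem)
        assert direction[1, 1] == 1  # E
        assert np.array_equal(d8_flow_direction(dem), direction)  # deterministic

    def test_neighbour_order_constants(self):
        assert NEIGHBOR_OFFSETS[0] == (0, 1)  # E first
        assert D8_CODES == (1, 2, 4, 8, 16, 32, 64, 128)


class TestFlowAccumulation:
    def test_single_file_chain(self):
        dem = raster([[5.0, 4.0, 3.0, 2.0, 1.0]])
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction)
        np.testing.assert_allclose(acc[0], [1, 2, 3, 4, 5])

    def test_all_outlets_all_one(self):
        direction = np.full((3, 3), OUTLET_CODE)
        np.testing.assert_allclose(flow_accumulation(direction), np.ones((3, 3)))

    def test_closed_basin_conservation(self):
        # fully convergent bowl: outlet accumulation equals cell count
        n = 7
        rows, cols = np.mgrid[0:n, 0:n]
        dem = raster(2.0 * np.abs(rows - n // 2) + (n - 1.0 - cols))
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction)
        outlet_mask = direction == OUTLET_CODE
        assert acc[outlet_mask].sum() == n * n

    def test_matches_brute_force_on_random_dems(self):
        for seed in range(20):
            dem = raster(np.random.default_rng(seed).uniform(0, 10, (8, 8)))
            direction = d8_flow_direction(fill_depressions(dem))
            acc = flow_accumulation(direction)
            np.testing.assert_allclose(acc, brute_force_accumulation(direction))

    def test_mass_conservation_across_outlets(self):
        for seed in range(10):
            dem = raster(np.random.default_rng(100 + seed).uniform(0, 10, (8, 8)))
            direction = d8_flow_direction(fill_depressions(dem))
            acc = flow_accumulation(direction)
            assert acc[direction == OUTLET_CODE].sum() == 64

    def test_cycle_detected(self):
        direction = np.full((1, 2), OUTLET_CODE)
        direction[0, 0] = 1  # east
        direction[0, 1] = 16  # west: 2-cycle
        with pytest.raises(ValueError, match="cycle"):
            flow_accumulation(direction)


class TestPourPointAndWatershed:
    def test_pour_point_on_chain(self):
        dem = raster([[5.0, 4.0, 3.0, 2.0, 1.0]])
        acc = flow_accumulation(d8_flow_direction(dem))
        mask = np.zeros((1, 5), bool)
        mask[0, 4] = True
        assert find_pour_point(acc, mask) == (0, 4)

    def test_buffer_adds_neighbour_ring(self):
        acc = np.ones((5, 5))
        acc[2, 3] = 10.0  # just outside the lake
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert find_pour_point(acc, mask, buffer_px=0) == (2, 2)
        assert find_pour_point(acc, mask, buffer_px=1) == (2, 3)

    def test_tie_breaks_row_major(self):
        acc = np.ones((3, 3))
        mask = np.ones((3, 3), bool)
        assert find_pour_point(acc, mask) == (0, 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            find_pour_point(np.ones((3, 3)), np.zeros((3, 3), bool))

    def test_fully_convergent_watershed_is_whole_grid(self):
        n = 7
        rows, cols = np.mgrid[0:n, 0:n]
        dem = raster(2.0 * np.abs(rows - n // 2) + (n - 1.0 - cols))
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction)
        outlet = (n // 2, n - 1)
        assert acc[outlet] == n * n
        assert delineate_watershed(direction, outlet).all()

    def test_ridge_top_watershed_is_single_cell(self):
        n = 7
        rows, cols = np.mgrid[0:n, 0:n]
        dem = raster(2.0 * np.abs(rows - n // 2) + (n - 1.0 - cols))
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction)
        ridge = np.argwhere(acc == 1)[0]
        ws = delineate_watershed(direction, tuple(ridge))
        assert ws.sum() == 1

    def test_watershed_matches_brute_force_tracing(self):
        for seed in range(5):
            dem = raster(np.random.default_rng(seed).uniform(0, 10, (8, 8)))
            direction = d8_flow_direction(fill_depressions(dem))
            acc = flow_accumulation(direction)
            pour = tuple(np.argwhere(acc == acc.max())[0])
            ws = delineate_watershed(direction, pour)
            for r in range(8):
                for c in range(8):
                    cell, reaches = (r, c), False
                    while cell is not None:
                        if cell == pour:
                            reaches = True
                            break
                        cell = downstream_cell(direction, *cell)
                    assert ws[r, c] == reaches

    def test_nesting_property(self, rng):
        dem = raster(rng.uniform(0, 10, (8, 8)))
        direction = d8_flow_direction(fill_depressions(dem))
        acc = flow_accumulation(direction)
        upstream = tuple(np.argwhere(acc > 3)[0])
        downstream = downstream_cell(direction, *upstream)
        if downstream is not None:
            ws_up = delineate_watershed(direction, upstream)
            ws_down = delineate_watershed(direction, downstream)
            assert (ws_up <= ws_down).all()

    def test_distinct_outlet_watersheds_disjoint(self):
        for seed in range(5):
            dem = raster(np.random.default_rng(seed).uniform(0, 10, (8, 8)))
            direction = d8_flow_direction(fill_depressions(dem))
            outlets = [tuple(rc) for rc in np.argwhere(direction == OUTLET_CODE)]
            total = np.zeros((8, 8), dtype=int)
            for outlet in outlets:
                total += delineate_watershed(direction, outlet).astype(int)
            assert (total == 1).all()  # disjoint and jointly exhaustive


class TestSummaries:
    def test_all_forest(self):
        lc = raster(np.full((3, 3), 23.0))
        mask = np.ones((3, 3), bool)
        class_map = {23: "forest"}
        forest, urban = summarize_landcover(lc, mask, class_map)
        assert forest == 1.0 and urban == 0.0

    def test_counting(self):
        lc = raster([[23.0, 23.0, 23.0, 1.0, 1.0], [12.0, 12.0, 12.0, 12.0, 12.0]])
        mask = np.ones((2, 5), bool)
        class_map = {23: "forest", 1: "urban", 12: "other"}
        forest, urban = summarize_landcover(lc, mask, class_map)
        assert forest == pytest.approx(0.3)
        assert urban == pytest.approx(0.2)

    def test_nodata_excluded_from_denominator(self):
        lc = Raster(values=np.array([[23.0, -9999.0], [23.0, 1.0]]), nodata=-9999.0)
        forest, urban = summarize_landcover(lc, np.ones((2, 2), bool), {23: "forest", 1: "urban"})
        assert forest == pytest.approx(2 / 3)
        assert urban == pytest.approx(1 / 3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            summarize_landcover(raster(np.ones((2, 2))), np.zeros((2, 2), bool), {})

    def test_wwtw_sums(self):
        r = raster(np.zeros((4, 4)), cell_size_m=10.0)
        mask = np.zeros((4, 4), bool)
        mask[3, 0] = True  # lower-left cell: x in [0, 10), y in [0, 10)
        assert sum_wwtw_load([], mask, r) == 0.0
        points = [(5.0, 5.0, 1000.0), (2.0, 8.0, 2500.0), (15.0, 5.0, 99.0)]
        assert sum_wwtw_load(points, mask, r) == 3500.0

    def test_boundary_point_counts_as_inside(self):
        r = raster(np.zeros((4, 4)), cell_size_m=10.0)
        mask = np.zeros((4, 4), bool)
        mask[3, 0] = True
        assert sum_wwtw_load([(0.0, 0.0, 7.0)], mask, r) == 7.0

    def test_negative_load_rejected(self):
        r = raster(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            sum_wwtw_load([(0.5, 0.5, -1.0)], np.ones((2, 2), bool), r)
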