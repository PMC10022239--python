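import itertools
import math

import numpy as np
import pytest

from chwplace.grids import Grid, GridValidationError
from chwplace.travel import (
    access_surface,
    build_cost_graph,
    population_share_beyond,
    travel_matrix,
)
from tests.conftest import make_grid


def brute_force_times(friction: Grid, source, connectivity=8):
    """Independent oracle: Bellman-Ford style exhaustive edge relaxation.

    Relaxes every adjacency n_cells times, which enumerates all simple
    paths implicitly; shares no code with the Dijkstra-based implementation.
    """
    nrow, ncol = friction.shape
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    dist = {source: 0.0}
    for _ in range(nrow * ncol):
        for (r, c) in list(dist):
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrow and 0 <= cc < ncol):
                    continue
                if friction.nodata_mask[r, c] or friction.nodata_mask[rr, cc]:
                    continue
                step = friction.cell_size_km * (math.sqrt(2) if dr and dc else 1.0)
                w = 0.5 * (friction.values[r, c] + friction.values[rr, cc]) * step
                nd = dist[(r, c)] + w
                if nd < dist.get((rr, cc), math.inf) - 1e-15:
                    dist[(rr, cc)] = nd
    return dist


class TestEdgeCosts:
    def test_uniform_horizontal_edge(self):
        g = build_cost_graph(make_grid(np.full((1, 2), 12.0)))
        assert g[0, 1] == pytest.approx(12.0)

    def test_mean_of_unequal_frictions(self):
        g = build_cost_graph(make_grid([[10.0, 20.0]]))
        assert g[0, 1] == pytest.approx(15.0)

    def test_diagonal_scaling(self):
        g = build_cost_graph(make_grid(np.full((2, 2), 10.0)))
        assert g[0, 3] == pytest.approx(10.0 * math.sqrt(2))

    def test_four_connectivity_has_no_diagonals(self):
        g = build_cost_graph(make_grid(np.full((2, 2), 10.0)), connectivity=4)
        assert g[0, 3] == 0.0

    def test_nodata_cells_untraversable(self):
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 1] = True
        g = build_cost_graph(make_grid(np.full((1, 3), 10.0), nodata=mask))
        assert g[0, 1] == 0.0 and g[1, 2] == 0.0

    def test_all_nodata_raises(self):
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(GridValidationError):
            build_cost_graph(make_grid(np.ones((2, 2)), nodata=mask))


class TestAccessSurface:
    def test_three_steps_uniform_friction(self, uniform_friction):
        surf = access_surface(uniform_friction, [(0, 0)])
        assert surf.values[0, 3] == pytest.approx(36.0)

    def test_facility_cell_is_zero(self, uniform_friction):
        surf = access_surface(uniform_friction, [(2, 2)])
        assert surf.values[2, 2] == 0.0

    def test_matches_exhaustive_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            friction = make_grid(rng.uniform(5, 40, (5, 5)))
            src = (int(rng.integers(5)), int(rng.integers(5)))
            surf = access_surface(friction, [src])
            oracle = brute_force_times(friction, src)
            for (r, c), t in oracle.items():
                assert surf.values[r, c] == pytest.approx(t, abs=1e-9)

    def test_unreachable_cell_is_infinite(self):
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 1] = True
        friction = make_grid(np.full((1, 3), 10.0), nodata=mask)
        surf = access_surface(friction, [(0, 0)])
        assert math.isinf(surf.values[0, 2])

    def test_facility_on_nodata_raises(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        friction = make_grid(np.ones((2, 2)), nodata=mask)
        with pytest.raises(GridValidationError, match="nodata"):
            access_surface(friction, [(0, 0)])

    def test_no_facilities_raises(self, uniform_friction):
        with pytest.raises(GridValidationError):
            access_surface(uniform_friction, [])


class TestTravelMatrix:
    def cells(self, shape):
        return list(itertools.product(range(shape[0]), range(shape[1])))

    def test_zero_cutoff_keeps_only_diagonal(self, uniform_friction):
        cells = self.cells((5, 5))
        ttm = travel_matrix(uniform_friction, cells, cells, cutoff_min=0.0)
        assert all(i == j for i, j in ttm.entries)
        assert len(ttm.entries) == 25
        assert all(t == 0.0 for t in ttm.entries.values())

    def test_uniform_friction_neighborhood_radius(self):
        # 12 min/km, cutoff 60 -> exactly the cells with path cost <= 60
        friction = make_grid(np.full((7, 7), 12.0))
        cells = self.cells((7, 7))
        ttm = travel_matrix(friction, [(3, 3)], cells, cutoff_min=60.0)
        oracle = brute_force_times(friction, (3, 3))
        ncol = 7
        expected = {r * ncol + c for (r, c), t in oracle.items() if t <= 60.0 + 1e-9}
        got = {j for (_, j) in ttm.entries}
        assert got == expected

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        friction = make_grid(rng.uniform(5, 30, (4, 4)))
        cells = self.cells((4, 4))
        ttm = travel_matrix(friction, cells, cells, cutoff_min=120.0)
        for (i, j), t in ttm.entries.items():
            assert ttm.entries[(j, i)] == pytest.approx(t)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(8)
        friction = make_grid(rng.uniform(5, 30, (4, 4)))
        cells = self.cells((4, 4))
        ttm = travel_matrix(friction, cells, cells, cutoff_min=1e6)
        d = ttm.entries
        keys = list(itertools.islice(itertools.product(range(16), repeat=3), 0, None, 7))
        for i, j, k in keys:
            ci, cj, ck = 1 * i, 1 * j, 1 * k
            assert d[(ci, ck)] <= d[(ci, cj)] + d[(cj, ck)] + 1e-6

    def test_raising_cutoff_never_removes_pairs(self):
        rng = np.random.default_rng(9)
        friction = make_grid(rng.uniform(5, 30, (4, 4)))
        cells = self.cells((4, 4))
        small = travel_matrix(friction, cells, cells, cutoff_min=30.0)
        large = travel_matrix(friction, cells, cells, cutoff_min=60.0)
        assert set(small.entries) <= set(large.entries)

    def test_lowering_friction_never_increases_times(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(10, 30, (4, 4))
        cells = self.cells((4, 4))
        base = travel_matrix(make_grid(vals), cells, cells, cutoff_min=500.0)
        lower = travel_matrix(make_grid(vals * 0.5), cells, cells, cutoff_min=500.0)
        for key, t in base.entries.items():
            assert lower.entries[key] <= t + 1e-9

    def test_matches_oracle_pairwise_on_random_5x5(self):
        rng = np.random.default_rng(11)
        friction = make_grid(rng.uniform(5, 40, (5, 5)))
        cells = self.cells((5, 5))
        ttm = travel_matrix(friction, cells, cells, cutoff_min=1e9)
        ncol = 5
        for src in [(0, 0), (2, 2), (4, 1)]:
            oracle = brute_force_times(friction, src)
            i = src[0] * ncol + src[1]
            for (r, c), t in oracle.items():
                assert ttm.entries[(i, r * ncol + c)] == pytest.approx(t, abs=1e-9)


class TestPopulationShare:
    def test_share_beyond_threshold(self):
        pop = make_grid([[100.0, 300.0]])
        access = make_grid([[10.0, 70.0]])
        assert population_share_beyond(pop, access, 60.0) == pytest.approx(0.75)

    def test_zero_when_all_near(self):
        pop = make_grid([[100.0, 300.0]])
        access = make_grid([[10.0, 20.0]])
        assert population_share_beyond(pop, access, 60.0) == 0.0
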