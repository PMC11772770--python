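"""Allocation engine: conversion permissions, resistance, the adaptive
competitive-advantage mechanism, and full greedy-oracle equivalence."""

import numpy as np
import pytest

from tipland.allocation import (
    AllocationConfig,
    CompetitiveState,
    allocate,
    competitive_advantage,
    competitive_advantage_matrix,
    conversion_potential,
    derive_conversion_matrix,
    estimate_resistance,
    update_competitive_state,
)
from tipland.demand import N_SERVICES, supply_from_grid
from tipland.grids import GeometryError, Raster
from tipland.land_system import N_LAND_SYSTEM_CLASSES


def as_raster(values, cell=990.0):
    return Raster(np.asarray(values, dtype=np.int16), cell, nodata=-1)


class TestConversionMatrix:
    def test_identical_maps_identity_only(self):
        ls = as_raster([[3, 4], [5, 6]])
        m = derive_conversion_matrix(ls, ls)
        assert (m == np.eye(N_LAND_SYSTEM_CLASSES, dtype=np.int8)).all()

    def test_single_transition_recorded(self):
        ls1, ls2 = as_raster([[3, 3]]), as_raster([[3, 0]])
        m = derive_conversion_matrix(ls1, ls2)
        assert m[3, 0] == 1 and m[0, 3] == 0

    def test_matches_transition_set_oracle(self, rng):
        v1 = rng.integers(0, 30, (20, 20)).astype(np.int16)
        v2 = rng.integers(0, 30, (20, 20)).astype(np.int16)
        m = derive_conversion_matrix(as_raster(v1), as_raster(v2))
        expected = set(zip(v1.ravel().tolist(), v2.ravel().tolist()))
        expected |= {(k, k) for k in range(30)}
        for a in range(30):
            for b in range(30):
                assert m[a, b] == (1 if (a, b) in expected else 0)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            derive_conversion_matrix(as_raster([[1]]), as_raster([[1, 2]]))


class TestResistance:
    def test_partial_persistence(self):
        v1 = np.full((1, 10), 7, dtype=np.int16)
        v2 = v1.copy()
        v2[0, :2] = 8
        res = estimate_resistance(as_raster(v1), as_raster(v2))
        assert res[7] == pytest.approx(0.8)

    def test_fully_persistent_and_fully_turned_over(self):
        v1 = np.array([[1, 1, 2, 2]], dtype=np.int16)
        v2 = np.array([[1, 1, 3, 3]], dtype=np.int16)
        res = estimate_resistance(as_raster(v1), as_raster(v2))
        assert res[1] == 1.0 and res[2] == 0.0

    def test_absent_class_gets_default(self):
        ls = as_raster([[1]])
        res = estimate_resistance(ls, ls, default=0.5)
        assert res[29] == 0.5


class TestCompetitiveState:
    def test_speed_sequence_under_defaults(self):
        state = CompetitiveState()
        speeds = [state.speed]
        for _ in range(2):
            update_competitive_state(state, np.zeros(4), np.zeros(4))
            speeds.append(state.speed)
        assert speeds == pytest.approx([1.0, 1.001, 1.002], abs=1e-12)

    def test_inertia_single_step(self):
        state = CompetitiveState(seed=1.0, step=0.001)
        demand = np.array([100.0, 0, 0, 0])
        supply = np.array([90.0, 0, 0, 0])
        update_competitive_state(state, demand, supply)
        assert state.i == 2
        assert state.inertia[0] == pytest.approx(10 / 1.001, abs=1e-12)

    def test_equilibrium_keeps_inertia_zero(self):
        state = CompetitiveState()
        demand = np.array([5.0, 6.0, 7.0, 8.0])
        for _ in range(10):
            update_competitive_state(state, demand, demand)
        assert (state.inertia == 0).all()

    def test_accumulation_over_iterations(self):
        state = CompetitiveState()
        demand = np.array([10.0, 0, 0, 0])
        supply = np.array([0.0, 0, 0, 0])
        update_competitive_state(state, demand, supply)
        update_competitive_state(state, demand, supply)
        assert state.inertia[0] == pytest.approx(10 / 1.001 + 10 / 1.002, abs=1e-12)

    def test_non_positive_seed_rejected(self):
        with pytest.raises(Exception):
            CompetitiveState(seed=0.0)


class TestCompetitiveAdvantage:
    def test_zero_inertia_zero_everywhere(self):
        state = CompetitiveState()
        ca = np.random.default_rng(0).uniform(0, 1, (30, 4))
        comp, unservable = competitive_advantage_matrix(state, ca)
        assert (comp == 0).all() and unservable == []

    def test_hand_worked_single_service(self):
        # inertia 10, CA_j=2, CA_u=1, column sum 5 -> 10 * (2-1)/5 = 2
        state = CompetitiveState()
        state.inertia = np.array([10.0, 0, 0, 0])
        ca = np.zeros((30, 4))
        ca[1, 0], ca[2, 0], ca[3, 0] = 2.0, 1.0, 2.0
        assert competitive_advantage(1, 2, state, ca) == pytest.approx(2.0)

    def test_same_class_contributes_zero(self):
        state = CompetitiveState()
        state.inertia = np.array([3.0, 1.0, 0, 0])
        ca = np.random.default_rng(1).uniform(0, 1, (30, 4))
        for u in (0, 7, 29):
            assert competitive_advantage(u, u, state, ca) == 0.0

    def test_unservable_service_flagged(self):
        state = CompetitiveState()
        state.inertia = np.array([0, 0, 0, 5.0])
        ca = np.zeros((30, 4))
        _, unservable = competitive_advantage_matrix(state, ca)
        assert unservable == ["shrubland"]


def test_conversion_potential_is_component_sum():
    assert conversion_potential(0.5, 0.2, 0.1, 0.0) == pytest.approx(0.8)
    # with zero inertia the potential reduces to P_loc + P_res
    assert conversion_potential(0.5, 0.2, 0.0) == pytest.approx(0.7)


# --------------------------------------------------------------------------
# full-engine behaviour


def single_service_instance(rng, nrow=8, ncol=8, n_classes=6, n_cand=3):
    """Random single-service allocation problem (only service 0 has capacity)."""
    values = rng.integers(0, n_classes, (nrow, ncol)).astype(np.int16)
    ca = np.zeros((N_LAND_SYSTEM_CLASSES, N_SERVICES))
    ca[:n_classes, 0] = rng.uniform(0.2, 1.0, n_classes)
    m = np.zeros((N_LAND_SYSTEM_CLASSES, N_LAND_SYSTEM_CLASSES), dtype=np.int8)
    np.fill_diagonal(m, 1)
    block = (rng.random((n_classes, n_classes)) < 0.7).astype(np.int8)
    m[:n_classes, :n_classes] |= block
    res = rng.uniform(0, 1, N_LAND_SYSTEM_CLASSES)
    cand = sorted(rng.choice(n_classes, size=n_cand, replace=False).tolist())
    suit = {int(j): rng.uniform(0, 1, (nrow, ncol)) for j in cand}
    grid = as_raster(values)
    supply0 = supply_from_grid(grid, ca)[0]
    demand = np.zeros(N_SERVICES)
    demand[0] = supply0 * rng.uniform(0.85, 1.25)
    return grid, suit, demand, ca, m, res


def oracle_allocate(grid, suit, demand, ca, m, res, config):
    """Exhaustive greedy reference allocator for single-service problems.

    Pure-python re-derivation: per internal iteration, scan every unfrozen
    cell in row-major order and every candidate class in ascending code
    order, keep the strictly best gap-shrinking conversion by potential
    P_loc + P_res + P_comp, convert it, then advance speed/inertia.
    """
    values = [row[:] for row in grid.values.tolist()]
    nrow, ncol = grid.shape
    cand = sorted(suit)
    demand0 = demand[0]
    supply = 0.0
    for r in range(nrow):
        for c in range(ncol):
            supply += ca[values[r][c]][0]
    thr = max(config.tolerance * abs(demand0), ca[:, 0].max())
    denom = ca[:, 0].sum()
    speed, inertia, i = config.comp_seed, 0.0, 1
    frozen = set()
    changes = []
    while i <= config.coarse_cap and abs(supply - demand0) > thr:
        scale = inertia / denom
        best, best_pot = None, -np.inf
        for r in range(nrow):
            for c in range(ncol):
                if (r, c) in frozen:
                    continue
                u = values[r][c]
                for j in cand:
                    if j == u or m[u][j] == 0:
                        continue
                    gap = supply - demand0
                    new_gap = gap + ca[j][0] - ca[u][0]
                    if not abs(new_gap) / thr < abs(gap) / thr - 1e-12:
                        continue
                    pot = suit[j][r][c] + res[u] + (ca[j][0] * scale - ca[u][0] * scale)
                    if pot > best_pot:
                        best_pot, best = pot, (r, c, u, j)
        if best is None:
            break
        r, c, u, j = best
        values[r][c] = j
        frozen.add((r, c))
        supply += ca[j][0] - ca[u][0]
        changes.append((i, r, c, u, j))
        i += 1
        speed += config.comp_step
        inertia += (demand0 - supply) / speed
    return np.array(values), changes


class TestAllocate:
    def test_equilibrium_demand_zero_changes(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng)
        demand = supply_from_grid(grid, ca)
        result = allocate(grid, suit, demand, ca, m, res)
        assert result.converged and result.changes == []
        assert result.iterations == 1
        np.testing.assert_array_equal(result.grid.values, grid.values)

    def test_infeasible_demand_reported_without_iterating(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng)
        demand = demand.copy()
        demand[0] = 10 * grid.values.size * ca[:, 0].max()
        result = allocate(grid, suit, demand, ca, m, res)
        assert result.infeasible and result.iterations == 0
        assert result.changes == []

    def test_top_ranked_cells_convert_on_gradient(self):
        """Raising demand by exactly k cells' capacity converts the k most
        suitable eligible cells."""
        n = 10
        values = np.full((n, n), 3, dtype=np.int16)  # all Forest_L
        ca = np.zeros((N_LAND_SYSTEM_CLASSES, N_SERVICES))
        ca[0, 0] = 1.0  # Cropland_L supplies 1 km2 cropland; forest supplies none
        m = np.zeros((N_LAND_SYSTEM_CLASSES, N_LAND_SYSTEM_CLASSES), dtype=np.int8)
        np.fill_diagonal(m, 1)
        m[3, 0] = 1
        res = np.full(N_LAND_SYSTEM_CLASSES, 0.5)
        gradient = np.linspace(0, 1, n * n).reshape(n, n)  # strict ordering
        k = 7
        # the absolute tolerance floor is one cell's capacity, so place the
        # target just above k cells to force exactly k conversions
        demand = np.array([k + 0.5, 0, 0, 0])
        result = allocate(
            as_raster(values), {0: gradient}, demand, ca, m, res,
            AllocationConfig(tolerance=1e-9),
        )
        assert result.converged
        converted = np.flatnonzero(result.grid.values.ravel() == 0)
        expected = np.argsort(gradient.ravel())[-k:]
        assert set(converted) == set(expected)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_greedy_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        grid, suit, demand, ca, m, res = single_service_instance(rng)
        config = AllocationConfig(coarse_cap=400, fine_enabled=False)
        result = allocate(grid, suit, demand, ca, m, res, config)
        if result.infeasible:
            return
        expected, changes = oracle_allocate(grid, suit, demand, ca, m, res, config)
        np.testing.assert_array_equal(result.grid.values, expected)
        assert result.changes == changes

    def test_cell_count_conserved_and_changes_legal(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng, 12, 12)
        result = allocate(grid, suit, demand, ca, m, res)
        assert result.grid.values.size == grid.values.size
        for _, r, c, a, b in result.changes:
            assert m[a, b] == 1 and a != b

    def test_supply_bookkeeping_audit(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng, 12, 12)
        result = allocate(grid, suit, demand, ca, m, res)
        np.testing.assert_allclose(
            result.supply, supply_from_grid(result.grid, ca), atol=1e-9
        )

    def test_frozen_cells_never_change(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng, 10, 10)
        frozen = np.zeros(grid.shape, dtype=bool)
        frozen[:5] = True
        result = allocate(grid, suit, demand, ca, m, res, frozen_mask=frozen)
        np.testing.assert_array_equal(
            result.grid.values[:5], grid.values[:5]
        )

    def test_deterministic_change_log(self, rng):
        grid, suit, demand, ca, m, res = single_service_instance(rng, 10, 10)
        runs = [allocate(grid, suit, demand, ca, m, res) for _ in range(2)]
        assert runs[0].changes == runs[1].changes
        np.testing.assert_array_equal(runs[0].grid.values, runs[1].grid.values)

    def test_monotone_response_to_demand(self):
        rng = np.random.default_rng(77)
        grid, suit, demand, ca, m, res = single_service_instance(rng, 12, 12)
        base = supply_from_grid(grid, ca)[0]
        thr = max(0.001 * base, ca[:, 0].max())
        supplies = []
        for bump in (0.0, 3 * thr, 6 * thr, 9 * thr):
            d = np.zeros(N_SERVICES)
            d[0] = base + bump
            r = allocate(grid, suit, d, ca, m, res)
            supplies.append(r.supply[0])
        assert all(b >= a - 1e-9 for a, b in zip(supplies, supplies[1:]))
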