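"""Demand-driven land-system allocation with adaptive competitive advantage.

The engine iteratively converts cells of a land-system grid until the
supply of the four land-system services (cropland, forest, grassland,
shrubland area) meets exogenous demand. A cell c converts to the candidate
class j with the highest conversion potential

    P_pot(c, j) = P_loc(c, j) + P_res(T0(c)) + P_nei(c, j) + P_comp(c, j)

where P_loc is the location-suitability surface, P_res the per-class
persistence (conversion resistance) of the cell's class at the start of the
external iteration, P_nei the neighbourhood term (0 by default), and P_comp
the adaptive competitive advantage

    P_comp(c, j) = sum_d inertia(d, i) * (CA[j, d] - CA[u, d]) / sum_j CA[j, d]

with u the cell's current class. The inertia of service d accumulates the
demand-supply gap over internal iterations, damped by a slowly growing
speed:

    inertia(d, 1) = 0
    inertia(d, i) = inertia(d, i-1) + (Demand_d - Supply_(d, i-1)) / speed_i
    speed_1 = seed (default 1);  speed_i = speed_(i-1) + step (default 0.001)

so classes whose capacities close the current gaps gain advantage as the
iteration proceeds. The allocation is demand-driven: a candidate conversion
is considered only while it strictly shrinks the aggregate (tolerance-
weighted) supply-demand gap. The coarse phase converts the single best such
candidate per internal iteration (ties break on row-major cell index, then
class code) up to a cap (default 20,000); if demand is still unmet, a fine
phase visits the remaining cells one by one in descending potential and
keeps only gap-shrinking conversions. Within one external iteration a
converted cell is frozen, which rules out oscillation and keeps the greedy
semantics exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .demand import N_SERVICES, SERVICES, supply_from_grid
from .grids import GridError, Raster, check_aligned
from .land_system import N_LAND_SYSTEM_CLASSES

log = logging.getLogger(__name__)

NOT_A_CANDIDATE = -np.inf  # sentinel potential for forbidden conversions


def derive_conversion_matrix(ls_y1: Raster, ls_y2: Raster) -> np.ndarray:
    """Binary from->to permission matrix observed between two maps.

    M[a, b] = 1 iff at least one cell transitioned a -> b; the diagonal is
    forced to 1 (staying put is always permitted).
    """
    check_aligned(ls_y1, ls_y2)
    valid = ls_y1.valid_mask() & ls_y2.valid_mask()
    m = np.zeros((N_LAND_SYSTEM_CLASSES, N_LAND_SYSTEM_CLASSES), dtype=np.int8)
    a = ls_y1.values[valid].astype(np.int64)
    b = ls_y2.values[valid].astype(np.int64)
    np.add.at(m, (a, b), 1)
    m = (m > 0).astype(np.int8)
    np.fill_diagonal(m, 1)
    return m


def estimate_resistance(
    ls_y1: Raster, ls_y2: Raster, default: float = 0.5
) -> np.ndarray:
    """Per-class persistence between two dates: the share of class-t cells
    at y1 still of class t at y2. Classes unseen at y1 get ``default``."""
    check_aligned(ls_y1, ls_y2)
    valid = ls_y1.valid_mask() & ls_y2.valid_mask()
    a = ls_y1.values[valid].astype(np.int64)
    b = ls_y2.values[valid].astype(np.int64)
    total = np.bincount(a, minlength=N_LAND_SYSTEM_CLASSES).astype(float)
    kept = np.bincount(a[a == b], minlength=N_LAND_SYSTEM_CLASSES).astype(float)
    with np.errstate(invalid="ignore"):
        res = np.where(total > 0, kept / np.maximum(total, 1), default)
    return res


@dataclass
class CompetitiveState:
    """Inertia/speed bookkeeping of the adaptive competitive advantage."""

    seed: float = 1.0
    step: float = 0.001
    i: int = 1
    speed: float = field(init=False)
    inertia: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.seed <= 0:
            raise GridError(f"speed seed must be positive, got {self.seed}")
        self.speed = self.seed
        self.inertia = np.zeros(N_SERVICES)


def update_competitive_state(
    state: CompetitiveState, demand: np.ndarray, supply_prev: np.ndarray
) -> CompetitiveState:
    """Advance to the next internal iteration: grow speed by one step and
    accumulate each service's (demand - supply)/speed into its inertia."""
    state.i += 1
    state.speed += state.step
    if state.speed <= 0:
        raise GridError("speed became non-positive")
    state.inertia = state.inertia + (np.asarray(demand) - np.asarray(supply_prev)) / state.speed
    return state


def competitive_advantage_matrix(
    state: CompetitiveState, ca: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """P_comp as a (from-class u, to-class j) matrix plus unservable services.

    The normalizer of service d is the capacity column sum over all classes;
    a service with zero total capacity but nonzero inertia is flagged
    unservable and contributes nothing.
    """
    denom = ca.sum(axis=0)
    unservable = [
        SERVICES[d]
        for d in range(N_SERVICES)
        if denom[d] == 0 and state.inertia[d] != 0
    ]
    scale = np.divide(
        state.inertia, denom, out=np.zeros(N_SERVICES), where=denom > 0
    )
    # comp[u, j] = sum_d scale_d * (ca[j,d] - ca[u,d])
    weighted = ca @ scale
    return weighted[None, :] - weighted[:, None], unservable


def competitive_advantage(
    j: int, u: int, state: CompetitiveState, ca: np.ndarray
) -> float:
    """Scalar P_comp for converting a cell of class u to class j."""
    comp, _ = competitive_advantage_matrix(state, ca)
    return float(comp[u, j])


def conversion_potential(
    p_loc: float, p_res: float, p_comp: float, p_nei: float = 0.0
) -> float:
    """Conversion potential: the plain sum of its four components."""
    return p_loc + p_res + p_nei + p_comp


@dataclass
class AllocationConfig:
    tolerance: float = 0.001          # relative, per service
    coarse_cap: int = 20_000          # internal-iteration cap, coarse phase
    fine_enabled: bool = True
    neighbourhood_weight: float = 0.0  # kept at 0; hook only
    comp_seed: float = 1.0            # Seed of the speed sequence
    comp_step: float = 0.001          # Step of the speed sequence

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.coarse_cap < 1:
            raise GridError("tolerance must be > 0 and coarse_cap >= 1")


@dataclass
class AllocationResult:
    grid: Raster
    converged: bool
    infeasible: bool
    iterations: int
    fine_visited: int
    changes: list[tuple[int, int, int, int, int]]  # (iteration, row, col, from, to)
    supply: np.ndarray
    demand: np.ndarray
    thresholds: np.ndarray
    unservable: list[str]
    state: CompetitiveState

    @property
    def gaps(self) -> np.ndarray:
        return self.supply - self.demand


def _demand_vector(demand) -> np.ndarray:
    if isinstance(demand, dict):
        return np.array([float(demand[d]) for d in SERVICES])
    demand = np.asarray(demand, dtype=float)
    if demand.shape != (N_SERVICES,):
        raise GridError(f"demand must cover the {N_SERVICES} services")
    return demand


def allocate(
    initial: Raster,
    suitability: dict[int, np.ndarray],
    demand,
    ca: np.ndarray,
    conversion_matrix: np.ndarray,
    resistance: np.ndarray,
    config: AllocationConfig | None = None,
    frozen_mask: np.ndarray | None = None,
) -> AllocationResult:
    """One external iteration of the allocation engine.

    Parameters
    ----------
    initial : land-system grid at the start of the external iteration.
    suitability : {candidate class code: P_loc surface}; only these classes
        can be converted *to*.
    demand : per-service demand in km² (dict keyed by service or array in
        service order).
    ca : (30, 4) supply-capacity matrix in km² per cell.
    conversion_matrix, resistance : from->to permissions and per-class
        persistence, both indexed by class code.
    frozen_mask : optional boolean spatial-constraint mask; True cells never
        change.

    Returns the final grid plus diagnostics (change log, convergence /
    infeasibility flags, final supply and gaps, competitive state). Demand
    beyond what any permitted re-labelling of the grid could supply is
    reported as infeasible before iterating.
    """
    config = config or AllocationConfig()
    demand_vec = _demand_vector(demand)
    if not np.all(np.isfinite(demand_vec)):
        raise GridError("demand must be finite")
    cand = sorted(suitability)
    if any(j < 0 or j >= N_LAND_SYSTEM_CLASSES for j in cand):
        raise GridError(f"candidate classes out of range: {cand}")

    nrow, ncol = initial.shape
    n = nrow * ncol
    cur = initial.values.astype(np.int64).ravel().copy()
    valid = initial.valid_mask().ravel()
    t0 = cur.copy()

    frozen = np.zeros(n, dtype=bool)
    if frozen_mask is not None:
        frozen |= np.asarray(frozen_mask, dtype=bool).ravel()
    frozen |= ~valid

    # base potential P_loc + P_res(T0); nodata/NaN suitability is excluded
    base = np.full((n, len(cand)), NOT_A_CANDIDATE)
    suit_ok = np.zeros((n, len(cand)), dtype=bool)
    allowed = np.zeros((n, len(cand)), dtype=bool)
    for k, j in enumerate(cand):
        surf = np.asarray(suitability[j], dtype=np.float64)
        if surf.shape != (nrow, ncol):
            raise GridError(f"suitability surface for class {j} has shape {surf.shape}")
        suit_ok[:, k] = valid & np.isfinite(surf.ravel())
        ok = suit_ok[:, k] & (conversion_matrix[t0, j] == 1)
        allowed[:, k] = ok
        base[suit_ok[:, k], k] = (
            surf.ravel()[suit_ok[:, k]] + resistance[t0[suit_ok[:, k]]]
        )

    supply = supply_from_grid(initial, ca)
    thresholds = np.maximum(config.tolerance * np.abs(demand_vec), ca.max(axis=0))
    # a service with no demand and no capacity has a gap of exactly zero;
    # give it a dummy positive band so the weighted-gap arithmetic is defined
    thresholds = np.where(thresholds > 0, thresholds, 1.0)

    def converged_now(s: np.ndarray) -> bool:
        return bool(np.all(np.abs(s - demand_vec) <= thresholds))

    # feasibility: the best any permitted relabelling could supply
    best_ca = np.full((N_LAND_SYSTEM_CLASSES, N_SERVICES), -np.inf)
    for u in np.unique(t0[valid]):
        reach = [j for k, j in enumerate(cand) if conversion_matrix[u, j] == 1]
        reach_ca = ca[reach + [u]] if reach else ca[[u]]
        best_ca[u] = reach_ca.max(axis=0)
    max_supply = np.zeros(N_SERVICES)
    for u in np.unique(t0[valid]):
        max_supply += best_ca[u] * np.sum(valid & (t0 == u))
    infeasible_services = demand_vec > max_supply + thresholds
    state = CompetitiveState(seed=config.comp_seed, step=config.comp_step)
    if infeasible_services.any():
        bad = [SERVICES[d] for d in np.flatnonzero(infeasible_services)]
        log.warning("demand infeasible for %s; not iterating", bad)
        return AllocationResult(
            grid=initial.with_values(initial.values.copy()), converged=False,
            infeasible=True, iterations=0, fine_visited=0, changes=[],
            supply=supply, demand=demand_vec, thresholds=thresholds,
            unservable=bad, state=state,
        )

    changes: list[tuple[int, int, int, int, int]] = []
    unservable: list[str] = []
    cand_arr = np.array(cand)

    # weighted-gap change of a u -> j relabel depends on (u, j) only
    delta_ca = ca[None, :, :] - ca[:, None, :]  # (u, j, d)

    def _gap_caps(g: np.ndarray) -> np.ndarray:
        """Per-service bound on the post-move |gap|: a service inside its
        tolerance band must stay inside; one outside may slip by at most
        one band width per move (the aggregate still has to shrink)."""
        in_band = np.abs(g) <= thresholds
        return np.where(in_band, thresholds, np.abs(g) + thresholds)

    def improving_pairs(s: np.ndarray) -> np.ndarray:
        """(30, 30) mask of relabels that strictly shrink the weighted gap
        while respecting the per-service caps."""
        g = s - demand_vec
        now = np.sum(np.abs(g) / thresholds)
        new_abs = np.abs(g[None, None, :] + delta_ca)
        shrink = np.sum(new_abs / thresholds, axis=2) < now - 1e-12
        no_harm = np.all(new_abs <= _gap_caps(g)[None, None, :] + 1e-12, axis=2)
        return shrink & no_harm

    def acceptable_move(s: np.ndarray, u: int, j: int) -> bool:
        g = s - demand_vec
        new = np.abs(g + ca[j] - ca[u])
        return bool(
            np.sum(new / thresholds) < np.sum(np.abs(g) / thresholds) - 1e-12
            and np.all(new <= _gap_caps(g) + 1e-12)
        )

    # ---- coarse phase: one conversion per internal iteration --------------
    while state.i <= config.coarse_cap:
        if converged_now(supply):
            break
        comp, unservable = competitive_advantage_matrix(state, ca)
        pot = base + comp[cur][:, cand_arr]
        improve = improving_pairs(supply)
        mask = (
            allowed
            & ~frozen[:, None]
            & (cur[:, None] != cand_arr[None, :])
            & improve[cur][:, cand_arr]
        )
        pot = np.where(mask, pot, NOT_A_CANDIDATE)
        flat_best = int(pot.argmax())  # row-major: cell index, then class code
        c, k = divmod(flat_best, len(cand))
        if pot[c, k] == NOT_A_CANDIDATE:
            log.info("no gap-reducing candidates left at iteration %d", state.i)
            break
        j = cand[k]
        changes.append((state.i, c // ncol, c % ncol, int(cur[c]), j))
        supply = supply + ca[j] - ca[cur[c]]
        cur[c] = j
        frozen[c] = True
        update_competitive_state(state, demand_vec, supply)

    # ---- fine phase: cell-by-cell sweep, gap-shrinking moves only ---------
    # unlike the coarse phase, cells already converted may be revisited; the
    # strict-decrease acceptance rule still guarantees termination
    fine_visited = 0
    if config.fine_enabled and not converged_now(supply):
        blocked = np.zeros(n, dtype=bool)
        if frozen_mask is not None:
            blocked |= np.asarray(frozen_mask, dtype=bool).ravel()
        blocked |= ~valid
        comp, unservable = competitive_advantage_matrix(state, ca)
        # permissions follow the cell's *current* class in this phase
        mask = (
            suit_ok
            & ~blocked[:, None]
            & (conversion_matrix[cur][:, cand_arr] == 1)
            & (cur[:, None] != cand_arr[None, :])
        )
        pot = np.where(mask, base + comp[cur][:, cand_arr], NOT_A_CANDIDATE)
        cell_best = pot.max(axis=1)
        order = np.argsort(-cell_best, kind="stable")
        for c in order:
            if cell_best[c] == NOT_A_CANDIDATE:
                break
            if converged_now(supply):
                break
            fine_visited += 1
            # best admissible class for this cell under the current state
            row_ok = (
                suit_ok[c]
                & (conversion_matrix[cur[c]][cand_arr] == 1)
                & (cand_arr != cur[c])
            )
            p = np.where(row_ok, base[c] + comp[cur[c]][cand_arr], NOT_A_CANDIDATE)
            k = int(p.argmax())
            if p[k] == NOT_A_CANDIDATE:
                continue
            j = cand[k]
            if acceptable_move(supply, int(cur[c]), j):
                changes.append((state.i, c // ncol, c % ncol, int(cur[c]), j))
                supply = supply + ca[j] - ca[cur[c]]
                cur[c] = j
                update_competitive_state(state, demand_vec, supply)
                comp, unservable = competitive_advantage_matrix(state, ca)

    final = initial.with_values(cur.reshape(nrow, ncol).astype(initial.values.dtype))
    result = AllocationResult(
        grid=final, converged=converged_now(supply), infeasible=False,
        iterations=state.i, fine_visited=fine_visited, changes=changes,
        supply=supply, demand=demand_vec, thresholds=thresholds,
        unservable=unservable, state=state,
    )
    if not result.converged:
        log.warning(
            "allocation did not converge: gaps %s (thresholds %s)",
            result.gaps, thresholds,
        )
    return result


def interpolate_demand(
    start: dict[str, float], end: dict[str, float], n_steps: int
) -> list[dict[str, float]]:
    """Linear per-service demand interpolation across a simulation horizon;
    returns ``n_steps`` targets ending exactly at ``end``."""
    if n_steps < 1:
        raise GridError("need at least one step")
    return [
        {
            d: start[d] + (end[d] - start[d]) * (s + 1) / n_steps
            for d in SERVICES
        }
        for s in range(n_steps)
    ]
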