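"""Capacitated set-covering placement of community health workers.

The model minimizes the total number of CHWs

    min Z = sum_j Y_j

subject to, for demand cells i with population a_i and candidate sites j
with per-CHW capacity k_j:

    sum_{j in N_i} X_ij >= 1            (universal coverage)
    sum_i a_i X_ij - k_j Y_j <= 0       (capacity)
    Y_j a nonnegative integer, X_ij in [0, 1]

where N_i is the set of sites within the walking-time cutoff of cell i
and X_ij is the fraction of cell i's inhabitants assigned to site j.
Unlike the classical binary-site formulation, Y_j counts CHWs, so several
CHWs may share one site — necessary in dense cells whose population
exceeds any single CHW's capacity.

The default backend is the HiGHS mixed-integer solver shipped with scipy
(:func:`scipy.optimize.milp`). An exhaustive-enumeration oracle
(:func:`brute_force_solve`) certifies optimality on tiny instances via a
max-flow transportation feasibility check, and :func:`check_solution`
audits any solution against the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse.csgraph import maximum_flow

from .grids import AdminPartition
from .scenarios import CapacityMap, DemandSet
from .travel import TravelTimeMatrix

__all__ = [
    "CsclModel",
    "Solution",
    "InfeasibleModelError",
    "build_model",
    "solve",
    "brute_force_solve",
    "check_solution",
    "solve_partitioned",
    "write_lp",
]


class InfeasibleModelError(ValueError):
    """Raised when demand cells have no candidate site within the cutoff."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(
            f"{len(self.cells)} demand cell(s) have an empty neighborhood "
            f"(unreachable under the walking-time cutoff): {self.cells[:20]}"
        )


@dataclass
class CsclModel:
    """Sparse CSCLP instance over flat grid cell ids.

    ``pair_i``/``pair_j`` index into ``demand_cells``/``site_cells`` and
    enumerate the stored (i, j) pairs with d_ij <= S; ``pair_time`` keeps
    the walking minutes for reporting.
    """

    demand_cells: np.ndarray  # flat ids, shape (nI,)
    a: np.ndarray  # persons per demand cell
    site_cells: np.ndarray  # flat ids, shape (nJ,)
    k: np.ndarray  # capacity per site
    pair_i: np.ndarray  # positions into demand_cells
    pair_j: np.ndarray  # positions into site_cells
    pair_time: np.ndarray
    cutoff_min: float = 60.0

    @property
    def n_demand(self) -> int:
        return self.demand_cells.size

    @property
    def n_sites(self) -> int:
        return self.site_cells.size

    @property
    def n_pairs(self) -> int:
        return self.pair_i.size

    def neighborhoods(self) -> list[np.ndarray]:
        """Site positions reachable from each demand cell."""
        out: list[list[int]] = [[] for _ in range(self.n_demand)]
        for ii, jj in zip(self.pair_i, self.pair_j):
            out[ii].append(jj)
        return [np.array(x, dtype=int) for x in out]

    def y_upper_bounds(self) -> np.ndarray:
        """Valid per-site bounds ceil(reachable population / k_j).

        The model itself is unbounded in Y; this bound can never cut an
        optimum (no more CHWs than needed to absorb every person who can
        reach the site) and is passed to the solver as a search aid.
        """
        reach = np.zeros(self.n_sites)
        np.add.at(reach, self.pair_j, self.a[self.pair_i])
        return np.ceil(reach / self.k).astype(int)


@dataclass
class Solution:
    """Solver output: integer CHW counts Y, allocations X, objective Z."""

    Y: np.ndarray  # integer per site
    X: np.ndarray  # fraction per stored pair, aligned with model.pair_i/j
    objective: int
    status: str  # optimal | gap_optimal | infeasible
    gap_abs: float = 0.0
    solver_message: str = ""

    @property
    def total_chws(self) -> int:
        return int(self.objective)

    def sites_frame(self, model: CsclModel, ncol: int | None = None) -> pd.DataFrame:
        rows = []
        for pos, y in enumerate(self.Y):
            if y > 0:
                cell = int(model.site_cells[pos])
                r, c = divmod(cell, ncol) if ncol else (cell, -1)
                rows.append({"cell": cell, "row": r, "col": c, "Y": int(y), "k": model.k[pos]})
        return pd.DataFrame(rows, columns=["cell", "row", "col", "Y", "k"])

    def allocations_frame(self, model: CsclModel) -> pd.DataFrame:
        keep = self.X > 1e-12
        return pd.DataFrame(
            {
                "demand_cell": model.demand_cells[model.pair_i[keep]],
                "site_cell": model.site_cells[model.pair_j[keep]],
                "X": self.X[keep],
                "persons": model.a[model.pair_i[keep]] * self.X[keep],
                "minutes": model.pair_time[keep],
            }
        )


def build_model(demand: DemandSet, capacity: CapacityMap, ttm: TravelTimeMatrix) -> CsclModel:
    """Assemble the sparse model from demand, capacities and travel times.

    Only pairs whose endpoints are in the demand and site sets are kept.
    A demand cell with an empty neighborhood signals population
    unreachable within the cutoff and raises :class:`InfeasibleModelError`.
    """
    d_pos = {int(c): p for p, c in enumerate(demand.demand_index)}
    s_pos = {int(c): p for p, c in enumerate(capacity.site_index)}
    pi, pj, pt = [], [], []
    for (i, j), t in ttm.entries.items():
        if i in d_pos and j in s_pos:
            pi.append(d_pos[i])
            pj.append(s_pos[j])
            pt.append(t)
    pair_i = np.array(pi, dtype=int)
    pair_j = np.array(pj, dtype=int)
    covered = np.zeros(len(d_pos), dtype=bool)
    if pair_i.size:
        covered[pair_i] = True
    if not covered.all():
        missing = demand.demand_index[~covered]
        raise InfeasibleModelError([int(c) for c in missing])
    order = np.lexsort((pair_j, pair_i))
    return CsclModel(
        demand_cells=np.asarray(demand.demand_index, dtype=int),
        a=np.asarray(demand.a, dtype=float),
        site_cells=np.asarray(capacity.site_index, dtype=int),
        k=np.asarray(capacity.k, dtype=float),
        pair_i=pair_i[order],
        pair_j=pair_j[order],
        pair_time=np.array(pt, dtype=float)[order],
        cutoff_min=ttm.cutoff_min,
    )


def _constraint_matrices(model: CsclModel):
    """Coverage and capacity constraint blocks over [Y, X] variables."""
    nY, nX, nI = model.n_sites, model.n_pairs, model.n_demand
    p = np.arange(nX)
    # coverage: sum_j X_ij >= 1 for each i
    cov = sp.coo_matrix(
        (np.ones(nX), (model.pair_i, nY + p)), shape=(nI, nY + nX)
    ).tocsr()
    # capacity: sum_i a_i X_ij - k_j Y_j <= 0 for each j
    cap_x = sp.coo_matrix(
        (model.a[model.pair_i], (model.pair_j, nY + p)), shape=(model.n_sites, nY + nX)
    )
    cap_y = sp.coo_matrix(
        (-model.k, (np.arange(nY), np.arange(nY))), shape=(model.n_sites, nY + nX)
    )
    cap = (cap_x + cap_y).tocsr()
    return cov, cap


def _strengthening_cuts(model: CsclModel):
    """Valid inequalities in Y that tighten the LP relaxation.

    Neither family can cut off an integer solution:

    * set-covering cut, one per demand cell: sum_{j in N_i} Y_j >= 1.
      X_ij > 0 forces Y_j >= 1 through the capacity row, so some
      reachable site of every covered cell must host a CHW.
    * absorption cut, one per demand cell: sum_{j in N_i} k_j Y_j >= a_i.
      Cell i ships its whole population into its neighborhood, whose
      total CHW capacity must absorb it.

    Without them the relaxation spreads fractional CHWs of size a_i/k_j
    over the grid and the branch-and-bound gap is enormous.
    """
    nY, nX, nI = model.n_sites, model.n_pairs, model.n_demand
    ones = sp.coo_matrix(
        (np.ones(nX), (model.pair_i, model.pair_j)), shape=(nI, nY)
    ).tocsr()
    ones.data[:] = np.minimum(ones.data, 1.0)  # collapse duplicate pairs
    setcover = sp.hstack([ones, sp.csr_matrix((nI, nX))]).tocsr()
    kweighted = sp.coo_matrix(
        (model.k[model.pair_j], (model.pair_i, model.pair_j)), shape=(nI, nY)
    ).tocsr()
    absorb = sp.hstack([kweighted, sp.csr_matrix((nI, nX))]).tocsr()
    return setcover, absorb


def solve(model: CsclModel, gap_abs: float = 0.0, time_limit: float | None = None) -> Solution:
    """Solve the mixed-integer program with the HiGHS backend.

    ``gap_abs`` is the allowed optimality gap in whole CHWs (the natural
    unit for this problem); 0 demands a proven optimum. The backend takes
    a relative gap, so the absolute gap is converted conservatively using
    an upper bound on Z, guaranteeing the absolute deviation never
    exceeds ``gap_abs``.
    """
    if model.n_demand == 0:
        return Solution(
            Y=np.zeros(model.n_sites, dtype=int),
            X=np.zeros(0),
            objective=0,
            status="optimal",
            gap_abs=gap_abs,
        )
    nY, nX = model.n_sites, model.n_pairs
    c = np.concatenate([np.ones(nY), np.zeros(nX)])
    cov, cap = _constraint_matrices(model)
    setcover, absorb = _strengthening_cuts(model)
    constraints = [
        LinearConstraint(cov, lb=np.ones(model.n_demand), ub=np.inf),
        LinearConstraint(cap, lb=-np.inf, ub=np.zeros(model.n_sites)),
        LinearConstraint(setcover, lb=np.ones(model.n_demand), ub=np.inf),
        LinearConstraint(absorb, lb=model.a, ub=np.inf),
    ]
    ub = np.concatenate([model.y_upper_bounds().astype(float), np.ones(nX)])
    bounds = Bounds(lb=np.zeros(nY + nX), ub=ub)
    integrality = np.concatenate([np.ones(nY), np.zeros(nX)])
    options: dict = {}
    if gap_abs > 0:
        # Z <= sum of per-site bounds is a crude but safe upper bound
        z_ub = max(1.0, float(model.y_upper_bounds().sum()))
        options["mip_rel_gap"] = gap_abs / z_ub
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    if res.x is None:
        return Solution(
            Y=np.zeros(nY, dtype=int),
            X=np.zeros(nX),
            objective=-1,
            status="infeasible",
            gap_abs=gap_abs,
            solver_message=res.message,
        )
    Y = np.rint(res.x[:nY]).astype(int)
    X = np.clip(res.x[nY:], 0.0, 1.0)
    if res.status == 0:
        status = "optimal" if gap_abs == 0 else "gap_optimal"
    else:  # feasible incumbent returned at a resource limit
        status = "gap_optimal"
    return Solution(
        Y=Y,
        X=X,
        objective=int(round(Y.sum())),
        status=status,
        gap_abs=gap_abs,
        solver_message=res.message,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle

_FLOW_SCALE = 1000  # person -> millipersons, for integer max-flow capacities


def _transport_feasible(model: CsclModel, Y: np.ndarray):
    """Transportation feasibility of CHW counts Y via integer max-flow.

    Network: source -> demand i (cap a_i) -> reachable sites j (cap a_i)
    -> sink (cap k_j * Y_j). Y is feasible iff the max flow saturates all
    demand. Populations are scaled to integer millipersons.
    """
    nI, nJ = model.n_demand, model.n_sites
    src, sink = 0, 1 + nI + nJ
    a_int = np.rint(model.a * _FLOW_SCALE).astype(np.int64)
    cap_int = np.rint(model.k * Y * _FLOW_SCALE).astype(np.int64)
    rows = list(np.zeros(nI, dtype=int))
    cols = list(1 + np.arange(nI))
    caps = list(a_int)
    rows += list(1 + model.pair_i)
    cols += list(1 + nI + model.pair_j)
    caps += list(a_int[model.pair_i])
    rows += list(1 + nI + np.arange(nJ))
    cols += [sink] * nJ
    caps += list(cap_int)
    graph = sp.csr_matrix(
        (np.array(caps, dtype=np.int64), (np.array(rows), np.array(cols))),
        shape=(sink + 1, sink + 1),
    )
    res = maximum_flow(graph, src, sink)
    if res.flow_value < a_int.sum():
        return None
    flow = res.flow.tocsr()
    X = np.zeros(model.n_pairs)
    for p, (ii, jj) in enumerate(zip(model.pair_i, model.pair_j)):
        X[p] = flow[1 + ii, 1 + nI + jj] / max(a_int[ii], 1)
    return np.clip(X, 0.0, 1.0)


def brute_force_solve(model: CsclModel, max_total: int = 10) -> Solution:
    """Exact solve by enumerating Y vectors in order of total CHW count.

    For each candidate total t = 0, 1, ..., every composition of t over
    the sites (respecting the valid per-site bounds) is tested for
    transportation feasibility with a max-flow certificate; the first
    feasible vector is optimal. Intended as an independent oracle on tiny
    instances (|J| <= 8).
    """
    if model.n_sites > 8:
        raise ValueError("brute-force oracle is limited to at most 8 sites")
    if model.n_demand == 0:
        return Solution(np.zeros(model.n_sites, dtype=int), np.zeros(0), 0, "optimal")
    ub = model.y_upper_bounds()
    total_a = model.a.sum()
    for t in range(0, max_total + 1):
        for combo in _compositions(t, ub):
            Y = np.array(combo, dtype=int)
            if float((model.k * Y).sum()) + 1e-9 < total_a:
                continue  # cannot absorb everyone
            X = _transport_feasible(model, Y)
            if X is not None:
                return Solution(Y=Y, X=X, objective=t, status="optimal")
    return Solution(
        Y=np.zeros(model.n_sites, dtype=int),
        X=np.zeros(model.n_pairs),
        objective=-1,
        status="infeasible",
        solver_message=f"no feasible placement with at most {max_total} CHWs",
    )


def _compositions(total: int, ub: np.ndarray):
    """All vectors 0 <= y <= ub with sum(y) == total, lexicographic."""
    n = len(ub)

    def rec(pos: int, remaining: int):
        if pos == n - 1:
            if remaining <= ub[pos]:
                yield (remaining,)
            return
        for v in range(min(remaining, ub[pos]) + 1):
            for tail in rec(pos + 1, remaining - v):
                yield (v,) + tail

    if n == 0:
        if total == 0:
            yield ()
        return
    yield from rec(0, total)


def check_solution(sol: Solution, model: CsclModel, tol: float = 1e-6) -> list[str]:
    """Audit a solution against the constraints; returns violations.

    Checks per-cell coverage >= 1 - tol, per-site inflow <= k_j Y_j (with
    relative slack tol), Y integrality/nonnegativity and X in [0, 1]. An
    empty list means the solution is valid.
    """
    violations: list[str] = []
    if sol.status == "infeasible":
        return ["solution is infeasible"]
    if np.any(sol.Y < 0) or np.any(np.abs(sol.Y - np.rint(sol.Y)) > tol):
        violations.append("Y contains negative or non-integer entries")
    if sol.X.size and (sol.X.min() < -tol or sol.X.max() > 1 + tol):
        violations.append("X outside [0, 1]")
    coverage = np.zeros(model.n_demand)
    np.add.at(coverage, model.pair_i, sol.X)
    for pos in np.nonzero(coverage < 1 - tol)[0]:
        violations.append(
            f"coverage {coverage[pos]:.8f} < 1 at demand cell {int(model.demand_cells[pos])}"
        )
    inflow = np.zeros(model.n_sites)
    np.add.at(inflow, model.pair_j, model.a[model.pair_i] * sol.X)
    limit = model.k * sol.Y
    slack_tol = tol * np.maximum(1.0, model.k)
    for pos in np.nonzero(inflow > limit + slack_tol)[0]:
        violations.append(
            f"capacity exceeded at site {int(model.site_cells[pos])}: "
            f"inflow {inflow[pos]:.3f} > {limit[pos]:.3f}"
        )
    return violations


def solve_partitioned(
    demand: DemandSet,
    capacity: CapacityMap,
    ttm: TravelTimeMatrix,
    partition: AdminPartition,
    gap_abs: float | dict[int, float] = 0.0,
    time_limit: float | None = None,
) -> dict[int, tuple[CsclModel, Solution]]:
    """Solve one independent model per administrative zone.

    Demand cells, sites and stored pairs are restricted to each zone;
    pairs straddling a zone border are dropped from both zone models,
    mirroring independent per-department runs. Returns
    ``{zone_id: (model, solution)}``; the national total is the sum of
    zone objectives. Per-zone infeasibility propagates with the zone id.
    """
    flat_zone = partition.zone_id.ravel()
    results: dict[int, tuple[CsclModel, Solution]] = {}
    for zid in partition.zones():
        zid = int(zid)
        d_in = flat_zone[demand.demand_index] == zid
        s_in = flat_zone[capacity.site_index] == zid
        if not d_in.any():
            continue
        sub_demand = DemandSet(demand.demand_index[d_in], demand.a[d_in])
        sub_capacity = CapacityMap(capacity.site_index[s_in], capacity.k[s_in])
        d_set = set(int(c) for c in sub_demand.demand_index)
        s_set = set(int(c) for c in sub_capacity.site_index)
        sub_entries = {
            (i, j): t for (i, j), t in ttm.entries.items() if i in d_set and j in s_set
        }
        sub_ttm = TravelTimeMatrix(
            cutoff_min=ttm.cutoff_min,
            demand_index=sub_demand.demand_index,
            site_index=sub_capacity.site_index,
            entries=sub_entries,
        )
        try:
            model = build_model(sub_demand, sub_capacity, sub_ttm)
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(exc.cells) from exc
        gz = gap_abs.get(zid, 0.0) if isinstance(gap_abs, dict) else gap_abs
        sol = solve(model, gap_abs=gz, time_limit=time_limit)
        if sol.status == "infeasible":
            raise InfeasibleModelError([f"zone {zid} infeasible: {sol.solver_message}"])
        results[zid] = (model, sol)
    return results


def write_lp(model: CsclModel, path) -> None:
    """Export the model in CPLEX LP text format for external solvers."""
    with open(path, "w") as fh:
        fh.write("Minimize\n obj: " + " + ".join(f"Y{j}" for j in range(model.n_sites)) + "\n")
        fh.write("Subject To\n")
        neigh = model.neighborhoods()
        pair_pos = {(ii, jj): p for p, (ii, jj) in enumerate(zip(model.pair_i, model.pair_j))}
        for i, js in enumerate(neigh):
            terms = " + ".join(f"X{pair_pos[(i, int(j))]}" for j in js)
            fh.write(f" cover{i}: {terms} >= 1\n")
        by_site: dict[int, list[int]] = {}
        for p, jj in enumerate(model.pair_j):
            by_site.setdefault(int(jj), []).append(p)
        for j, ps in by_site.items():
            terms = " + ".join(f"{model.a[model.pair_i[p]]:.10g} X{p}" for p in ps)
            fh.write(f" cap{j}: {terms} - {model.k[j]:.10g} Y{j} <= 0\n")
        fh.write("Bounds\n")
        for j, ub in enumerate(model.y_upper_bounds()):
            fh.write(f" 0 <= Y{j} <= {int(ub)}\n")
        for p in range(model.n_pairs):
            fh.write(f" 0 <= X{p} <= 1\n")
        fh.write("General\n " + " ".join(f"Y{j}" for j in range(model.n_sites)) + "\nEnd\n")
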