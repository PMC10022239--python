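"""End-to-end orchestration: layers -> classification -> access ->
scenario materialization -> optimization -> summary, plus the +/-10%
parameter sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AdminPartition, FacilityList, Grid, facilities_to_cells
from .optimizer import CsclModel, Solution, build_model, solve, solve_partitioned
from .scenarios import (
    CapacityMap,
    DemandSet,
    ScenarioSpec,
    build_capacity_map,
    build_demand_set,
    load_scenario,
)
from .travel import access_surface, population_share_beyond, travel_matrix
from .urbanization import UrbanLabelGrid, apply_metropolitan, classify_urban
from .workload import SolutionSummary, summarize

__all__ = ["PipelineResult", "run_scenario", "merge_zone_results", "sensitivity", "SENSITIVITY_PARAMS"]


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one scenario run."""

    spec: ScenarioSpec
    labels: UrbanLabelGrid
    ccs_access: Grid
    demand: DemandSet
    capacity: CapacityMap
    model: CsclModel | None
    solution: Solution | None
    summary: SolutionSummary | None
    zone_results: dict[int, tuple[CsclModel, Solution]] | None = None

    @property
    def total_chws(self) -> int:
        return 0 if self.solution is None else self.solution.total_chws


def merge_zone_results(
    zone_results: dict[int, tuple[CsclModel, Solution]],
) -> tuple[CsclModel, Solution]:
    """Concatenate disjoint per-zone models/solutions into national ones."""
    models = [m for m, _ in zone_results.values()]
    sols = [s for _, s in zone_results.values()]
    off_i = np.cumsum([0] + [m.n_demand for m in models[:-1]])
    off_j = np.cumsum([0] + [m.n_sites for m in models[:-1]])
    model = CsclModel(
        demand_cells=np.concatenate([m.demand_cells for m in models]),
        a=np.concatenate([m.a for m in models]),
        site_cells=np.concatenate([m.site_cells for m in models]),
        k=np.concatenate([m.k for m in models]),
        pair_i=np.concatenate([m.pair_i + o for m, o in zip(models, off_i)]),
        pair_j=np.concatenate([m.pair_j + o for m, o in zip(models, off_j)]),
        pair_time=np.concatenate([m.pair_time for m in models]),
        cutoff_min=models[0].cutoff_min,
    )
    sol = Solution(
        Y=np.concatenate([s.Y for s in sols]),
        X=np.concatenate([s.X for s in sols]),
        objective=int(sum(s.objective for s in sols)),
        status="optimal" if all(s.status == "optimal" for s in sols) else "gap_optimal",
        gap_abs=max(s.gap_abs for s in sols),
    )
    return model, sol


def run_scenario(
    region,
    scenario,
    density_threshold: float = 300.0,
    cluster_pop_threshold: float = 2000.0,
    connectivity: int = 8,
    gap_abs: float = 0.0,
    partitioned: bool = False,
    time_limit: float | None = None,
) -> PipelineResult:
    """Run the full placement pipeline for one scenario.

    ``region`` is any object with attributes ``pop`` and ``friction``
    (Grids), ``facilities`` (FacilityList), ``metro_mask`` (bool array)
    and ``zones`` (AdminPartition) — a SyntheticRegion or file-loaded
    layers. With ``partitioned=True`` each zone is solved independently
    and results are merged for the summary.
    """
    pop: Grid = region.pop
    friction: Grid = region.friction
    facilities: FacilityList = region.facilities
    spec = load_scenario(scenario)

    labels = classify_urban(
        pop,
        density_threshold=density_threshold,
        cluster_pop_threshold=cluster_pop_threshold,
        connectivity=connectivity,
    )
    if region.metro_mask is not None:
        labels = apply_metropolitan(labels, region.metro_mask)

    ccs = FacilityList(
        points=facilities.ccs_points(), is_ccs=np.ones(int(facilities.is_ccs.sum()), bool)
    )
    ccs_cells = facilities_to_cells(ccs, pop)
    access = access_surface(friction, ccs_cells, connectivity=connectivity)

    demand = build_demand_set(pop, access, spec)
    if demand.demand_index.size == 0:
        warnings.warn(f"scenario {spec.id!r}: empty demand set (fully covered)")
        return PipelineResult(spec, labels, access, demand,
                              CapacityMap(np.array([0]), np.array([1.0])),
                              None, None, None)
    capacity = build_capacity_map(labels, access, pop, spec)
    ncol = pop.shape[1]
    cells = [divmod(int(f), ncol) for f in demand.demand_index]
    site_cells = [divmod(int(f), ncol) for f in capacity.site_index]
    ttm = travel_matrix(friction, cells, site_cells, spec.max_walk_min, connectivity=connectivity)

    zone_results = None
    if partitioned:
        zone_results = solve_partitioned(
            demand, capacity, ttm, region.zones, gap_abs=gap_abs, time_limit=time_limit
        )
        model, sol = merge_zone_results(zone_results)
    else:
        model = build_model(demand, capacity, ttm)
        sol = solve(model, gap_abs=gap_abs, time_limit=time_limit)
    summary = summarize(sol, model, labels=labels, partition=region.zones)
    return PipelineResult(
        spec=spec,
        labels=labels,
        ccs_access=access,
        demand=demand,
        capacity=capacity,
        model=model,
        solution=sol,
        summary=summary,
        zone_results=zone_results,
    )


#: parameter name -> how a +/-delta perturbation is applied
SENSITIVITY_PARAMS = (
    "max_walk_min",
    "capacity",
    "ccs_threshold",
    "density_threshold",
    "cluster_pop_threshold",
)


def sensitivity(
    region,
    baseline_scenario,
    params=SENSITIVITY_PARAMS,
    delta: float = 0.10,
    density_threshold: float = 300.0,
    cluster_pop_threshold: float = 2000.0,
    connectivity: int = 8,
    gap_abs: float = 0.0,
    partitioned: bool = False,
    time_limit: float | None = None,
) -> pd.DataFrame:
    """Independent +/-``delta`` perturbations of each threshold parameter.

    Each run perturbs a single parameter (walking-time cutoff, all
    capacity thresholds, CCS proximity threshold, urban density
    threshold, urban cluster population threshold) with everything else
    at baseline, then reruns the full pipeline. Returns a table with the
    baseline row first and percent change in total CHWs per run.
    """
    base_spec = load_scenario(baseline_scenario)

    def run(spec, dens, clus):
        return run_scenario(
            region,
            spec,
            density_threshold=dens,
            cluster_pop_threshold=clus,
            connectivity=connectivity,
            gap_abs=gap_abs,
            partitioned=partitioned,
            time_limit=time_limit,
        )

    rows = []
    base = run(base_spec, density_threshold, cluster_pop_threshold)
    base_total = base.total_chws

    def record(param, direction, result):
        s = result.summary
        rows.append(
            {
                "parameter": param,
                "direction": direction,
                "total_chws": result.total_chws,
                "pct_change": 100.0 * (result.total_chws - base_total) / max(base_total, 1),
                "mean_assigned": None if s is None else s.mean_assigned,
                "share_rural": None if s is None else s.stratum_shares.get("rural", 0.0),
                "share_urban": None if s is None else s.stratum_shares.get("urban", 0.0),
                "share_metropolitan": None if s is None else s.stratum_shares.get("metropolitan", 0.0),
            }
        )

    record("baseline", "0%", base)
    for param in params:
        for sign, tag in ((-delta, f"-{delta:.0%}"), (+delta, f"+{delta:.0%}")):
            factor = 1.0 + sign
            spec, dens, clus = base_spec, density_threshold, cluster_pop_threshold
            if param == "max_walk_min":
                spec = base_spec.with_max_walk(base_spec.max_walk_min * factor)
            elif param == "capacity":
                spec = base_spec.with_scaled_capacities(factor)
            elif param == "ccs_threshold":
                spec = base_spec.with_ccs_threshold(base_spec.ccs_time_threshold_min * factor)
            elif param == "density_threshold":
                dens = density_threshold * factor
            elif param == "cluster_pop_threshold":
                clus = cluster_pop_threshold * factor
            else:
                raise ValueError(f"unknown sensitivity parameter {param!r}")
            record(param, tag, run(spec, dens, clus))
    return pd.DataFrame(rows)
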