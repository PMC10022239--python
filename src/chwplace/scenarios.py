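"""Placement scenarios: walking-time cutoff, per-stratum CHW capacities
and the demand rule.

A scenario fixes the maximum walking time S between a CHW and the
households served, and the capacity k_j (maximum people per CHW) at each
candidate site as a function of the site's stratum (rural / urban /
metropolitan) and its proximity to the nearest community health centre
(CCS). Four built-in scenarios are provided:

* A  — whole territory; capacities 1000 rural / 2500 urban / 4000 metro.
* B  — only cells strictly more than 30 min from a CCS are demand;
       capacities 1000 rural / 2500 urban and metro.
* C  — whole territory; within 60 min of a CCS every stratum gets 4000,
       beyond it 1000 rural / 2500 urban and metro.
* C2 — like C but rural capacity is 1000 at any CCS distance and the
       4000-within-60 rule applies to urban cells only.

Proximity comparisons are strict on the far side ("more than 30/60
minutes"); cells at exactly the threshold count as within.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .grids import Grid, require_aligned
from .urbanization import STRATUM_NAMES, UrbanLabelGrid

__all__ = [
    "CapacityRule",
    "ScenarioSpec",
    "CapacityMap",
    "DemandSet",
    "builtin_scenarios",
    "build_capacity_map",
    "build_demand_set",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
]

STRATA = ("rural", "urban", "metropolitan")
DEFAULT_MAX_WALK_MIN = 60.0


@dataclass(frozen=True)
class CapacityRule:
    """One capacity assignment: stratum x CCS-proximity -> persons/CHW.

    ``stratum`` is one of rural/urban/metropolitan or "any"; ``ccs_side``
    is "within" (access time <= threshold), "beyond" (strictly more) or
    "any". Rules are evaluated in order; the first match wins.
    """

    stratum: str
    ccs_side: str
    capacity: float

    def __post_init__(self):
        if self.stratum not in STRATA + ("any",):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.ccs_side not in ("within", "beyond", "any"):
            raise ValueError(f"unknown ccs_side {self.ccs_side!r}")
        if not self.capacity > 0:
            raise ValueError("capacity must be positive")

    def matches(self, stratum: str, beyond: bool) -> bool:
        if self.stratum not in ("any", stratum):
            return False
        if self.ccs_side == "within":
            return not beyond
        if self.ccs_side == "beyond":
            return beyond
        return True


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario: cutoff S, demand rule and ordered capacity rules."""

    id: str
    max_walk_min: float = DEFAULT_MAX_WALK_MIN
    ccs_time_threshold_min: float = 60.0
    demand: str = "all"  # or "beyond_ccs_threshold"
    capacities: tuple[CapacityRule, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.demand not in ("all", "beyond_ccs_threshold"):
            raise ValueError(f"unknown demand rule {self.demand!r}")
        if not self.max_walk_min > 0:
            raise ValueError("max_walk_min must be positive")

    def capacity_for(self, stratum: str, ccs_minutes: float) -> float:
        """Capacity at a cell of the given stratum and CCS access time."""
        beyond = ccs_minutes > self.ccs_time_threshold_min
        for rule in self.capacities:
            if rule.matches(stratum, beyond):
                return rule.capacity
        raise ValueError(
            f"scenario {self.id!r}: no capacity rule for stratum {stratum!r}, "
            f"{'beyond' if beyond else 'within'} {self.ccs_time_threshold_min} min of a CCS"
        )

    # -- derived scenarios for sensitivity runs ------------------------------
    def with_max_walk(self, minutes: float) -> "ScenarioSpec":
        return replace(self, max_walk_min=minutes)

    def with_ccs_threshold(self, minutes: float) -> "ScenarioSpec":
        return replace(self, ccs_time_threshold_min=minutes)

    def with_scaled_capacities(self, factor: float) -> "ScenarioSpec":
        rules = tuple(replace(r, capacity=r.capacity * factor) for r in self.capacities)
        return replace(self, capacities=rules)


@dataclass
class CapacityMap:
    """Per-site CHW capacity k_j over candidate site cells J (flat ids)."""

    site_index: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.site_index = np.asarray(self.site_index, dtype=int)
        self.k = np.asarray(self.k, dtype=float)
        if np.any(self.k <= 0):
            raise ValueError("all site capacities must be positive")


@dataclass
class DemandSet:
    """Demand cells I (flat ids) and their populations a_i > 0."""

    demand_index: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        self.demand_index = np.asarray(self.demand_index, dtype=int)
        self.a = np.asarray(self.a, dtype=float)
        if np.any(self.a <= 0):
            raise ValueError("demand populations must be strictly positive")

    @property
    def total_population(self) -> float:
        return float(self.a.sum())


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The four built-in scenarios A, B, C and C2 (cutoff S = 60 min)."""
    A = ScenarioSpec(
        id="A",
        max_walk_min=60.0,
        ccs_time_threshold_min=60.0,
        demand="all",
        capacities=(
            CapacityRule("rural", "any", 1000),
            CapacityRule("urban", "any", 2500),
            CapacityRule("metropolitan", "any", 4000),
        ),
    )
    B = ScenarioSpec(
        id="B",
        max_walk_min=60.0,
        ccs_time_threshold_min=30.0,
        demand="beyond_ccs_threshold",
        capacities=(
            CapacityRule("rural", "any", 1000),
            CapacityRule("urban", "any", 2500),
            CapacityRule("metropolitan", "any", 2500),
        ),
    )
    C = ScenarioSpec(
        id="C",
        max_walk_min=60.0,
        ccs_time_threshold_min=60.0,
        demand="all",
        capacities=(
            CapacityRule("any", "within", 4000),
            CapacityRule("rural", "beyond", 1000),
            CapacityRule("urban", "beyond", 2500),
            CapacityRule("metropolitan", "beyond", 2500),
        ),
    )
    C2 = ScenarioSpec(
        id="C2",
        max_walk_min=60.0,
        ccs_time_threshold_min=60.0,
        demand="all",
        capacities=(
            CapacityRule("rural", "any", 1000),
            CapacityRule("urban", "within", 4000),
            CapacityRule("urban", "beyond", 2500),
            CapacityRule("metropolitan", "any", 2500),
        ),
    )
    return {s.id: s for s in (A, B, C, C2)}


def build_demand_set(pop: Grid, ccs_access: Grid, spec: ScenarioSpec) -> DemandSet:
    """Select the demand cells I under the scenario's demand rule.

    All inhabited cells for full-territory scenarios; only inhabited cells
    strictly beyond the CCS time threshold for restricted scenarios. An
    empty demand set is legal (a fully covered zone).
    """
    require_aligned(pop, ccs_access)
    inhabited = (~pop.nodata_mask) & (pop.values > 0)
    if spec.demand == "beyond_ccs_threshold":
        inhabited &= ccs_access.values > spec.ccs_time_threshold_min
    rows, cols = np.nonzero(inhabited)
    flat = rows * pop.shape[1] + cols
    return DemandSet(demand_index=flat, a=pop.values[rows, cols])


def build_capacity_map(
    labels: UrbanLabelGrid,
    ccs_access: Grid,
    pop: Grid,
    spec: ScenarioSpec,
    site_index: np.ndarray | None = None,
) -> CapacityMap:
    """Materialize per-site capacities k_j for candidate sites J.

    By default J is the demand set itself (CHWs live where the people
    they serve live); pass ``site_index`` to use a different candidate
    set, e.g. all inhabited cells.
    """
    require_aligned(pop, ccs_access)
    if labels.shape != pop.shape:
        raise ValueError("label grid misaligned with population grid")
    if site_index is None:
        site_index = build_demand_set(pop, ccs_access, spec).demand_index
    site_index = np.asarray(site_index, dtype=int)
    ncol = pop.shape[1]
    k = np.empty(site_index.size)
    for pos, flat in enumerate(site_index):
        r, c = divmod(int(flat), ncol)
        stratum = STRATUM_NAMES[int(labels.label[r, c])]
        k[pos] = spec.capacity_for(stratum, float(ccs_access.values[r, c]))
    return CapacityMap(site_index=site_index, k=k)


# ---------------------------------------------------------------------------
# config-file round trip

def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "id": spec.id,
        "max_walk_min": spec.max_walk_min,
        "ccs_time_threshold_min": spec.ccs_time_threshold_min,
        "demand": spec.demand,
        "capacities": [
            {"stratum": r.stratum, "ccs_side": r.ccs_side, "capacity": r.capacity}
            for r in spec.capacities
        ],
    }


def scenario_from_dict(d: dict) -> ScenarioSpec:
    rules = tuple(
        CapacityRule(r["stratum"], r.get("ccs_side", "any"), float(r["capacity"]))
        for r in d["capacities"]
    )
    return ScenarioSpec(
        id=str(d["id"]),
        max_walk_min=float(d.get("max_walk_min", DEFAULT_MAX_WALK_MIN)),
        ccs_time_threshold_min=float(d.get("ccs_time_threshold_min", 60.0)),
        demand=d.get("demand", "all"),
        capacities=rules,
    )


def load_scenario(source) -> ScenarioSpec:
    """Load a scenario from a builtin id, a YAML file path, or a dict."""
    if isinstance(source, ScenarioSpec):
        return source
    if isinstance(source, dict):
        return scenario_from_dict(source)
    builtins = builtin_scenarios()
    if source in builtins:
        return builtins[source]
    with open(source) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
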