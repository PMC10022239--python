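"""Workload arithmetic, solution summaries and gap/sensitivity analyses.

Capacity thresholds translate into household-visit frequencies through
simple workload arithmetic: a CHW doing ``households_per_day`` visits over
``working_days_per_year`` days can deliver

    visits/household/year = households_per_day * working_days_per_year
                            / (capacity / household_size)

so a 1000-person capacity corresponds to ~8 visits per household per year,
2500 to ~3 and 4000 to ~2 under the default parameters (8 households/day,
4.3 persons/household, 220 working days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AdminPartition
from .optimizer import CsclModel, Solution
from .urbanization import STRATUM_NAMES, UrbanLabelGrid

__all__ = [
    "WorkloadParams",
    "SolutionSummary",
    "visits_per_year",
    "naive_chw_requirement",
    "chw_table",
    "summarize",
    "compare_to_current",
]

AT_CAPACITY_RELTOL = 1e-6


@dataclass(frozen=True)
class WorkloadParams:
    """Assumptions linking CHW capacity to visit frequency."""

    households_per_day: float = 8.0
    household_size: float = 4.3
    working_days_per_year: float = 220.0

    def __post_init__(self):
        if min(self.households_per_day, self.household_size, self.working_days_per_year) <= 0:
            raise ValueError("workload parameters must be positive")


def visits_per_year(capacity: float, params: WorkloadParams = WorkloadParams()) -> float:
    """Average yearly visits per household a CHW with ``capacity`` can make.

    Strictly decreasing in capacity; round to the nearest integer for the
    conventional "n visits per year" reading.
    """
    if not capacity > 0:
        raise ValueError("capacity must be positive")
    households = capacity / params.household_size
    return params.households_per_day * params.working_days_per_year / households


def naive_chw_requirement(
    pop_by_stratum: dict[str, float], ratio: dict[str, float]
) -> float:
    """CHWs needed if geography were ignored: sum of pop/ratio by stratum.

    This is the back-of-envelope requirement using population-to-CHW
    ratios alone, without travel-time or spatial-distribution constraints.
    """
    total = 0.0
    for stratum, pop in pop_by_stratum.items():
        if stratum not in ratio:
            raise KeyError(f"no CHW ratio supplied for stratum {stratum!r}")
        if ratio[stratum] <= 0:
            raise ValueError("CHW ratios must be positive")
        total += pop / ratio[stratum]
    return total


@dataclass
class SolutionSummary:
    """Descriptive statistics of a placement solution.

    Per-CHW assigned populations treat each of the Y_j CHWs at a site as
    one observation receiving an equal share of the site's inflow.
    """

    total_chws: int
    stratum_counts: dict[str, int]
    stratum_shares: dict[str, float]
    mean_assigned: float
    q5_assigned: float
    q95_assigned: float
    at_capacity_fraction: float
    under_100_fraction: float
    zone_totals: dict[int, int] = field(default_factory=dict)
    total_assigned_persons: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        row = {
            "total_chws": self.total_chws,
            "mean_assigned": self.mean_assigned,
            "q5_assigned": self.q5_assigned,
            "q95_assigned": self.q95_assigned,
            "at_capacity_fraction": self.at_capacity_fraction,
            "under_100_fraction": self.under_100_fraction,
        }
        for s, v in self.stratum_shares.items():
            row[f"share_{s}"] = v
        return pd.DataFrame([row])


def chw_table(
    sol: Solution,
    model: CsclModel,
    labels: UrbanLabelGrid | None = None,
    partition: AdminPartition | None = None,
) -> pd.DataFrame:
    """One row per individual CHW: site cell, assigned persons, stratum, zone.

    The inflow sum_i a_i X_ij at a site with Y_j CHWs is split equally
    among them, the only symmetric choice when several CHWs share a cell.
    """
    inflow = np.zeros(model.n_sites)
    np.add.at(inflow, model.pair_j, model.a[model.pair_i] * sol.X)
    rows = []
    ncol = labels.shape[1] if labels is not None else (
        partition.shape[1] if partition is not None else None
    )
    for pos in np.nonzero(sol.Y > 0)[0]:
        y = int(sol.Y[pos])
        cell = int(model.site_cells[pos])
        share = inflow[pos] / y
        stratum = zone = None
        if ncol is not None:
            r, c = divmod(cell, ncol)
            if labels is not None:
                stratum = STRATUM_NAMES[int(labels.label[r, c])]
            if partition is not None:
                zone = int(partition.zone_id[r, c])
        for _ in range(y):
            rows.append(
                {"cell": cell, "assigned": share, "k": model.k[pos], "stratum": stratum, "zone": zone}
            )
    return pd.DataFrame(rows, columns=["cell", "assigned", "k", "stratum", "zone"])


def summarize(
    sol: Solution,
    model: CsclModel,
    labels: UrbanLabelGrid | None = None,
    partition: AdminPartition | None = None,
) -> SolutionSummary:
    """Summary statistics over individual CHWs.

    Quantiles (5% / 95%) use the empirical distribution with linear
    interpolation, one observation per CHW. "At capacity" means assigned
    >= k_j (within a 1e-6 relative tolerance).
    """
    table = chw_table(sol, model, labels=labels, partition=partition)
    n = len(table)
    if n == 0:
        return SolutionSummary(0, {}, {}, float("nan"), float("nan"), float("nan"), 0.0, 0.0)
    assigned = table["assigned"].to_numpy()
    at_cap = assigned >= table["k"].to_numpy() * (1 - AT_CAPACITY_RELTOL)
    counts: dict[str, int] = {}
    if labels is not None:
        counts = table.groupby("stratum", observed=True).size().to_dict()
    shares = {s: c / n for s, c in counts.items()}
    zone_totals: dict[int, int] = {}
    if partition is not None:
        zone_totals = {int(z): int(c) for z, c in table.groupby("zone").size().items()}
    q5, q95 = np.quantile(assigned, [0.05, 0.95])
    return SolutionSummary(
        total_chws=n,
        stratum_counts={s: int(c) for s, c in counts.items()},
        stratum_shares=shares,
        mean_assigned=float(assigned.mean()),
        q5_assigned=float(q5),
        q95_assigned=float(q95),
        at_capacity_fraction=float(at_cap.mean()),
        under_100_fraction=float((assigned < 100).mean()),
        zone_totals=zone_totals,
        total_assigned_persons=float(assigned.sum()),
    )


def compare_to_current(
    suggested: dict[int, int], current: dict[int, int], zone_names: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-zone difference current - suggested; negative means a deficit.

    Zones missing from the current table count as 0 current CHWs.
    """
    zones = sorted(set(suggested) | set(current))
    rows = []
    for z in zones:
        cur = int(current.get(z, 0))
        sug = int(suggested.get(z, 0))
        rows.append(
            {
                "zone": z,
                "name": (zone_names or {}).get(z, str(z)),
                "current": cur,
                "suggested": sug,
                "difference": cur - sug,
            }
        )
    return pd.DataFrame(rows)
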