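"""Least-cost walking times over a friction surface.

The friction raster gives the minutes needed to cross one km of each cell.
Adjacent cells are joined by edges whose cost is the arithmetic mean of the
two cell frictions times the step length (cell size, times sqrt(2) for
diagonal moves). Travel times are shortest-path distances on this graph:
the time-to-nearest-facility surface is a multi-source sweep, and the
pairwise demand-to-site matrix is truncated at the walking-time cutoff S,
which induces the neighborhood N_i = {j : d_ij <= S} of each demand cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .grids import Grid, GridValidationError

__all__ = [
    "TravelTimeMatrix",
    "build_cost_graph",
    "access_surface",
    "travel_matrix",
    "population_share_beyond",
]

#: slack added to the <= S comparison so exact-boundary times are kept
#: despite float rounding in path sums
CUTOFF_TOL = 1e-9

_STEPS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_STEPS_8 = _STEPS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class TravelTimeMatrix:
    """Sparse walking times d_ij (minutes) truncated at ``cutoff_min``.

    ``entries`` maps (demand flat cell id, site flat cell id) to minutes;
    only pairs with d_ij <= cutoff are stored. ``demand_index`` and
    ``site_index`` list the flat cell ids of I and J.
    """

    cutoff_min: float
    demand_index: np.ndarray
    site_index: np.ndarray
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def neighborhood(self, i: int) -> list[int]:
        """Sites within the cutoff of demand cell ``i`` (flat id)."""
        return [j for (ii, j) in self.entries if ii == i]

    def neighborhoods(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.demand_index}
        for (i, j) in self.entries:
            out[i].append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, t) for (i, j), t in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["demand_cell", "site_cell", "minutes"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_cost_graph(friction: Grid, connectivity: int = 8) -> sp.csr_matrix:
    """Build the weighted adjacency graph of traversable cells.

    Returns an n_cells x n_cells CSR matrix over flattened (row-major)
    cell ids. Nodata cells have no incident edges. Edge cost between
    adjacent cells a, b is mean(friction_a, friction_b) * step_km where
    step_km = cell_size (* sqrt(2) on diagonals).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    traversable = ~friction.nodata_mask
    if not traversable.any():
        raise GridValidationError("friction grid is entirely nodata")
    nrow, ncol = friction.shape
    n = nrow * ncol
    f = friction.values
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    costs: list[np.ndarray] = []
    steps = _STEPS_4 if connectivity == 4 else _STEPS_8
    for dr, dc in steps:
        # each ordered neighbor offset contributes one direction of edges
        r0 = slice(max(0, -dr), min(nrow, nrow - dr))
        c0 = slice(max(0, -dc), min(ncol, ncol - dc))
        r1 = slice(max(0, dr), min(nrow, nrow + dr))
        c1 = slice(max(0, dc), min(ncol, ncol + dc))
        ok = traversable[r0, c0] & traversable[r1, c1]
        rr, cc = np.nonzero(ok)
        src = (rr + r0.start) * ncol + (cc + c0.start)
        dst = (rr + r1.start) * ncol + (cc + c1.start)
        step_km = friction.cell_size_km * (np.sqrt(2.0) if dr and dc else 1.0)
        w = 0.5 * (f[r0, c0][ok] + f[r1, c1][ok]) * step_km
        rows_out.append(src)
        cols_out.append(dst)
        costs.append(w)
    graph = sp.coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n, n),
    )
    return graph.tocsr()


def access_surface(friction: Grid, facility_cells, connectivity: int = 8) -> Grid:
    """Minutes of walking from every cell to its nearest facility.

    ``facility_cells`` is a list of (row, col) cells. Facility cells get
    time 0; unreachable cells get +inf; nodata stays masked. A facility on
    a nodata cell is an error.
    """
    if len(facility_cells) == 0:
        raise GridValidationError("at least one facility cell is required")
    ncol = friction.shape[1]
    flat = []
    for r, c in facility_cells:
        if friction.nodata_mask[r, c]:
            raise GridValidationError(f"facility at nodata cell ({r}, {c})")
        flat.append(r * ncol + c)
    graph = build_cost_graph(friction, connectivity=connectivity)
    dist = dijkstra(graph, directed=False, indices=sorted(set(flat)), min_only=True)
    values = dist.reshape(friction.shape)
    return Grid(
        values=np.where(friction.nodata_mask, 0.0, values),
        cell_size_km=friction.cell_size_km,
        origin=friction.origin,
        nodata_mask=friction.nodata_mask.copy(),
    )


def travel_matrix(
    friction: Grid,
    demand_cells,
    site_cells,
    cutoff_min: float,
    connectivity: int = 8,
) -> TravelTimeMatrix:
    """Pairwise walking times between demand cells and candidate sites.

    Stores exactly the pairs with shortest-path time <= cutoff (within a
    1e-9 boundary tolerance). Computed as one bounded Dijkstra sweep per
    source over the cost graph rather than a dense all-pairs solve.
    """
    if not cutoff_min >= 0:
        raise ValueError("cutoff_min must be nonnegative")
    ncol = friction.shape[1]
    d_flat = np.array([r * ncol + c for r, c in demand_cells], dtype=int)
    s_flat = np.array([r * ncol + c for r, c in site_cells], dtype=int)
    graph = build_cost_graph(friction, connectivity=connectivity)
    limit = cutoff_min * (1 + CUTOFF_TOL) + CUTOFF_TOL
    # sweep from the smaller side; costs are symmetric (walking only)
    if len(s_flat) <= len(d_flat):
        sources, targets, transpose = s_flat, d_flat, True
    else:
        sources, targets, transpose = d_flat, s_flat, False
    uniq_sources, inv = np.unique(sources, return_inverse=True)
    dist = dijkstra(graph, directed=False, indices=uniq_sources, limit=limit)
    sub = dist[inv][:, targets]  # (n_sources, n_targets)
    entries: dict[tuple[int, int], float] = {}
    src_ids = sources
    tgt_ids = targets
    keep = sub <= cutoff_min + CUTOFF_TOL
    for a, b in zip(*np.nonzero(keep)):
        t = float(min(sub[a, b], cutoff_min))
        if transpose:
            entries[(int(tgt_ids[b]), int(src_ids[a]))] = t
        else:
            entries[(int(src_ids[a]), int(tgt_ids[b]))] = t
    return TravelTimeMatrix(
        cutoff_min=float(cutoff_min),
        demand_index=d_flat,
        site_index=s_flat,
        entries=entries,
    )


def population_share_beyond(pop: Grid, access: Grid, threshold_min: float) -> float:
    """Fraction of total population living strictly beyond ``threshold_min``
    walking minutes of the nearest facility."""
    valid = ~pop.nodata_mask
    total = float(pop.values[valid].sum())
    if total == 0:
        return 0.0
    far = valid & (access.values > threshold_min) & ~access.nodata_mask
    return float(pop.values[far].sum()) / total
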