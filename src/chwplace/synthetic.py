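"""Seeded synthetic regions and tiny hand-checkable model instances.

The generator emulates the structural features the placement method
assumes — a handful of dense urban cores over a sparse rural background,
a smoothly varying walking-friction surface with a high-friction ridge
(a mountain-range analogue), a sparse facility network concentrated in
dense cells, and contiguous administrative zones — without attempting
statistical realism of any particular geography. One integer seed governs
all draws; independent sub-streams per layer make layers individually
reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import AdminPartition, FacilityList, Grid, write_grid
from .optimizer import CsclModel
from .travel import TravelTimeMatrix

__all__ = [
    "SyntheticRegion",
    "generate_region",
    "write_region",
    "fixture_instances",
    "FixtureInstance",
    "random_instance",
]


@dataclass
class SyntheticRegion:
    """A bundle of aligned layers plus the parameters that produced it."""

    pop: Grid
    friction: Grid
    facilities: FacilityList
    zones: AdminPartition
    metro_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def _cap_rural_density(values: np.ndarray, cap: float, rounds: int = 50) -> np.ndarray:
    """Cap cell values at ``cap`` and push the excess onto cells below it,
    preserving the total (keeps the rural background under the urban
    density threshold by construction)."""
    v = values.copy()
    for _ in range(rounds):
        over = v > cap
        if not over.any():
            break
        excess = float((v[over] - cap).sum())
        v[over] = cap
        room = (v > 0) & (v < cap)
        if not room.any():
            break
        headroom = cap - v[room]
        add = np.minimum(headroom, excess * headroom / headroom.sum())
        v[room] += add
    return v


def generate_region(
    seed: int,
    shape: tuple[int, int] = (40, 40),
    total_pop: float = 120_000.0,
    n_urban_cores: int = 2,
    urban_share: float = 0.55,
    friction_range: tuple[float, float] = (10.0, 60.0),
    n_ccs: int = 6,
    n_zones: int = 6,
    cell_size_km: float = 1.0,
    core_sigma_km: float = 1.5,
) -> SyntheticRegion:
    """Generate a reproducible synthetic region.

    Population is ``n_urban_cores`` Gaussian-decay clusters (cores dense
    enough to exceed 300 persons/km^2 and 2000 persons per cluster)
    carrying ``urban_share`` of the total, over a sparse rural background
    carrying the rest, rescaled so the grid sums to ``total_pop`` exactly.
    Friction is a smooth random field in ``friction_range`` with a
    high-friction horizontal ridge. CCS facilities are drawn preferring
    high-density cells; zones are contiguous vertical strips; the
    metropolitan mask covers the densest core.
    """
    if not (0 < urban_share < 1):
        raise ValueError("urban_share must lie strictly between 0 and 1")
    if min(total_pop, n_urban_cores, n_ccs, n_zones) <= 0:
        raise ValueError("generator parameters must be positive")
    core_mass = urban_share * total_pop / n_urban_cores
    if core_mass <= 2500:
        raise ValueError(
            "urban cores too small to exceed the 2000-person urban-cluster "
            f"threshold reliably (mass per core {core_mass:.0f})"
        )
    nrow, ncol = shape
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_fric, rng_fac, rng_misc = (np.random.default_rng(s) for s in ss.spawn(4))
    cell_area = cell_size_km**2

    # --- population: rural background -------------------------------------
    inhabited = rng_pop.random((nrow, ncol)) < 0.75
    background = np.where(inhabited, rng_pop.uniform(2.0, 60.0, shape), 0.0)
    background *= (1 - urban_share) * total_pop / background.sum()
    # keep every rural cell strictly below the 300/km^2 urban density cut
    background = _cap_rural_density(background, 290.0 * cell_area)

    # --- population: urban cores ------------------------------------------
    cores = np.zeros(shape)
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    margin = max(3, int(2 * core_sigma_km / cell_size_km))
    centers = []
    for _ in range(n_urban_cores):
        r0 = int(rng_pop.integers(margin, nrow - margin))
        c0 = int(rng_pop.integers(margin, ncol - margin))
        centers.append((r0, c0))
        d2 = ((rr - r0) ** 2 + (cc - c0) ** 2) * cell_size_km**2
        kernel = np.exp(-d2 / (2 * core_sigma_km**2))
        # truncate the far tail so cores stay compact and uninhabited
        # rural cells remain genuinely empty
        kernel[kernel < 1e-3] = 0.0
        cores += kernel / kernel.sum() * core_mass
    pop_values = background + cores
    pop_values *= total_pop / pop_values.sum()
    pop = Grid(values=pop_values, cell_size_km=cell_size_km)

    # --- friction ----------------------------------------------------------
    fmin, fmax = friction_range
    noise = rng_fric.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min() + 1e-12)
    friction_values = fmin + smooth * (fmax - fmin)
    ridge_row = int(rng_fric.integers(nrow // 4, 3 * nrow // 4))
    ridge = np.exp(-((rr - ridge_row) ** 2) / (2 * 2.0**2))
    friction_values = np.clip(friction_values + ridge * 0.8 * (fmax - fmin), fmin, fmax)
    friction = Grid(values=friction_values, cell_size_km=cell_size_km)

    # --- facilities (CCS preferentially in dense cells) --------------------
    weights = (pop_values.ravel() ** 2) + 1e-12
    weights /= weights.sum()
    n_other = max(1, n_ccs // 2)
    chosen = rng_fac.choice(pop.n_cells, size=n_ccs + n_other, replace=False, p=weights)
    points, flags = [], []
    for pos, flat in enumerate(chosen):
        r, c = divmod(int(flat), ncol)
        points.append(pop.cell_center(r, c))
        flags.append(pos < n_ccs)
    facilities = FacilityList(points=points, is_ccs=np.array(flags))

    # --- zones: contiguous vertical strips ---------------------------------
    edges = np.linspace(0, ncol, n_zones + 1).astype(int)
    zone_id = np.zeros(shape, dtype=int)
    names = {}
    for z in range(n_zones):
        zone_id[:, edges[z] : edges[z + 1]] = z + 1
        names[z + 1] = f"Zone {z + 1}"
    zones = AdminPartition(zone_id=zone_id, level="department", zone_names=names)

    # --- metropolitan mask: densest core and its surroundings --------------
    densest = max(centers, key=lambda rc: pop_values[rc])
    metro_mask = ((rr - densest[0]) ** 2 + (cc - densest[1]) ** 2) <= (
        2.0 / cell_size_km
    ) ** 2

    provenance = {
        "seed": int(seed),
        "shape": list(shape),
        "total_pop": float(total_pop),
        "n_urban_cores": int(n_urban_cores),
        "urban_share": float(urban_share),
        "friction_range": list(friction_range),
        "n_ccs": int(n_ccs),
        "n_zones": int(n_zones),
        "cell_size_km": float(cell_size_km),
        "core_centers": [list(c) for c in centers],
    }
    return SyntheticRegion(
        pop=pop,
        friction=friction,
        facilities=facilities,
        zones=zones,
        metro_mask=metro_mask,
        provenance=provenance,
    )


def write_region(region: SyntheticRegion, outdir) -> dict[str, str]:
    """Write a region bundle (ASCII rasters + CSVs) readable by the
    geodata loaders; returns the file paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "population": os.path.join(outdir, "population.asc"),
        "friction": os.path.join(outdir, "friction.asc"),
        "facilities": os.path.join(outdir, "facilities.csv"),
        "zones": os.path.join(outdir, "zones.asc"),
        "zone_names": os.path.join(outdir, "zone_names.csv"),
        "metro_mask": os.path.join(outdir, "metro_mask.asc"),
    }
    write_grid(region.pop, paths["population"])
    write_grid(region.friction, paths["friction"])
    zg = Grid(
        values=region.zones.zone_id.astype(float),
        cell_size_km=region.pop.cell_size_km,
        origin=region.pop.origin,
    )
    write_grid(zg, paths["zones"], fmt="%d")
    mg = Grid(
        values=region.metro_mask.astype(float),
        cell_size_km=region.pop.cell_size_km,
        origin=region.pop.origin,
    )
    write_grid(mg, paths["metro_mask"], fmt="%d")
    pd.DataFrame(
        {
            "x": [p[0] for p in region.facilities.points],
            "y": [p[1] for p in region.facilities.points],
            "is_ccs": region.facilities.is_ccs.astype(int),
        }
    ).to_csv(paths["facilities"], index=False)
    pd.DataFrame(
        {"id": list(region.zones.zone_names), "name": list(region.zones.zone_names.values())}
    ).to_csv(paths["zone_names"], index=False)
    return paths


# ---------------------------------------------------------------------------
# tiny named instances with certified optima


@dataclass
class FixtureInstance:
    """A hand-built model instance with its certified outcome."""

    name: str
    model: CsclModel | None
    expected_objective: int | None  # None = infeasible
    note: str = ""
    # kept for instances whose construction must fail (empty neighborhood)
    raw: dict = field(default_factory=dict)


def _make_model(a, k, pairs, cutoff=60.0) -> CsclModel:
    a = np.asarray(a, dtype=float)
    k = np.asarray(k, dtype=float)
    pair_i = np.array([p[0] for p in pairs], dtype=int)
    pair_j = np.array([p[1] for p in pairs], dtype=int)
    pair_t = np.array([p[2] if len(p) > 2 else 0.0 for p in pairs], dtype=float)
    return CsclModel(
        demand_cells=np.arange(len(a)),
        a=a,
        site_cells=100 + np.arange(len(k)),
        k=k,
        pair_i=pair_i,
        pair_j=pair_j,
        pair_time=pair_t,
        cutoff_min=cutoff,
    )


def fixture_instances() -> dict[str, FixtureInstance]:
    """Named tiny instances with brute-force-certified optima.

    * multiplicity — one cell, a=2500, k=1000: needs Y=3 at a single
      site, impossible under a binary-site formulation.
    * split — two cells of 1200 sharing a central site, k=1000
      everywhere: Z*=3, and the balanced Y=(1,1,1) placement is feasible
      only with fractional allocations since each cell's population
      exceeds any single site's capacity.
    * isolated — a demand cell with an empty neighborhood (infeasible).
    * chain — four cells in a line with only adjacent pairs stored, for
      partitioned-solve tests.
    """
    out: dict[str, FixtureInstance] = {}
    out["multiplicity"] = FixtureInstance(
        name="multiplicity",
        model=_make_model([2500], [1000], [(0, 0, 0.0)]),
        expected_objective=3,
        note="ceil(2500/1000) CHWs stacked on one site",
    )
    # sites: 0=peripheral near cell 0, 1=central (reaches both), 2=peripheral near cell 1
    out["split"] = FixtureInstance(
        name="split",
        model=_make_model(
            [1200, 1200],
            [1000, 1000, 1000],
            [(0, 0, 10.0), (0, 1, 40.0), (1, 1, 40.0), (1, 2, 10.0)],
        ),
        expected_objective=3,
        note="every cell exceeds any single site capacity; X must split",
    )
    out["isolated"] = FixtureInstance(
        name="isolated",
        model=None,
        expected_objective=None,
        note="demand cell 1 has no site within the cutoff",
        raw={
            "a": [500.0, 300.0],
            "k": [1000.0],
            "pairs": [(0, 0, 5.0)],  # cell 1 unreachable
            "n_demand": 2,
        },
    )
    out["chain"] = FixtureInstance(
        name="chain",
        model=_make_model(
            [500, 500, 500, 500],
            [1000, 1000, 1000, 1000],
            [
                (0, 0, 0.0), (0, 1, 30.0),
                (1, 0, 30.0), (1, 1, 0.0), (1, 2, 30.0),
                (2, 1, 30.0), (2, 2, 0.0), (2, 3, 30.0),
                (3, 2, 30.0), (3, 3, 0.0),
            ],
        ),
        expected_objective=2,
        note="sites 1 and 2 cover everyone; zone split at the middle forces 2 as well",
    )
    return out


def random_instance(
    rng: np.random.Generator,
    max_demand: int = 6,
    max_sites: int = 6,
) -> CsclModel:
    """A random small CSCLP instance for solver-vs-oracle comparisons.

    Populations 100-3000, capacities from {500, 1000, 2500, 4000}, random
    bipartite reachability with every demand cell reaching at least one
    site. Instances are always feasible in the multiplicity formulation
    (every N_i contains a site that can host any number of CHWs).
    """
    nI = int(rng.integers(1, max_demand + 1))
    nJ = int(rng.integers(1, max_sites + 1))
    a = rng.integers(100, 3001, size=nI).astype(float)
    k = rng.choice([500.0, 1000.0, 2500.0, 4000.0], size=nJ)
    pairs = []
    for i in range(nI):
        reachable = np.nonzero(rng.random(nJ) < 0.5)[0]
        if reachable.size == 0:
            reachable = np.array([int(rng.integers(0, nJ))])
        for j in reachable:
            pairs.append((i, int(j), float(rng.uniform(0, 60))))
    return _make_model(a, k, pairs)


def fixture_ttm(fix: FixtureInstance) -> TravelTimeMatrix:
    """TravelTimeMatrix view of a fixture, for build_model round trips."""
    m = fix.model
    entries = {
        (int(m.demand_cells[ii]), int(m.site_cells[jj])): float(t)
        for ii, jj, t in zip(m.pair_i, m.pair_j, m.pair_time)
    }
    return TravelTimeMatrix(
        cutoff_min=m.cutoff_min,
        demand_index=m.demand_cells,
        site_index=m.site_cells,
        entries=entries,
    )
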