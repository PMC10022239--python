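"""Gridded geodata: rasters, administrative zones and facility points.

All layers live on one harmonized rectangular grid. Cell indices are
(row, col), 0-based, with row 0 the northernmost row (raster convention).
Point-to-cell mapping uses half-open cell intervals ``[x, x + size)``.
Rasters are read and written as single-band ESRI ASCII grids, a plain-text
format with a 6-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows from north to south.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "AdminPartition",
    "FacilityList",
    "GridAlignmentError",
    "GridValidationError",
    "read_grid",
    "write_grid",
    "aggregate",
    "rake_to_targets",
    "facilities_to_cells",
    "read_facilities",
    "read_partition",
    "require_aligned",
]

DEFAULT_NODATA = -9999.0


class GridValidationError(ValueError):
    """Raised when grid contents violate a role-specific invariant."""


class GridAlignmentError(ValueError):
    """Raised when two layers do not share shape, origin and cell size."""


@dataclass
class Grid:
    """A single-band raster: values, cell size in km, origin, nodata mask.

    ``origin`` is the (x, y) coordinate of the lower-left corner of the
    lower-left cell, matching the ESRI ASCII convention. ``values`` may
    carry persons per cell (population role) or minutes per km (friction
    role); ``nodata_mask`` is True where the cell holds no data.
    """

    values: np.ndarray
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridValidationError("grid values must be a 2-D array")
        if not self.cell_size_km > 0:
            raise GridValidationError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GridValidationError("nodata mask shape mismatch")
        # +inf is legal (unreachable cells in access surfaces); NaN is not
        if np.any(np.isnan(self.values[~self.nodata_mask])):
            raise GridValidationError("NaN values outside nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.size

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy())

    def flat_values(self) -> np.ndarray:
        return self.values.ravel()

    def cell_to_flat(self, row: int, col: int) -> int:
        return int(row) * self.shape[1] + int(col)

    def flat_to_cell(self, idx: int) -> tuple[int, int]:
        ncol = self.shape[1]
        return divmod(int(idx), ncol)

    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its containing cell; raises if outside the extent."""
        x0, y0 = self.origin
        nrow, ncol = self.shape
        s = self.cell_size_km
        col = math.floor((x - x0) / s)
        row_from_bottom = math.floor((y - y0) / s)
        row = nrow - 1 - row_from_bottom
        if not (0 <= col < ncol and 0 <= row < nrow):
            raise GridValidationError(
                f"point ({x}, {y}) falls outside the grid extent "
                f"[{x0}, {x0 + ncol * s}) x [{y0}, {y0 + nrow * s})"
            )
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        nrow = self.shape[0]
        s = self.cell_size_km
        return (x0 + (col + 0.5) * s, y0 + (nrow - 1 - row + 0.5) * s)


@dataclass
class AdminPartition:
    """Zone membership per cell: every non-nodata cell has exactly one zone."""

    zone_id: np.ndarray
    level: str = "zone"
    zone_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zone_id = np.asarray(self.zone_id, dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.zone_id.shape

    def zones(self) -> np.ndarray:
        return np.unique(self.zone_id[self.zone_id >= 0])

    def name(self, zid: int) -> str:
        return self.zone_names.get(int(zid), str(zid))


@dataclass
class FacilityList:
    """Point facilities; ``is_ccs`` flags community health centres (set L)."""

    points: list[tuple[float, float]]
    is_ccs: np.ndarray

    def __post_init__(self) -> None:
        self.is_ccs = np.asarray(self.is_ccs, dtype=bool)
        if len(self.points) != self.is_ccs.size:
            raise GridValidationError("points / is_ccs length mismatch")

    def ccs_points(self) -> list[tuple[float, float]]:
        return [p for p, c in zip(self.points, self.is_ccs) if c]


def require_aligned(*grids) -> None:
    """Strict alignment check: identical shape, origin and cell size.

    No silent resampling is performed; misaligned layers are an error.
    """
    ref = grids[0]
    ref_shape = ref.shape
    ref_origin = getattr(ref, "origin", None)
    ref_size = getattr(ref, "cell_size_km", None)
    for g in grids[1:]:
        if g.shape != ref_shape:
            raise GridAlignmentError(f"shape mismatch: {g.shape} vs {ref_shape}")
        size = getattr(g, "cell_size_km", None)
        origin = getattr(g, "origin", None)
        if size is not None and ref_size is not None and not math.isclose(size, ref_size):
            raise GridAlignmentError(f"cell size mismatch: {size} vs {ref_size}")
        if origin is not None and ref_origin is not None:
            if not (
                math.isclose(origin[0], ref_origin[0], abs_tol=1e-9)
                and math.isclose(origin[1], ref_origin[1], abs_tol=1e-9)
            ):
                raise GridAlignmentError(f"origin mismatch: {origin} vs {ref_origin}")


def _validate_role(grid: Grid, role: str) -> Grid:
    valid = ~grid.nodata_mask
    if role == "population":
        bad = int(np.sum(grid.values[valid] < 0))
        if bad:
            raise GridValidationError(f"population grid has {bad} negative cell(s)")
    elif role == "friction":
        bad = int(np.sum(grid.values[valid] <= 0))
        if bad:
            raise GridValidationError(f"friction grid has {bad} nonpositive cell(s)")
    elif role != "generic":
        raise ValueError(f"unknown grid role {role!r}")
    return grid


def read_grid(path, role: str = "generic") -> Grid:
    """Read a single-band ESRI ASCII grid and validate it for its role.

    ``role`` is "population" (values must be >= 0), "friction" (values must
    be > 0 outside nodata) or "generic" (no constraint).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridValidationError(f"missing header field {key!r} in {path}")
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "".join(lines[n_header:])
    values = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    if values.size != nrow * ncol:
        raise GridValidationError(
            f"expected {nrow * ncol} values in {path}, found {values.size}"
        )
    values = values.reshape(nrow, ncol)
    mask = np.isclose(values, nodata)
    values = np.where(mask, 0.0, values)
    grid = Grid(
        values=values,
        cell_size_km=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata_mask=mask,
    )
    return _validate_role(grid, role)


def write_grid(grid: Grid, path, nodata: float = DEFAULT_NODATA, fmt: str = "%.10g") -> None:
    """Write a Grid as an ESRI ASCII raster (north row first)."""
    nrow, ncol = grid.shape
    out = np.where(grid.nodata_mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size_km:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


def aggregate(grid: Grid, factor: int) -> Grid:
    """Block-sum a population grid by an integer factor.

    Nodata cells contribute 0 to their block unless the whole block is
    nodata, in which case the output cell is nodata. Trailing partial
    blocks (shape not divisible by ``factor``) are summed as-is, so the
    grand total is always conserved. Cell size is multiplied by the factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return grid.copy()
    nrow, ncol = grid.shape
    out_r = math.ceil(nrow / factor)
    out_c = math.ceil(ncol / factor)
    vals = np.where(grid.nodata_mask, 0.0, grid.values)
    out = np.zeros((out_r, out_c))
    all_nodata = np.zeros((out_r, out_c), dtype=bool)
    for br in range(out_r):
        for bc in range(out_c):
            sl = np.s_[br * factor : (br + 1) * factor, bc * factor : (bc + 1) * factor]
            out[br, bc] = vals[sl].sum()
            all_nodata[br, bc] = bool(grid.nodata_mask[sl].all())
    return Grid(
        values=out,
        cell_size_km=grid.cell_size_km * factor,
        origin=grid.origin,
        nodata_mask=all_nodata,
    )


def rake_to_targets(pop: Grid, zones: AdminPartition, targets: dict[int, float]) -> Grid:
    """Proportionally rescale population within each zone to match targets.

    Within zone z every cell is multiplied by ``target_z / current_sum_z``,
    so zone sums equal the targets exactly (up to float rounding). A zone
    with zero current population but a positive target is an error: there
    is no support to distribute people onto.
    """
    if pop.shape != zones.shape:
        raise GridAlignmentError("population grid and zone partition are misaligned")
    out = pop.copy()
    valid = ~pop.nodata_mask
    for zid, target in targets.items():
        if target < 0:
            raise GridValidationError(f"negative raking target for zone {zid}")
        sel = (zones.zone_id == zid) & valid
        current = float(pop.values[sel].sum())
        if current == 0.0:
            if target > 0:
                raise GridValidationError(
                    f"zone {zid} has zero population but positive target {target}"
                )
            continue
        out.values[sel] *= target / current
    return out


def facilities_to_cells(fac: FacilityList, grid: Grid) -> list[tuple[int, int]]:
    """Map facility points to containing cells; duplicates are allowed.

    All offending out-of-extent points are collected and reported together.
    """
    cells: list[tuple[int, int]] = []
    outside: list[tuple[float, float]] = []
    for x, y in fac.points:
        try:
            cells.append(grid.point_to_cell(x, y))
        except GridValidationError:
            outside.append((x, y))
    if outside:
        raise GridValidationError(f"{len(outside)} facility point(s) outside extent: {outside}")
    return cells


def read_facilities(path) -> FacilityList:
    """Read facilities from CSV (columns x, y, is_ccs) or GeoJSON points."""
    path = str(path)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            gj = json.load(fh)
        points, flags = [], []
        for feat in gj["features"]:
            lon, lat = feat["geometry"]["coordinates"][:2]
            points.append((float(lon), float(lat)))
            flags.append(bool(feat.get("properties", {}).get("is_ccs", False)))
        return FacilityList(points=points, is_ccs=np.array(flags))
    df = pd.read_csv(path)
    pts = list(zip(df["x"].astype(float), df["y"].astype(float)))
    return FacilityList(points=pts, is_ccs=df["is_ccs"].astype(int).to_numpy().astype(bool))


def read_partition(raster_path, names_path=None, level: str = "zone") -> AdminPartition:
    """Read a zone-id raster (.asc) plus optional CSV id→name lookup."""
    grid = read_grid(raster_path, role="generic")
    zone_id = np.where(grid.nodata_mask, -1, np.rint(grid.values).astype(int))
    names: dict[int, str] = {}
    if names_path is not None:
        df = pd.read_csv(names_path)
        names = {int(r["id"]): str(r["name"]) for _, r in df.iterrows()}
    return AdminPartition(zone_id=zone_id, level=level, zone_names=names)
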