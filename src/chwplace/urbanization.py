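"""Rural/urban/metropolitan classification of grid cells.

Follows the degree-of-urbanization rule: cells whose population density
strictly exceeds a threshold (default 300 persons/km^2) are grouped into
contiguous clusters, and clusters whose total population strictly exceeds
a size threshold (default 2000 persons) are labelled urban; every other
cell is rural. A metropolitan area is overlaid afterwards from an explicit
commune mask, which takes precedence over the density-based label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid, GridAlignmentError

__all__ = ["RURAL", "URBAN", "METROPOLITAN", "UrbanLabelGrid", "classify_urban", "apply_metropolitan"]

RURAL, URBAN, METROPOLITAN = 0, 1, 2
STRATUM_NAMES = {RURAL: "rural", URBAN: "urban", METROPOLITAN: "metropolitan"}

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class UrbanLabelGrid:
    """Integer stratum codes per cell: 0 rural, 1 urban, 2 metropolitan."""

    label: np.ndarray
    density_threshold: float
    cluster_pop_threshold: float
    connectivity: int = 8
    codebook: dict[int, str] = field(default_factory=lambda: dict(STRATUM_NAMES))

    @property
    def shape(self):
        return self.label.shape

    def stratum_name(self, row: int, col: int) -> str:
        return self.codebook[int(self.label[row, col])]

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.label == code)) for code, name in self.codebook.items()}


def classify_urban(
    pop: Grid,
    density_threshold: float = 300.0,
    cluster_pop_threshold: float = 2000.0,
    connectivity: int = 8,
) -> UrbanLabelGrid:
    """Label cells urban/rural by the contiguous-cluster density rule.

    Both thresholds are strict inequalities: density must exceed
    ``density_threshold`` and a cluster's summed population must exceed
    ``cluster_pop_threshold`` for its cells to be urban.
    """
    if density_threshold <= 0 or cluster_pop_threshold <= 0:
        raise ValueError("urbanization thresholds must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    density = np.where(pop.nodata_mask, 0.0, pop.values) / pop.cell_area_km2()
    dense = density > density_threshold
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    clusters, n_clusters = ndimage.label(dense, structure=structure)
    label = np.full(pop.shape, RURAL, dtype=np.int8)
    if n_clusters:
        sums = ndimage.sum_labels(
            np.where(pop.nodata_mask, 0.0, pop.values), clusters, index=np.arange(1, n_clusters + 1)
        )
        urban_ids = np.nonzero(sums > cluster_pop_threshold)[0] + 1
        label[np.isin(clusters, urban_ids)] = URBAN
    return UrbanLabelGrid(
        label=label,
        density_threshold=float(density_threshold),
        cluster_pop_threshold=float(cluster_pop_threshold),
        connectivity=connectivity,
    )


def apply_metropolitan(labels: UrbanLabelGrid, metro_mask: np.ndarray) -> UrbanLabelGrid:
    """Relabel masked cells metropolitan; the mask wins over rural/urban."""
    metro_mask = np.asarray(metro_mask, dtype=bool)
    if metro_mask.shape != labels.shape:
        raise GridAlignmentError("metropolitan mask misaligned with label grid")
    out = labels.label.copy()
    out[metro_mask] = METROPOLITAN
    return UrbanLabelGrid(
        label=out,
        density_threshold=labels.density_threshold,
        cluster_pop_threshold=labels.cluster_pop_threshold,
        connectivity=labels.connectivity,
    )
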