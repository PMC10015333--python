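"""Square analysis grid over the focal region and the cells x taxa
presence matrix.

The grid is anchored at the minimum corner of the region's bounding box and
cells wholly outside the region are discarded, so every retained cell has
positive land area and cell denominators are land areas, not full squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import STRtree, box, unary_union
from shapely.geometry.base import BaseGeometry

from .geoio import Taxon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridConfig:
    """Grid geometry and hotspot-cap parameters.

    cell_size: cell edge length in metres (default 100 km).
    cap_fraction: maximum fraction of cells a hotspot set may contain.
    presence_epsilon: minimum range-cell land overlap (m^2) that counts as
        presence; guards against sliver artifacts from digitized borders.
    """

    cell_size: float = 100_000.0
    cap_fraction: float = 0.05
    presence_epsilon: float = 1.0
    origin_rule: str = "bbox_min_corner"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0 < self.cap_fraction < 1:
            raise ValueError("cap_fraction must be in (0, 1)")
        if self.presence_epsilon < 0:
            raise ValueError("presence_epsilon must be >= 0")
        if self.origin_rule != "bbox_min_corner":
            raise ValueError("only origin_rule='bbox_min_corner' is supported")


@dataclass
class Cell:
    cell_id: int
    row: int
    col: int
    polygon: BaseGeometry
    land_area: float
    protected_area: float


@dataclass
class RegionGrid:
    """Tiling of the focal region into square cells with per-cell land and
    protected areas. Cell ids are row-major (row 0 at the southern edge)."""

    cells: list[Cell]
    config: GridConfig

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells]

    def land_areas(self) -> np.ndarray:
        return np.array([c.land_area for c in self.cells])

    def protected_areas(self) -> np.ndarray:
        return np.array([c.protected_area for c in self.cells])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "row": [c.row for c in self.cells],
                "col": [c.col for c in self.cells],
                "land_area": [c.land_area for c in self.cells],
                "protected_area": [c.protected_area for c in self.cells],
            }
        )


def build_grid(
    region: BaseGeometry,
    protected: Sequence[BaseGeometry] | BaseGeometry | None,
    config: GridConfig | None = None,
) -> RegionGrid:
    """Superimpose a square grid on the focal region.

    Each retained cell records land_area = area(cell ∩ region) > 0 and
    protected_area = area(cell ∩ region ∩ protected). Cell squares are
    half-open; shared edges are measure-zero and never affect areas.
    """
    config = config or GridConfig()
    if region.is_empty or region.area <= 0:
        raise ValueError("region must have positive area")
    if protected is None:
        prot_union: BaseGeometry | None = None
    elif isinstance(protected, BaseGeometry):
        prot_union = protected if not protected.is_empty else None
    else:
        prot_union = unary_union(list(protected)) if len(protected) else None

    s = config.cell_size
    minx, miny, maxx, maxy = region.bounds
    ncols = max(1, math.ceil((maxx - minx) / s - 1e-9))
    nrows = max(1, math.ceil((maxy - miny) / s - 1e-9))

    cells: list[Cell] = []
    cell_id = 0
    for r in range(nrows):
        y0 = miny + r * s
        for c in range(ncols):
            x0 = minx + c * s
            square = box(x0, y0, x0 + s, y0 + s)
            land = square.intersection(region)
            if land.area <= 0:
                continue
            pa = 0.0
            if prot_union is not None:
                pa = land.intersection(prot_union).area
            cells.append(
                Cell(
                    cell_id=cell_id,
                    row=r,
                    col=c,
                    polygon=square,
                    land_area=land.area,
                    protected_area=pa,
                )
            )
            cell_id += 1
    return RegionGrid(cells=cells, config=config)


@dataclass
class PresenceMatrix:
    """Boolean cells x taxa incidence with per-cell richness over any
    taxon subset."""

    cell_ids: list[int]
    taxon_ids: list[str]
    incidence: np.ndarray  # bool, shape (n_cells, n_taxa)
    _col: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.cell_ids), len(self.taxon_ids)):
            raise ValueError("incidence shape does not match cell/taxon ids")
        self._col = {t: j for j, t in enumerate(self.taxon_ids)}

    def richness(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Per-cell count of present taxa, optionally restricted to a subset."""
        if subset is None:
            return self.incidence.sum(axis=1)
        cols = [self._col[t] for t in subset]
        return self.incidence[:, cols].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.incidence.astype(int), columns=self.taxon_ids, copy=True
        )
        df.insert(0, "cell_id", self.cell_ids)
        return df


def presence_matrix(
    grid: RegionGrid,
    taxa: Sequence[Taxon],
    region: BaseGeometry,
) -> PresenceMatrix:
    """Overlay taxon ranges on the grid: a taxon is present in a cell when
    its range overlaps the cell's land portion by more than presence_epsilon."""
    eps = grid.config.presence_epsilon
    polys = [c.polygon for c in grid.cells]
    tree = STRtree(polys)
    inc = np.zeros((grid.n_cells, len(taxa)), dtype=bool)
    empty_taxa = []
    for j, t in enumerate(taxa):
        rng = t.focal_range.intersection(region)
        if rng.is_empty:
            empty_taxa.append(t.taxon_id)
            continue
        hit_any = False
        for i in tree.query(rng):
            if rng.intersection(polys[i]).area > eps:
                inc[i, j] = True
                hit_any = True
        if not hit_any:
            empty_taxa.append(t.taxon_id)
    if empty_taxa:
        logger.info("%d taxa with zero presences: %s", len(empty_taxa), empty_taxa)
    return PresenceMatrix(
        cell_ids=grid.cell_ids,
        taxon_ids=[t.taxon_id for t in taxa],
        incidence=inc,
    )
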