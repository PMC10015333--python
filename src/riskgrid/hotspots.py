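"""Capped top-richness hotspot selection and hotspot overlap statistics.

Hotspots are the cells with the highest richness, up to a cap of a fixed
fraction (default 5%) of all grid cells. A richness class (all cells tied at
one richness value) is included only if the whole class fits under the cap:
the selection threshold R is the smallest richness at which the number of
cells with richness >= R does not exceed the cap. There is no random
tie-breaking within a class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gridding import PresenceMatrix, RegionGrid


@dataclass
class HotspotSet:
    """Cells selected as hotspots for one taxon subset.

    ``threshold`` is None for an empty set (no cell holds any taxon).
    """

    label: str
    threshold: int | None
    cell_ids: frozenset[int]
    cap: int

    def __post_init__(self) -> None:
        self.cell_ids = frozenset(self.cell_ids)
        if len(self.cell_ids) > self.cap:
            raise ValueError("hotspot set exceeds its cap")


def hotspot_cap(n_cells: int, cap_fraction: float) -> int:
    """Maximum number of hotspot cells: floor(cap_fraction * n_cells)."""
    return math.floor(cap_fraction * n_cells)


def select_hotspots(
    richness: Sequence[int] | np.ndarray,
    cap_fraction: float = 0.05,
    cell_ids: Sequence[int] | None = None,
    label: str = "",
) -> HotspotSet:
    """Select the capped top-richness cells.

    R = min { r >= 1 : #{cells with richness >= r} <= floor(cap_fraction * n) };
    the set is every cell with richness >= R. When no cell has richness >= 1
    the set is empty with threshold None. Note the full-tie rule can yield an
    empty set even with positive richness, when the top class itself exceeds
    the cap.
    """
    richness = np.asarray(richness)
    n = richness.size
    if n == 0:
        raise ValueError("richness vector is empty")
    if not 0 < cap_fraction < 1:
        raise ValueError("cap_fraction must be in (0, 1)")
    if cell_ids is None:
        cell_ids = list(range(n))
    elif len(cell_ids) != n:
        raise ValueError("cell_ids length does not match richness")
    cap = hotspot_cap(n, cap_fraction)

    if richness.max() < 1:
        return HotspotSet(label=label, threshold=None, cell_ids=frozenset(), cap=cap)

    # counts of cells with richness >= r are non-increasing in r: walk down
    # from the top until the tail fits under the cap
    rmax = int(richness.max())
    threshold = rmax + 1
    for r in range(rmax, 0, -1):
        if int((richness >= r).sum()) <= cap:
            threshold = r
        else:
            break
    members = frozenset(
        cid for cid, rv in zip(cell_ids, richness) if rv >= threshold
    )
    return HotspotSet(label=label, threshold=threshold, cell_ids=members, cap=cap)


def overlap_percent(a: HotspotSet, b: HotspotSet) -> float:
    """Mean reciprocal shared-cell percentage of two hotspot sets.

    100 * (|a∩b|/|a| + |a∩b|/|b|) / 2. Averaging the two directions removes
    the asymmetry introduced by sets of different sizes. Empty sets give 0
    with a warning (undefined denominator).
    """
    if len(a.cell_ids) == 0 or len(b.cell_ids) == 0:
        warnings.warn(
            f"overlap between {a.label!r} and {b.label!r} undefined "
            "(empty hotspot set); returning 0",
            stacklevel=2,
        )
        return 0.0
    shared = len(a.cell_ids & b.cell_ids)
    return 100.0 * (shared / len(a.cell_ids) + shared / len(b.cell_ids)) / 2.0


def display_percent(value: float) -> int:
    """Integer display rounding (half to even); full precision stays in CSVs."""
    return int(round(value))


@dataclass
class OverlapMatrix:
    labels: list[str]
    percent: np.ndarray  # square, symmetric, diagonal 100 for non-empty sets

    @property
    def mean_offdiagonal(self) -> float:
        p = np.asarray(self.percent)
        n = p.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(p[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.labels, columns=self.labels)


def overlap_matrix(sets: Sequence[HotspotSet]) -> OverlapMatrix:
    """All pairwise mean reciprocal overlaps; diagonal is 100 for non-empty
    sets and 0 (flagged) for empty ones."""
    if len(sets) < 2:
        raise ValueError("need at least two hotspot sets")
    n = len(sets)
    pct = np.zeros((n, n))
    for i in range(n):
        pct[i, i] = 100.0 if len(sets[i].cell_ids) else 0.0
        for j in range(i + 1, n):
            pct[i, j] = pct[j, i] = overlap_percent(sets[i], sets[j])
    return OverlapMatrix(labels=[s.label for s in sets], percent=pct)


@dataclass
class CoverageResult:
    """Fraction of a taxon subset reached by a hotspot set, its per-group
    breakdown, and the land fraction the hotspot cells occupy."""

    proportion: float
    per_group: pd.DataFrame  # columns: group, n, n_covered, proportion
    land_fraction: float


def hotspot_coverage(
    h: HotspotSet,
    pm: PresenceMatrix,
    subset: Sequence[str],
    grid: RegionGrid,
    groups: dict[str, str] | None = None,
) -> CoverageResult:
    """Fraction of ``subset`` taxa with at least one presence inside the
    hotspot cells, with per-group breakdown and hotspot land fraction."""
    subset = list(subset)
    if not subset:
        raise ValueError("taxon subset is empty")
    in_h = np.array([cid in h.cell_ids for cid in pm.cell_ids])
    col = {t: j for j, t in enumerate(pm.taxon_ids)}
    covered = {
        t: bool(pm.incidence[in_h, col[t]].any()) if in_h.any() else False
        for t in subset
    }
    prop = sum(covered.values()) / len(subset)

    rows = []
    if groups:
        by_group: dict[str, list[str]] = {}
        for t in subset:
            by_group.setdefault(groups.get(t, "unknown"), []).append(t)
        for g in sorted(by_group):
            ts = by_group[g]
            ncov = sum(covered[t] for t in ts)
            rows.append(
                {"group": g, "n": len(ts), "n_covered": ncov, "proportion": ncov / len(ts)}
            )
    per_group = pd.DataFrame(rows, columns=["group", "n", "n_covered", "proportion"])

    land = grid.land_areas()
    total = land.sum()
    hot_land = land[in_h].sum() if in_h.any() else 0.0
    return CoverageResult(
        proportion=prop,
        per_group=per_group,
        land_fraction=float(hot_land / total) if total > 0 else 0.0,
    )
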