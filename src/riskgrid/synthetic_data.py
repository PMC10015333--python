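"""Synthetic study-system generator with known ground truth.

Emulates the structure of a national at-risk-species analysis without any
real data: a rectangular "world" (the hemisphere analogue) whose northern
band is the focal jurisdiction; taxa whose ranges straddle the focal
region's southern border so that a target Beta-distributed fraction of each
range falls inside (right-skewed: most taxa are range-edge peripherals);
east-west clustering of ranges toward a designated longitude band (creating
a richness hotspot); a fraction of taxa listed by both the national and the
global body; and sparse, patchy protected areas placed to a target coverage,
optionally biased away from (or toward) the richness cluster.

The generator is a pure function of (scenario, seed): identical inputs give
byte-identical layers. Randomness is split into fixed substreams (taxa vs
protection), so adding taxa does not perturb protected-area placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from shapely import box, unary_union
from shapely.geometry import Polygon

from .geoio import GLOBAL_STATUSES, GROUPS, NATIONAL_STATUSES, StudyLayers, Taxon

# substream labels: child seeds are derived as (seed, label)
_STREAM_TAXA = 1
_STREAM_PROTECTION = 2

DEFAULT_GROUP_COUNTS: dict[str, int] = {
    # proportions loosely follow a national at-risk registry: plants dominate,
    # mosses/lichens are small groups
    "birds": 18,
    "mammals": 12,
    "reptiles": 10,
    "amphibians": 8,
    "arthropods": 20,
    "molluscs": 10,
    "vascular_plants": 55,
    "mosses": 7,
    "lichens": 8,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Generating conditions for one synthetic study system.

    Defaults are anchored to the emulated system: ~12.5% of focal land
    protected, ~9% of taxa listed by both bodies, and a right-skewed
    Beta(0.35, 1.6) target for the fraction of each range inside the focal
    region (most taxa peripheral, a small endemic tail).
    """

    seed: int = 0
    world_extent: tuple[float, float] = (4_000_000.0, 3_000_000.0)  # metres
    border_y: float = 1_800_000.0  # focal region = y >= border_y
    group_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    n_global_only: int = 10
    peripherality_beta: tuple[float, float] = (0.35, 1.6)
    southern_clustering: float = 3.0
    cluster_center_frac: float = 0.3  # of world width
    cluster_sd_frac: float = 0.08
    dual_listing_fraction: float = 0.09
    protected_coverage: float = 0.125
    protection_bias: float = 0.0
    pa_size_lognormal: tuple[float, float] = (np.log(1.5e9), 0.8)  # m^2
    range_area_lognormal: tuple[float, float] = (np.log(4e11), 0.9)  # m^2
    assessment_window: tuple[int, int] = (1980, 2020)
    placement_tol: float = 0.01
    coverage_tol: float = 0.005
    ragged_border: bool = False

    def world_polygon(self) -> Polygon:
        w, h = self.world_extent
        return box(0.0, 0.0, w, h)

    def focal_polygon(self) -> Polygon:
        w, h = self.world_extent
        if not self.ragged_border:
            return box(0.0, self.border_y, w, h)
        # ragged southern border: deterministic sawtooth to stress slivers
        n_teeth = 16
        amp = 40_000.0
        xs = np.linspace(0.0, w, n_teeth * 2 + 1)
        ys = self.border_y + amp * np.where(np.arange(xs.size) % 2 == 0, -1.0, 1.0)
        ring = [(0.0, h)] + list(zip(xs, ys)) + [(w, h)]
        return Polygon(ring)


@dataclass
class GroundTruth:
    """Every drawn parameter, for recoverability checks."""

    taxa: pd.DataFrame  # per-taxon targets and realizations
    protected_coverage_target: float
    protected_coverage_realized: float
    scenario: SyntheticScenario


class InfeasibleGeometryError(ValueError):
    pass


def _place_range(
    area: float,
    aspect: float,
    cx: float,
    target_p: float,
    scenario: SyntheticScenario,
    focal: Polygon,
) -> Polygon:
    """Place a rectangular range of the given area so the realized fraction
    inside the focal region equals target_p, by bisection on the north-south
    centroid offset (monotone because the range is convex)."""
    w_world, h_world = scenario.world_extent
    if area > scenario.world_polygon().area:
        raise InfeasibleGeometryError("range larger than the world")
    width = np.sqrt(area * aspect)
    height = area / width
    focal_height = h_world - scenario.border_y
    # a rectangle taller than focal_height / p can never have fraction p
    # inside the focal band; shrink the height (area is a nuisance
    # parameter, the target fraction is not)
    max_height = min(0.95 * focal_height / max(target_p, 1e-6), 0.9 * scenario.border_y / max(1.0 - target_p, 1e-6))
    if height > max_height:
        height = max_height
        width = min(area / height, 0.98 * w_world)
    cx = float(np.clip(cx, width / 2.0, w_world - width / 2.0))

    def frac_inside(cy: float) -> float:
        r = box(cx - width / 2.0, cy - height / 2.0, cx + width / 2.0, cy + height / 2.0)
        return r.intersection(focal).area / r.area

    lo = height / 2.0  # fully south
    hi = h_world - height / 2.0  # as far north as the world allows
    f_lo, f_hi = frac_inside(lo), frac_inside(hi)
    target = float(np.clip(target_p, f_lo, f_hi))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac_inside(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(frac_inside(0.5 * (lo + hi)) - target) <= scenario.placement_tol / 4:
            break
    cy = 0.5 * (lo + hi)
    poly = box(cx - width / 2.0, cy - height / 2.0, cx + width / 2.0, cy + height / 2.0)
    return poly, target


def _draw_cx(rng: np.random.Generator, scenario: SyntheticScenario) -> float:
    w, _ = scenario.world_extent
    p_cluster = scenario.southern_clustering / (1.0 + scenario.southern_clustering)
    if rng.random() < p_cluster:
        return float(
            np.clip(
                rng.normal(scenario.cluster_center_frac * w, scenario.cluster_sd_frac * w),
                0.0,
                w,
            )
        )
    return float(rng.uniform(0.0, w))


def _generate_taxa(scenario: SyntheticScenario, focal: Polygon):
    rng = np.random.default_rng([scenario.seed, _STREAM_TAXA])
    a, b = scenario.peripherality_beta
    w_world, _ = scenario.world_extent
    taxa: list[Taxon] = []
    gt_rows: list[dict] = []

    nat_statuses = [s for s in NATIONAL_STATUSES if s != "none"]
    glob_statuses = [s for s in GLOBAL_STATUSES if s != "none"]

    def one_taxon(tid, group, national, global_, rng):
        target_p = float(np.clip(rng.beta(a, b), 0.005, 1.0))
        area = float(
            np.clip(
                rng.lognormal(*scenario.range_area_lognormal), 1e9, 0.2 * focal.area / 0.005
            )
        )
        aspect = float(rng.uniform(0.7, 1.8))
        cx = _draw_cx(rng, scenario)
        rng_poly, target_p = _place_range(area, aspect, cx, target_p, scenario, focal)
        realized = rng_poly.intersection(focal).area / rng_poly.area
        year = int(rng.integers(scenario.assessment_window[0], scenario.assessment_window[1] + 1))
        t = Taxon(
            taxon_id=tid,
            name=f"Synthetic taxon {tid}",
            group=group,
            national_status=national,
            global_status=global_,
            assessment_year=year,
            focal_range=rng_poly.intersection(focal),
            hemisphere_range=rng_poly,
        )
        gt_rows.append(
            {
                "taxon_id": tid,
                "group": group,
                "national_status": national,
                "global_status": global_,
                "target_prop_in_focal": target_p,
                "realized_prop_in_focal": realized,
                "range_area": area,
                "centroid_x": cx,
                "assessment_year": year,
            }
        )
        return t

    i = 0
    for group in GROUPS:
        for _ in range(scenario.group_counts.get(group, 0)):
            national = nat_statuses[rng.integers(0, 3)]
            global_ = (
                glob_statuses[rng.integers(0, 3)]
                if rng.random() < scenario.dual_listing_fraction
                else "none"
            )
            taxa.append(one_taxon(f"t{i:04d}", group, national, global_, rng))
            i += 1
    for _ in range(scenario.n_global_only):
        group = GROUPS[rng.integers(0, len(GROUPS))]
        global_ = glob_statuses[rng.integers(0, 3)]
        taxa.append(one_taxon(f"t{i:04d}", group, "none", global_, rng))
        i += 1
    return taxa, pd.DataFrame(gt_rows)


def _generate_protected(scenario: SyntheticScenario, focal: Polygon):
    """Rejection-placed square patches until the union hits the target
    coverage; the last patch is shrunk by bisection to land within the
    coverage tolerance."""
    rng = np.random.default_rng([scenario.seed, _STREAM_PROTECTION])
    target = scenario.protected_coverage * focal.area
    tol = scenario.coverage_tol * focal.area
    if scenario.protected_coverage <= 0:
        return [], 0.0
    w_world, h_world = scenario.world_extent
    cluster_x = scenario.cluster_center_frac * w_world
    patches: list[Polygon] = []
    union = None
    covered = 0.0
    for _ in range(100_000):
        if covered >= target - tol / 2.0:
            break
        area = float(np.clip(rng.lognormal(*scenario.pa_size_lognormal), 1e7, 0.5 * focal.area))
        side = np.sqrt(area)
        x = rng.uniform(0.0, w_world)
        y = rng.uniform(scenario.border_y, h_world)
        if scenario.protection_bias != 0.0:
            # bias < 0 pushes patches away from the richness cluster band
            d = abs(x - cluster_x) / w_world  # 0 at the cluster, ~1 far away
            accept = np.exp(scenario.protection_bias * (1.0 - 2.0 * d))
            if rng.random() > min(accept, 1.0):
                continue
        patch = box(x - side / 2, y - side / 2, x + side / 2, y + side / 2).intersection(focal)
        if patch.is_empty or patch.area <= 0:
            continue
        new_union = patch if union is None else unary_union([union, patch])
        if new_union.area > target + tol / 2.0:
            # shrink this patch about its centre to hit the target
            lo, hi = 0.0, 1.0
            cx, cy = x, y
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                half = side * mid / 2.0
                cand = box(cx - half, cy - half, cx + half, cy + half).intersection(focal)
                cand_union = cand if union is None else unary_union([union, cand])
                if cand_union.area < target:
                    lo = mid
                else:
                    hi = mid
                if abs(cand_union.area - target) <= tol / 2:
                    break
            half = side * 0.5 * (lo + hi) / 2.0
            patch = box(cx - half, cy - half, cx + half, cy + half).intersection(focal)
            if patch.is_empty:
                continue
            new_union = patch if union is None else unary_union([union, patch])
        patches.append(patch)
        union = new_union
        covered = union.area
    return patches, covered / focal.area


def generate(scenario: SyntheticScenario) -> tuple[StudyLayers, GroundTruth]:
    """Build a complete StudyLayers bundle plus its ground truth."""
    focal = scenario.focal_polygon()
    world = scenario.world_polygon()
    taxa, gt_taxa = _generate_taxa(scenario, focal)
    patches, realized_cov = _generate_protected(scenario, focal)
    layers = StudyLayers(
        focal_region=focal,
        hemisphere_mask=world,
        protected_areas=patches,
        taxa=taxa,
        crs_note="synthetic planar equal-area frame (m)",
    )
    gt = GroundTruth(
        taxa=gt_taxa,
        protected_coverage_target=scenario.protected_coverage,
        protected_coverage_realized=realized_cov,
        scenario=scenario,
    )
    return layers, gt


NULL_VARIANTS = (
    "no_status_effect",
    "no_group_effect",
    "equal_national_global",
    "protection_independent_of_richness",
)


def make_null_variant(scenario: SyntheticScenario, which: str) -> SyntheticScenario:
    """A scenario with the named effect removed, everything else fixed.

    In this generator taxa of every status and group already share one
    peripherality distribution and one placement rule, so the first three
    variants are the base scenario unchanged (they exist so calibration
    code can state its intent); the protection variant removes the
    east-west placement bias so cell protection is independent of richness.
    """
    if which not in NULL_VARIANTS:
        raise ValueError(f"unknown null variant {which!r}; one of {NULL_VARIANTS}")
    if which == "protection_independent_of_richness":
        return replace(scenario, protection_bias=0.0)
    return scenario


def analytic_median(scenario: SyntheticScenario) -> float:
    """Median of the scenario's target peripherality Beta distribution."""
    a, b = scenario.peripherality_beta
    return float(stats.beta.ppf(0.5, a, b))
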