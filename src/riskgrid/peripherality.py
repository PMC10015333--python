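"""Peripherality: the proportion of each taxon's hemisphere range that
falls inside the focal region.

The smaller the proportion, the more peripheral the taxon is in the focal
jurisdiction — many at-risk taxa in high-latitude countries only enter at
the poleward edge of a much larger range. The statistic reported here is the
inverse of peripherality: 1.0 means endemic, values near 0 mean the focal
populations are a thin range edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geoio import StudyLayers, Taxon

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class TaxonMetrics:
    """Per-taxon scalar metrics assembled across pipeline stages."""

    taxon_id: str
    focal_range_area: float
    hemisphere_range_area: float | None
    prop_in_focal: float | None
    protected_fraction: float | None = None
    years_since_assessment: float | None = None


def prop_range_in_focal(t: Taxon, layers: StudyLayers) -> float:
    """area(range ∩ focal ∩ hemisphere mask) / area(range ∩ hemisphere mask).

    The denominator clips the range to the hemisphere mask; the numerator is
    additionally clipped to the focal region, so digitization noise that
    pushes the focal portion slightly outside the hemisphere map cannot push
    the ratio above 1. Endemics return exactly 1.0.
    """
    if t.hemisphere_range is None:
        raise ValueError(f"taxon {t.taxon_id!r} has no hemisphere range")
    denom_geom = t.hemisphere_range.intersection(layers.hemisphere_mask)
    denom = denom_geom.area
    if denom <= 0:
        raise DegenerateGeometryError(
            f"taxon {t.taxon_id!r}: hemisphere range has zero area inside the mask"
        )
    numer = denom_geom.intersection(layers.focal_region).area
    return min(numer / denom, 1.0)


def compute_metrics(layers: StudyLayers, reference_year: int = 2020) -> pd.DataFrame:
    """Per-taxon metrics table (peripherality columns; protection filled by
    the protection module). Taxa without a hemisphere range get NaN
    prop_in_focal and are reported, mirroring map-source attrition."""
    rows = []
    skipped = []
    for t in layers.taxa:
        if t.hemisphere_range is not None:
            prop = prop_range_in_focal(t, layers)
            hemi_area = t.hemisphere_range.intersection(layers.hemisphere_mask).area
        else:
            prop = np.nan
            hemi_area = np.nan
            skipped.append(t.taxon_id)
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "group": t.group,
                "national_status": t.national_status,
                "global_status": t.global_status,
                "focal_range_area": t.focal_range.intersection(layers.focal_region).area,
                "hemisphere_range_area": hemi_area,
                "prop_in_focal": prop,
                "years_since_assessment": (
                    np.nan
                    if t.assessment_year is None
                    else float(reference_year - t.assessment_year)
                ),
            }
        )
    if skipped:
        logger.info(
            "%d taxa lack a hemisphere range and are excluded from "
            "peripherality: %s",
            len(skipped),
            skipped,
        )
    return pd.DataFrame(rows)


def peripherality_summary(
    metrics: pd.DataFrame,
    by: list[str] | None = None,
    cutoff: float = 0.20,
) -> pd.DataFrame:
    """Summary of prop_in_focal per grouping level: n, mean, median, the
    fraction below ``cutoff`` (default 20% of range in the focal region) and
    the fraction of endemics (exactly 1 after clipping)."""
    if len(metrics) == 0:
        raise ValueError("metrics table is empty")
    df = metrics.dropna(subset=["prop_in_focal"])

    def summarize(sub: pd.DataFrame) -> pd.Series:
        p = sub["prop_in_focal"].to_numpy()
        return pd.Series(
            {
                "n": len(p),
                "mean": p.mean() if len(p) else np.nan,
                "median": float(np.median(p)) if len(p) else np.nan,
                f"frac_below_{cutoff:g}": float((p < cutoff).mean()) if len(p) else np.nan,
                "frac_endemic": float((p == 1.0).mean()) if len(p) else np.nan,
            }
        )

    if not by:
        out = summarize(df).to_frame().T
        out.insert(0, "level", "all")
        return out.reset_index(drop=True)
    parts = []
    for keys, sub in df.groupby(by, sort=True):
        row = summarize(sub)
        if not isinstance(keys, tuple):
            keys = (keys,)
        for k, v in zip(by, keys):
            row[k] = v
        parts.append(row)
    out = pd.DataFrame(parts).reset_index(drop=True)
    return out[[*by, "n", "mean", "median", f"frac_below_{cutoff:g}", "frac_endemic"]]
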