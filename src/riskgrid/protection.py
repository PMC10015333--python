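"""Protected-area overlap per taxon range and per grid cell, and the
hotspot vs non-hotspot protection summaries.

Per-cell statistics use the cell's land area as the denominator (land in the
focal region only, not the full square). Per-taxon statistics use the range
clipped to the focal region. The per-cell protection-vs-richness trends are
deliberately descriptive: grid-cell data are strongly spatially
autocorrelated, so the beta-regression confidence bands attached to the
trend are likely too narrow and no p-value is surfaced in the headline
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .betareg import BetaRegFit, LRTResult, fit_beta, lrt, squeeze
from .geoio import StudyLayers, Taxon
from .gridding import PresenceMatrix, RegionGrid
from .hotspots import HotspotSet
from .peripherality import DegenerateGeometryError


def protected_fraction_range(t: Taxon, layers: StudyLayers) -> float:
    """Fraction of the taxon's focal-region range overlapped by protected
    areas: area(range ∩ focal ∩ protected) / area(range ∩ focal)."""
    clipped = t.focal_range.intersection(layers.focal_region)
    denom = clipped.area
    if denom <= 0:
        raise DegenerateGeometryError(
            f"taxon {t.taxon_id!r}: range has zero area inside the focal region"
        )
    if not layers.protected_areas:
        return 0.0
    numer = clipped.intersection(layers.protected_union).area
    return min(numer / denom, 1.0)


def add_protection_metrics(metrics: pd.DataFrame, layers: StudyLayers) -> pd.DataFrame:
    """Fill the protected_fraction column of a per-taxon metrics table."""
    by_id = {t.taxon_id: t for t in layers.taxa}
    fracs = [
        protected_fraction_range(by_id[tid], layers) for tid in metrics["taxon_id"]
    ]
    out = metrics.copy()
    out["protected_fraction"] = fracs
    return out


@dataclass
class CellProtectionSummary:
    """Aggregates over the cell table: mean/median protected fraction for
    hotspot vs non-hotspot cells and pooled land-weighted protection of each
    hotspot set (sum of protected area over sum of land area)."""

    table: pd.DataFrame
    mean_hotspot_national: float
    median_hotspot_national: float
    mean_nonhotspot_national: float
    median_nonhotspot_national: float
    mean_hotspot_global: float
    median_hotspot_global: float
    mean_nonhotspot_global: float
    median_nonhotspot_global: float
    landweighted_hotspot_national: float
    landweighted_hotspot_global: float
    landweighted_hotspot_both: float


def _mean_median(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return (float("nan"), float("nan"))
    return float(x.mean()), float(np.median(x))


def _landweighted(df: pd.DataFrame, mask: np.ndarray) -> float:
    land = df["land_area"].to_numpy()[mask].sum()
    if land <= 0:
        return 0.0
    return float(df["protected_area"].to_numpy()[mask].sum() / land)


def cell_protection_table(
    grid: RegionGrid,
    pm: PresenceMatrix,
    hotspot_national: HotspotSet,
    hotspot_global: HotspotSet,
    national_ids: list[str],
    global_ids: list[str],
) -> CellProtectionSummary:
    """One record per cell with richness, hotspot membership and protection,
    plus hotspot vs non-hotspot aggregates."""
    df = grid.to_frame()
    df["protected_fraction"] = df["protected_area"] / df["land_area"]
    df["richness_national"] = pm.richness(national_ids)
    df["richness_global"] = pm.richness(global_ids)
    df["is_hotspot_national"] = [
        cid in hotspot_national.cell_ids for cid in df["cell_id"]
    ]
    df["is_hotspot_global"] = [cid in hotspot_global.cell_ids for cid in df["cell_id"]]

    pf = df["protected_fraction"].to_numpy()
    hn = df["is_hotspot_national"].to_numpy()
    hg = df["is_hotspot_global"].to_numpy()
    mh_n, md_n = _mean_median(pf[hn])
    mn_n, mdn_n = _mean_median(pf[~hn])
    mh_g, md_g = _mean_median(pf[hg])
    mn_g, mdn_g = _mean_median(pf[~hg])
    return CellProtectionSummary(
        table=df,
        mean_hotspot_national=mh_n,
        median_hotspot_national=md_n,
        mean_nonhotspot_national=mn_n,
        median_nonhotspot_national=mdn_n,
        mean_hotspot_global=mh_g,
        median_hotspot_global=md_g,
        mean_nonhotspot_global=mn_g,
        median_nonhotspot_global=mdn_g,
        landweighted_hotspot_national=_landweighted(df, hn),
        landweighted_hotspot_global=_landweighted(df, hg),
        landweighted_hotspot_both=_landweighted(df, hn & hg),
    )


def protection_vs_richness(
    records: pd.DataFrame,
    stratum: str,
    hotspot: bool,
    richness_col: str = "richness_national",
) -> tuple[BetaRegFit, pd.DataFrame]:
    """Descriptive beta-regression trend of per-cell protected fraction on
    at-risk richness within hotspot or non-hotspot cells.

    Returns the fit and a fitted trend line for plotting. No p-value is
    surfaced; bands derived from the vcov are likely too narrow because of
    spatial autocorrelation.
    """
    flag_col = {"national": "is_hotspot_national", "global": "is_hotspot_global"}[
        stratum
    ]
    sub = records[records[flag_col] == hotspot]
    if len(sub) < 10:
        raise ValueError(
            f"stratum has {len(sub)} cells; at least 10 required for a trend"
        )
    y = squeeze(sub["protected_fraction"].to_numpy(), len(sub))
    if np.allclose(y, y[0]):
        raise ValueError("all protected fractions identical in stratum; singular fit")
    r = sub[richness_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(r), r])
    fit = fit_beta(y, X, names=["intercept", richness_col])
    grid_r = np.linspace(r.min(), r.max(), 50)
    eta = fit.coefficients[0] + fit.coefficients[1] * grid_r
    trend = pd.DataFrame(
        {"richness": grid_r, "fitted_protected_fraction": 1 / (1 + np.exp(-eta))}
    )
    trend.attrs["note"] = (
        "descriptive trend; CI from vcov likely too narrow (spatial autocorrelation)"
    )
    return fit, trend


def protection_vs_time(metrics: pd.DataFrame) -> tuple[BetaRegFit, LRTResult]:
    """Does habitat protection increase with time since at-risk assessment?

    Beta regression of protected_fraction on years_since_assessment, with a
    likelihood-ratio test of the slope against the intercept-only model. A
    flat relationship means being deemed at risk has not translated into
    subsequent habitat protection.
    """
    sub = metrics.dropna(subset=["years_since_assessment", "protected_fraction"])
    if len(sub) == 0:
        raise ValueError("no taxa with an assessment year")
    if len(sub) < 10:
        raise ValueError(f"only {len(sub)} taxa with assessment years; need >= 10")
    y = squeeze(sub["protected_fraction"].to_numpy(), len(sub))
    if np.allclose(y, y[0]):
        raise ValueError("all protected fractions identical; singular fit")
    t = sub["years_since_assessment"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    full = fit_beta(y, X, names=["intercept", "years_since_assessment"])
    reduced = fit_beta(y, X[:, :1], names=["intercept"])
    return full, lrt(full, reduced)
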