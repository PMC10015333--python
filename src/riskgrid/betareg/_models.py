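"""The five standard proportion models of the analysis.

M1: proportion of hemisphere range in the focal region ~ national status x
    taxonomic group (nationally at-risk taxa; vascular plants and mosses
    merged into 'plants'; the interaction is dropped when its LRT is
    non-significant).
M2: the same proportion ~ six-level threat status (three national + three
    global levels), each taxon contributing one row per listing body, with
    a random intercept per taxon for the dual-listed.
M3: as M2 with status collapsed to national vs global.
M4: proportion of focal range protected ~ national status.
M5: proportion of focal range protected ~ global status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._contrasts import ContrastTable, lsmeans_contrasts
from ._design import build_design
from ._fit import BetaRegFit, LRTResult, fit_beta, fit_beta_mixed, lrt, squeeze

logger = logging.getLogger(__name__)

NATIONAL_LEVELS = ["special_concern", "threatened", "endangered"]
GLOBAL_LEVELS = ["vulnerable", "endangered_g", "critically_endangered"]
STATUS6_LEVELS = NATIONAL_LEVELS + GLOBAL_LEVELS
MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class ModelResult:
    model_id: str
    n: int
    final_fit: BetaRegFit
    lrts: dict[str, LRTResult] = field(default_factory=dict)
    contrasts: dict[str, ContrastTable] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def coefficient_frame(self) -> pd.DataFrame:
        f = self.final_fit
        se = np.sqrt(np.clip(np.diag(f.vcov), 0.0, None))
        return pd.DataFrame(
            {"term": f.names, "estimate": f.coefficients, "se": se,
             "z": f.coefficients / np.where(se > 0, se, np.nan)}
        )


def _merge_plants(group: pd.Series) -> pd.Series:
    return group.replace({"vascular_plants": "plants", "mosses": "plants"})


def _stacked_status_rows(data: pd.DataFrame, response: str) -> pd.DataFrame:
    """One row per taxon per listing body; dual-listed taxa appear twice
    sharing the taxon id as random-intercept group."""
    nat = data[data["national_status"] != "none"].copy()
    nat["status6"] = nat["national_status"]
    nat["listing"] = "national"
    glob = data[data["global_status"] != "none"].copy()
    glob["status6"] = glob["global_status"]
    glob["listing"] = "global"
    out = pd.concat([nat, glob], ignore_index=True)
    return out.dropna(subset=[response])


def run_model(model_id: str, data: pd.DataFrame, alpha: float = 0.05) -> ModelResult:
    """Fit one of the standard models on a per-taxon metrics table.

    ``data`` needs columns taxon_id, group, national_status, global_status,
    prop_in_focal, protected_fraction (models M4/M5). All fits are
    deterministic; responses are squeezed with n = model rows.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if model_id == "M1":
        return _run_m1(data, alpha)
    if model_id in ("M2", "M3"):
        return _run_m23(model_id, data)
    return _run_m45(model_id, data)


def _run_m1(data: pd.DataFrame, alpha: float) -> ModelResult:
    sub = data[data["national_status"] != "none"].dropna(subset=["prop_in_focal"]).copy()
    sub["group_m1"] = _merge_plants(sub["group"])
    n = len(sub)
    y = squeeze(sub["prop_in_focal"].to_numpy(), n)
    notes = [f"{n} nationally at-risk taxa with hemisphere ranges"]

    factors = {"national_status": NATIONAL_LEVELS, "group_m1": None}
    d_full, X_full = build_design(
        sub, factors, interaction=("national_status", "group_m1"), drop_aliased=True
    )
    if d_full.dropped_columns:
        notes.append(f"aliased interaction columns dropped: {d_full.dropped_columns}")
    d_main, X_main = build_design(sub, factors)
    fit_full = fit_beta(y, X_full, names=d_full.columns, design_info=d_full)
    fit_main = fit_beta(y, X_main, names=d_main.columns, design_info=d_main)
    lrt_int = lrt(fit_full, fit_main)
    lrts = {"interaction": lrt_int}

    if lrt_int.p < alpha:
        final = fit_full
        notes.append("interaction retained (LRT significant)")
    else:
        final = fit_main
        notes.append("interaction dropped (LRT non-significant)")
        d_nostat, X_nostat = build_design(sub, {"group_m1": None})
        d_nogrp, X_nogrp = build_design(sub, {"national_status": NATIONAL_LEVELS})
        lrts["national_status"] = lrt(
            fit_main, fit_beta(y, X_nostat, names=d_nostat.columns)
        )
        lrts["group_m1"] = lrt(fit_main, fit_beta(y, X_nogrp, names=d_nogrp.columns))

    contrasts = {
        "national_status": lsmeans_contrasts(final, "national_status"),
        "group_m1": lsmeans_contrasts(final, "group_m1"),
    }
    return ModelResult("M1", n, final, lrts, contrasts, notes)


def _run_m23(model_id: str, data: pd.DataFrame) -> ModelResult:
    stacked = _stacked_status_rows(data, "prop_in_focal")
    n = len(stacked)
    y = squeeze(stacked["prop_in_focal"].to_numpy(), n)
    groups = stacked["taxon_id"].to_numpy()
    n_dual = int(stacked["taxon_id"].duplicated().sum())
    notes = [f"{n} rows ({n_dual} taxa listed by both bodies appear twice)"]

    factor = "status6" if model_id == "M2" else "listing"
    levels = STATUS6_LEVELS if model_id == "M2" else ["national", "global"]
    d_full, X_full = build_design(stacked, {factor: levels})
    fit_full = fit_beta_mixed(y, X_full, groups, names=d_full.columns, design_info=d_full)
    d_red, X_red = build_design(stacked, {})
    fit_red = fit_beta_mixed(y, X_red, groups, names=d_red.columns)
    lrts = {factor: lrt(fit_full, fit_red)}
    if fit_full.boundary:
        notes.append("random-intercept SD estimated at the zero boundary")
    contrasts = {factor: lsmeans_contrasts(fit_full, factor)}
    return ModelResult(model_id, n, fit_full, lrts, contrasts, notes)


def _run_m45(model_id: str, data: pd.DataFrame) -> ModelResult:
    status_col = "national_status" if model_id == "M4" else "global_status"
    levels = NATIONAL_LEVELS if model_id == "M4" else GLOBAL_LEVELS
    sub = data[data[status_col] != "none"].dropna(subset=["protected_fraction"]).copy()
    n = len(sub)
    y = squeeze(sub["protected_fraction"].to_numpy(), n)
    notes = [f"{n} taxa with {status_col} set"]

    d_full, X_full = build_design(sub, {status_col: levels})
    fit_full = fit_beta(y, X_full, names=d_full.columns, design_info=d_full)
    d_red, X_red = build_design(sub, {})
    fit_red = fit_beta(y, X_red, names=d_red.columns)
    lrts = {status_col: lrt(fit_full, fit_red)}
    contrasts = {status_col: lsmeans_contrasts(fit_full, status_col)}
    return ModelResult(model_id, n, fit_full, lrts, contrasts, notes)
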