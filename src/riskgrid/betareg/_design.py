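"""Minimal design-matrix builder: treatment-coded factors, continuous
covariates, and one optional two-way interaction.

Keeps enough metadata (factor levels, continuous means) to build balanced
reference grids for least-squares means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    pass


@dataclass
class Design:
    factors: dict[str, list[str]]  # name -> levels, first level is reference
    continuous: list[str]
    interaction: tuple[str, str] | None
    columns: list[str] = field(default_factory=list)
    cont_means: dict[str, float] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)

    def _build_columns(self) -> list[str]:
        cols = ["intercept"]
        for f, levels in self.factors.items():
            cols += [f"{f}[{lv}]" for lv in levels[1:]]
        cols += list(self.continuous)
        if self.interaction is not None:
            f1, f2 = self.interaction
            for l1 in self.factors[f1][1:]:
                for l2 in self.factors[f2][1:]:
                    cols.append(f"{f1}[{l1}]:{f2}[{l2}]")
        return [c for c in cols if c not in self.dropped_columns]

    def row(self, levels: dict[str, str], cont: dict[str, float] | None = None) -> np.ndarray:
        """Design row for one combination of factor levels (continuous
        covariates default to their observed means)."""
        cont = cont or {}
        vals: dict[str, float] = {"intercept": 1.0}
        for f, lvls in self.factors.items():
            for lv in lvls[1:]:
                vals[f"{f}[{lv}]"] = 1.0 if levels[f] == lv else 0.0
        for c in self.continuous:
            vals[c] = cont.get(c, self.cont_means.get(c, 0.0))
        if self.interaction is not None:
            f1, f2 = self.interaction
            for l1 in self.factors[f1][1:]:
                for l2 in self.factors[f2][1:]:
                    vals[f"{f1}[{l1}]:{f2}[{l2}]"] = (
                        1.0 if (levels[f1] == l1 and levels[f2] == l2) else 0.0
                    )
        return np.array([vals[c] for c in self.columns])

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.empty((n, len(self.columns)))
        col_arrays: dict[str, np.ndarray] = {"intercept": np.ones(n)}
        for f, lvls in self.factors.items():
            obs = df[f].to_numpy()
            for lv in lvls[1:]:
                col_arrays[f"{f}[{lv}]"] = (obs == lv).astype(float)
        for c in self.continuous:
            col_arrays[c] = df[c].to_numpy(dtype=float)
        if self.interaction is not None:
            f1, f2 = self.interaction
            for l1 in self.factors[f1][1:]:
                for l2 in self.factors[f2][1:]:
                    col_arrays[f"{f1}[{l1}]:{f2}[{l2}]"] = (
                        col_arrays[f"{f1}[{l1}]"] * col_arrays[f"{f2}[{l2}]"]
                    )
        for j, c in enumerate(self.columns):
            X[:, j] = col_arrays[c]
        return X

    def reference_grid(self) -> list[dict[str, str]]:
        """Balanced grid: the cartesian product of all factor levels."""
        names = list(self.factors)
        combos = itertools.product(*(self.factors[f] for f in names))
        return [dict(zip(names, combo)) for combo in combos]


def build_design(
    df: pd.DataFrame,
    factors: dict[str, list[str] | None] | list[str],
    continuous: list[str] | None = None,
    interaction: tuple[str, str] | None = None,
    drop_aliased: bool = False,
) -> tuple[Design, np.ndarray]:
    """Construct a Design and its matrix for ``df``.

    Factor levels may be given explicitly (unobserved levels are dropped
    with a log message) or inferred in sorted order. With ``drop_aliased``,
    rank-deficient columns (e.g. empty factor-level combinations under an
    interaction) are dropped; otherwise rank deficiency raises
    SingularDesignError naming the aliased columns.
    """
    if isinstance(factors, list):
        factors = {f: None for f in factors}
    resolved: dict[str, list[str]] = {}
    for f, lvls in factors.items():
        observed = list(pd.unique(df[f]))
        if lvls is None:
            resolved[f] = sorted(observed)
        else:
            kept = [lv for lv in lvls if lv in observed]
            missing = [lv for lv in lvls if lv not in observed]
            if missing:
                logger.warning("factor %s: dropping unobserved levels %s", f, missing)
            if len(kept) < 1:
                raise ValueError(f"factor {f} has no observed levels")
            resolved[f] = kept
        extra = sorted(set(observed) - set(resolved[f]))
        if extra:
            raise ValueError(f"factor {f}: unexpected levels {extra}")

    continuous = list(continuous or [])
    design = Design(factors=resolved, continuous=continuous, interaction=interaction)
    design.cont_means = {c: float(df[c].mean()) for c in continuous}
    design.columns = design._build_columns()
    X = design.matrix(df)

    # detect aliased columns by incremental rank
    aliased: list[str] = []
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j, cname in enumerate(design.columns):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
            keep.append(j)
        else:
            aliased.append(cname)
    if aliased:
        if not drop_aliased:
            raise SingularDesignError(f"aliased design columns: {aliased}")
        logger.warning("dropping aliased design columns: %s", aliased)
        design.dropped_columns = aliased
        design.columns = [design.columns[j] for j in keep]
        X = X[:, keep]
    return design, X
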