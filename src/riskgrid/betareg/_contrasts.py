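"""Least-squares means and pairwise contrasts on the logit scale.

LS means are factor-level linear predictors evaluated on a balanced
reference grid: other factors weighted equally across their levels,
continuous covariates at their observed means. Pairwise differences use
delta-method SEs from the coefficient covariance; the default multiplicity
adjustment is Tukey's studentized-range (the asymptotic, infinite-df form),
and a compact letter display is produced at alpha = 0.05.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._fit import BetaRegFit


@dataclass
class ContrastTable:
    factor: str
    lsmeans: pd.DataFrame  # level, estimate (logit), se, response_scale
    contrasts: pd.DataFrame  # level_a, level_b, estimate, se, z, p, p_adjusted
    letters: dict[str, str]
    alpha: float = 0.05


def _tukey_sf(z_abs: float, k: int) -> float:
    # |z|*sqrt(2) is the studentized-range statistic with infinite df
    return float(stats.studentized_range.sf(z_abs * np.sqrt(2.0), k, np.inf))


def compact_letters(
    levels: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Assign letters so that two levels share a letter iff they are not
    significantly different. Letter groups are the maximal cliques of the
    non-significance graph, ordered by their best (highest) mean."""
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    adj = np.ones((k, k), dtype=bool)
    for pair in significant:
        a, b = tuple(pair)
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = False

    cliques: list[frozenset[int]] = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(adj[i, j] for i, j in combinations(members, 2)):
            s = frozenset(members)
            if not any(s < c for c in cliques):
                cliques = [c for c in cliques if not c < s]
                cliques.append(s)
    cliques.sort(key=lambda c: -max(means[levels[i]] for i in c))
    letters = {lv: "" for lv in levels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for i in sorted(clique):
            letters[levels[i]] += letter
    return letters


def lsmeans_contrasts(
    fit: BetaRegFit,
    factor: str,
    adjust: str = "tukey",
    alpha: float = 0.05,
) -> ContrastTable:
    """All pairwise least-squares-mean contrasts for one factor."""
    if adjust not in ("tukey", "none"):
        raise ValueError("adjust must be 'tukey' or 'none'")
    design = fit.design_info
    if design is None:
        raise ValueError("fit carries no design info; refit via build_design")
    if factor not in design.factors:
        raise ValueError(f"factor {factor!r} not in the design")
    levels = design.factors[factor]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")

    beta = fit.coefficients
    V = fit.vcov
    grid = design.reference_grid()

    def lsmean_row(level: str) -> np.ndarray:
        rows = [design.row(dict(g, **{factor: level})) for g in grid if g[factor] == levels[0]]
        return np.mean(rows, axis=0)

    xbar = {lv: lsmean_row(lv) for lv in levels}
    ls = pd.DataFrame(
        {
            "level": levels,
            "estimate": [float(xbar[lv] @ beta) for lv in levels],
            "se": [float(np.sqrt(max(xbar[lv] @ V @ xbar[lv], 0.0))) for lv in levels],
        }
    )
    ls["response_scale"] = 1.0 / (1.0 + np.exp(-ls["estimate"]))

    k = len(levels)
    rows = []
    for a, b in combinations(levels, 2):
        c = xbar[a] - xbar[b]
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        z = est / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = _tukey_sf(abs(z), k) if adjust == "tukey" else p
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
                "p_adjusted": max(p_adj, p),
            }
        )
    contrasts = pd.DataFrame(rows)

    significant = {
        frozenset((r["level_a"], r["level_b"]))
        for _, r in contrasts.iterrows()
        if r["p_adjusted"] < alpha
    }
    means = dict(zip(ls["level"], ls["estimate"]))
    letters = compact_letters(levels, means, significant)
    return ContrastTable(
        factor=factor, lsmeans=ls, contrasts=contrasts, letters=letters, alpha=alpha
    )
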