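"""Nonparametric group comparison battery.

For every extracted feature: a Shapiro-Wilk normality screen per group,
a tie-corrected Kruskal-Wallis omnibus test across the three groups, and
-- when the omnibus is significant at alpha = 0.05 -- Dunn's rank-based
post hoc z tests on the pairs (C-D, D-T, T-C).  Post hoc p-values are
unadjusted by default (Holm available by flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHA = 0.05
DEFAULT_PAIRS = (("C", "D"), ("D", "T"), ("T", "C"))


@dataclass
class GroupComparison:
    """Full statistical record for one feature across the groups."""

    feature: str
    group_n: dict[str, int]
    shapiro: dict[str, tuple[float, float] | None]  # group -> (W, p), None if n/a
    kw_h: float
    kw_p: float
    dunn: dict[tuple[str, str], tuple[float, float]] | None  # pair -> (z, p)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.kw_p < self.alpha)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation via scipy).

    Requires 3 <= n <= 5000; a constant sample has no defined W and is
    reported as non-computable by the caller.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk p-approximation unreliable above n=5000")
    if np.ptp(values) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    H = [12/(N(N+1))] * sum n_i Rbar_i^2 - 3(N+1), divided by
    1 - sum(t^3 - t)/(N^3 - N) over tie groups.  All-identical data give
    H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    groups: dict[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    holm: bool = False,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's pairwise z tests on the joint ranks of all groups.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))
    * (1/n_i + 1/n_j)], two-sided normal p.  Unadjusted by default; Holm
    step-down adjustment behind the flag.
    """
    names = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=np.float64) for g in names}
    for a, b in pairs:
        if a not in arrays or b not in arrays:
            raise ValueError(f"pair ({a}, {b}) references an unknown group")
        if len(arrays[a]) == 0 or len(arrays[b]) == 0:
            raise ValueError(f"pair ({a}, {b}) has an empty group")
    pooled = np.concatenate([arrays[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for g in names:
        n = len(arrays[g])
        mean_rank[g] = float(ranks[pos:pos + n].mean())
        pos += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in pairs:
        na, nb = len(arrays[a]), len(arrays[b])
        se = np.sqrt(denom_base * (1.0 / na + 1.0 / nb))
        if se == 0:  # fully tied data
            out[(a, b)] = (0.0, 1.0)
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = (float(z), float(min(p, 1.0)))
    if holm:
        out = _holm_adjust(out)
    return out


def _holm_adjust(results):
    items = sorted(results.items(), key=lambda kv: kv[1][1])
    m = len(items)
    adjusted, running = {}, 0.0
    for rank, (pair, (z, p)) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[pair] = (z, running)
    return {pair: adjusted[pair] for pair in results}


def compare_feature(
    name: str,
    groups: dict[str, Sequence[float]],
    alpha: float = ALPHA,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    posthoc_always: bool = False,
    holm: bool = False,
) -> GroupComparison:
    """Run the full battery (normality screen, omnibus, post hoc) on one feature."""
    shapiro: dict[str, tuple[float, float] | None] = {}
    for g, vals in groups.items():
        try:
            shapiro[g] = shapiro_wilk(vals)
        except ValueError:
            shapiro[g] = None
    h, p = kruskal_wallis(list(groups.values()))
    dunn = None
    if posthoc_always or p < alpha:
        usable = [(a, b) for a, b in pairs if a in groups and b in groups]
        dunn = dunn_posthoc(groups, usable, holm=holm)
    return GroupComparison(
        feature=name,
        group_n={g: len(v) for g, v in groups.items()},
        shapiro=shapiro,
        kw_h=h,
        kw_p=p,
        dunn=dunn,
        alpha=alpha,
    )


def compare_table(
    table: pd.DataFrame,
    group_col: str = "group",
    alpha: float = ALPHA,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    posthoc_always: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Battery over every numeric column of a feature table.

    Returns one row per feature with W/p per group, KW H/p, Dunn z/p per
    pair and 0.05-level significance flags.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    labels = table[group_col]
    feature_cols = [
        c for c in table.columns
        if c != group_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for col in feature_cols:
        groups = {
            g: table.loc[labels == g, col].to_numpy()
            for g in sorted(labels.unique())
        }
        cmp_ = compare_feature(col, groups, alpha=alpha, pairs=pairs,
                               posthoc_always=posthoc_always, holm=holm)
        row: dict = {"feature": col, "kw_H": cmp_.kw_h, "kw_p": cmp_.kw_p,
                     "significant": cmp_.significant}
        for g, res in cmp_.shapiro.items():
            row[f"shapiro_W_{g}"] = res[0] if res else np.nan
            row[f"shapiro_p_{g}"] = res[1] if res else np.nan
            row[f"n_{g}"] = cmp_.group_n[g]
        for a, b in pairs:
            key = f"dunn_{a}{b}"
            if cmp_.dunn and (a, b) in cmp_.dunn:
                z, p = cmp_.dunn[(a, b)]
                row[f"{key}_z"], row[f"{key}_p"] = z, p
            else:
                row[f"{key}_z"], row[f"{key}_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)
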