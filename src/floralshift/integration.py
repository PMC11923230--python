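"""Floral trait integration censuses.

Traits fall into four categories (volatiles, colour, morphology, nectar).
Integration is summarised by the census of all-pairs Pearson correlation
coefficients (PCCs): how many trait pairs exist, how many are significantly
correlated at alpha, and how the distribution of |PCC| within a category
compares across lines (classical one-way F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("floralshift.integration")

CATEGORIES = ("volatiles", "color", "morphology", "nectar")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PccCensus:
    """All-pairs Pearson correlation census of one trait matrix."""

    n_traits: int
    pairs: pd.DataFrame  # columns: trait_a, trait_b, n, r, p
    n_undefined: int = 0

    @property
    def n_pairs(self) -> int:
        return n_pairs(self.n_traits)

    def n_significant(self, alpha: float = DEFAULT_ALPHA) -> int:
        return int((self.pairs["p"] < alpha).sum())


def n_pairs(k: int) -> int:
    """Number of unordered trait pairs, k(k-1)/2."""
    if k < 2:
        raise ValueError(f"need at least 2 traits, got {k}")
    return k * (k - 1) // 2


def pcc_matrix(traits: pd.DataFrame, min_n: int = 3) -> PccCensus:
    """Pearson r and two-sided p for every trait pair.

    Rows are samples, columns traits. Missing values are handled
    pairwise-complete; a pair with fewer than ``min_n`` complete
    observations, or a constant column within its complete observations, is
    undefined and excluded from the census (logged). Constant columns are
    dropped up front with a warning and do not count toward n_traits.

    p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df, two-sided.
    """
    numeric = traits.select_dtypes(include=[np.number])
    constant = [c for c in numeric.columns if numeric[c].dropna().nunique() <= 1]
    if constant:
        logger.warning("dropping constant trait columns: %s", constant)
        numeric = numeric.drop(columns=constant)
    cols = list(numeric.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 non-constant numeric traits")
    rows = []
    undefined = 0
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = numeric[[a, b]].dropna()
            n = len(sub)
            if n < min_n or sub[a].nunique() <= 1 or sub[b].nunique() <= 1:
                undefined += 1
                logger.info("pair (%s, %s) undefined (n=%d)", a, b, n)
                continue
            r, p = stats.pearsonr(sub[a], sub[b])
            rows.append({"trait_a": a, "trait_b": b, "n": n, "r": float(r), "p": float(p)})
    pairs = pd.DataFrame(rows, columns=["trait_a", "trait_b", "n", "r", "p"])
    return PccCensus(n_traits=len(cols), pairs=pairs, n_undefined=undefined)


def percent_significant(census: PccCensus, alpha: float = DEFAULT_ALPHA) -> float:
    """Percent of trait pairs significant at alpha, to 2 decimals.

    The denominator is the full k(k-1)/2 pair count of the census.
    """
    np_ = census.n_pairs
    if np_ == 0:
        raise ValueError("census has no pairs")
    return round(100.0 * census.n_significant(alpha) / np_, 2)


def category_f_test(
    abs_pcc_by_line: Mapping[str, Sequence[float]],
) -> tuple[float, int, int, float]:
    """One-way ANOVA F comparing |PCC| distributions across lines.

    Returns (F, df_between, df_within, p).
    """
    groups = [np.asarray(v, dtype=float) for v in abs_pcc_by_line.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if any(np.any(np.isnan(g)) for g in groups):
        raise ValueError("groups contain NaN")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    if not np.isfinite(f):  # all-identical degenerate case
        raise ValueError("degenerate groups: F undefined")
    return float(f), k - 1, n - k, float(p)


def terpenoid_carotenoid_correlation(
    totals: pd.DataFrame,
    group_col: str = "color",
    x_col: str = "terpenoid_total",
    y_col: str = "carotenoid_total",
) -> dict[str, tuple[float, float]]:
    """Pearson r and p between per-plant total terpenoid emission and total
    carotenoid production, within each colour group."""
    out = {}
    for group, sub in totals.groupby(group_col, observed=True):
        sub = sub[[x_col, y_col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has n < 3 complete pairs")
        r, p = stats.pearsonr(sub[x_col], sub[y_col])
        out[group] = (float(r), float(p))
    return out
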