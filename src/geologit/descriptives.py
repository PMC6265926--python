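"""Descriptive screening stage: prevalence tables and chi-square tests.

Mirrors the univariate stage of a survey analysis: the method-type mix
(none / traditional / modern), per-category prevalence cross-tabs
against the binary outcome, and Pearson chi-square tests of
independence at the 5% level that gate covariates into the multivariate
model.  Percentages are rounded half-up to one decimal, the print
convention of survey reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .dataset import OUTCOME

__all__ = [
    "round_half_up",
    "prevalence_by_method",
    "crosstab",
    "screen_covariates",
    "CrossTab",
]

log = logging.getLogger(__name__)

_METHODS = ("none", "traditional", "modern")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (so 46.85 -> 46.9, unlike banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_by_method(dataset) -> pd.DataFrame:
    """Counts and percentages of no / traditional / modern method use."""
    df = dataset.df if hasattr(dataset, "df") else dataset
    vals = df["method_type"].astype(str)
    unknown = sorted(set(vals) - set(_METHODS))
    if unknown:
        raise ValueError(f"unknown method label(s): {unknown}")
    total = len(vals)
    counts = [int((vals == m).sum()) for m in _METHODS]
    return pd.DataFrame(
        {
            "method": ["No method", "Traditional method", "Modern method"],
            "n": counts,
            "percent": [round_half_up(100.0 * c / total) for c in counts],
        }
    )


@dataclass
class CrossTab:
    """A covariate-by-outcome contingency table with its chi-square test."""

    covariate: str
    counts: pd.DataFrame      # rows: levels; columns: non-user (0), user (1)
    row_percent: pd.DataFrame  # same shape, rows sum to 100 within rounding
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05


def crosstab(dataset, covariate: str, alpha: float = 0.05,
             correction: bool = False) -> CrossTab:
    """Cross-tabulate one categorical covariate against the outcome.

    Pearson chi-square without continuity correction by default.  Levels
    with zero marginal total are dropped from the test with a warning.
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    tab = pd.crosstab(df[covariate].astype(str), df[OUTCOME])
    for col in (0, 1):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[[0, 1]]
    empty = tab.sum(axis=1) == 0
    if empty.any():
        log.warning(
            "dropping zero-count level(s) of %r: %s",
            covariate, list(tab.index[empty]),
        )
        tab = tab[~empty]
    if len(tab) < 2:
        raise ValueError(
            f"covariate {covariate!r} has a single level; test undefined"
        )
    stat, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=correction)
    row_tot = tab.sum(axis=1)
    pct = tab.div(row_tot, axis=0) * 100.0
    pct = pct.map(round_half_up)
    return CrossTab(
        covariate=covariate,
        counts=tab,
        row_percent=pct,
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def screen_covariates(dataset, covariates: list[str], alpha: float = 0.05) -> list[str]:
    """Covariates whose chi-square association has p < alpha, input order kept."""
    return [
        cov for cov in covariates
        if crosstab(dataset, cov, alpha=alpha).p_value < alpha
    ]
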