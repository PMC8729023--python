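"""Prevalence estimates, stratified chi-square association tests, and the
proportion sample-size formula.

Proportions come with Wilson score 95% intervals by default (Wald and
Clopper-Pearson are available); association between a binary outcome and a
K-level factor uses the uncorrected Pearson chi-square on the 2xK table.
No continuity correction and no multiple-testing adjustment are applied.
Reported percentages are rounded half-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceEstimate",
    "AssociationResult",
    "SampleSizeResult",
    "DegenerateTableError",
    "SmallCellWarning",
    "round_half_up",
    "prevalence",
    "chi_square",
    "stratified_prevalence",
    "sample_size",
]

CI_METHODS = {"wilson": "wilson", "wald": "normal", "clopper_pearson": "beta"}


class DegenerateTableError(ValueError):
    """Contingency table has an all-zero row or column."""


class SmallCellWarning(UserWarning):
    """An expected cell count is below 1; the chi-square may be unreliable."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as in conventional reporting
    (Python's built-in ``round`` is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with its 95% confidence interval.

    ``pct(ndigits)`` gives the half-up-rounded percentage for reports.
    """

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    stratum: str = "overall"
    ci_method: str = "wilson"

    def pct(self, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.proportion, ndigits)


@dataclass(frozen=True)
class AssociationResult:
    """Uncorrected Pearson chi-square on a 2xK outcome-by-factor table."""

    table: tuple
    statistic: float
    df: int
    p_value: float
    alpha: float = 0.05
    small_cells: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimum sample size for estimating a proportion.

    ``minimum`` truncates the raw bound (the convention matching a printed
    "minimum of N"); ``conservative`` is the ceiling, which guarantees the
    margin.
    """

    raw: float
    minimum: int
    conservative: int


def prevalence(
    k: int,
    n: int,
    stratum: str = "overall",
    ci_method: str = "wilson",
    confidence: float = 0.95,
) -> PrevalenceEstimate:
    """Point prevalence k/n with a binomial confidence interval."""
    if n <= 0:
        raise ValueError(f"undefined prevalence: denominator {n} must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"numerator {k} outside [0, {n}]")
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(CI_METHODS)}")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method=CI_METHODS[ci_method])
    # boundary cases are exact for score/exact intervals; clear float fuzz
    lo = 0.0 if k == 0 else lo
    hi = 1.0 if k == n else hi
    return PrevalenceEstimate(
        numerator=k,
        denominator=n,
        proportion=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
        stratum=stratum,
        ci_method=ci_method,
    )


def chi_square(table: Sequence[Sequence[int]] | np.ndarray) -> AssociationResult:
    """Pearson chi-square, Sum (O-E)^2/E, with no continuity correction.

    For a 2xK table the degrees of freedom are K-1.  An expected cell below
    1 attaches a :class:`SmallCellWarning` (the test is still computed).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("table has an all-zero row or column")
    stat, p, df, expected = sps.chi2_contingency(arr, correction=False)
    small = bool(np.any(expected < 1))
    if small:
        warnings.warn(
            "expected cell count below 1; chi-square approximation is unreliable",
            SmallCellWarning,
            stacklevel=2,
        )
    return AssociationResult(
        table=tuple(map(tuple, arr.astype(int))),
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        small_cells=small,
    )


@dataclass
class StratifiedResult:
    """Per-stratum prevalence estimates plus the association test."""

    estimates: list = field(default_factory=list)
    association: Optional[AssociationResult] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": e.stratum,
                "k": e.numerator,
                "n": e.denominator,
                "pct": e.pct(1),
                "ci_lo": e.ci_low,
                "ci_hi": e.ci_high,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)


def stratified_prevalence(
    cohort: pd.DataFrame,
    outcome: str,
    stratifier: str,
    levels: Optional[Sequence[str]] = None,
    ci_method: str = "wilson",
) -> StratifiedResult:
    """Prevalence of a boolean ``outcome`` column by the levels of a
    ``stratifier`` column, with the 2xK chi-square association test.

    Records with a missing stratifier value are dropped from this test only
    (never imputed), mirroring per-factor denominators in survey reports.
    """
    df = cohort[[outcome, stratifier]].copy()
    df = df[df[stratifier].notna() & (df[stratifier].astype(str) != "missing")]
    if levels is None:
        levels = sorted(df[stratifier].astype(str).unique())
    result = StratifiedResult()
    cells_pos, cells_neg = [], []
    for lev in levels:
        sub = df[df[stratifier].astype(str) == str(lev)]
        n = len(sub)
        if n == 0:
            raise ValueError(f"stratifier level {lev!r} is empty")
        k = int(sub[outcome].astype(bool).sum())
        result.estimates.append(prevalence(k, n, stratum=str(lev), ci_method=ci_method))
        cells_pos.append(k)
        cells_neg.append(n - k)
    if len(levels) >= 2 and sum(cells_pos) > 0 and sum(cells_neg) > 0:
        result.association = chi_square([cells_pos, cells_neg])
    return result


def sample_size(
    confidence: float = 0.95, margin: float = 0.05, p: float = 0.5
) -> SampleSizeResult:
    """Minimum n to estimate a proportion ``p`` within ``margin`` at the
    given confidence: ``n = z^2 p (1-p) / margin^2``."""
    if not 0 < margin < 1:
        raise ValueError(f"margin must be in (0, 1), got {margin}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    raw = z * z * p * (1 - p) / (margin * margin)
    return SampleSizeResult(raw=raw, minimum=int(raw), conservative=math.ceil(raw))
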