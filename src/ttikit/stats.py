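"""Normality-gated two-group statistics with effect sizes.

The workflow mirrors standard practice for vacuole-morphometry data: each
group is screened with the Shapiro–Wilk test (alpha = 0.05); when both groups
look normal a two-sided Student's t test (pooled variance) is used, otherwise
the Mann–Whitney U test (asymptotic, with tie and continuity corrections).
For significant differences an effect size r is reported — r = |Z|/sqrt(N)
for Mann–Whitney, r = sqrt(t^2/(t^2+df)) for the t test — and classed as
strong (r >= 0.5), medium (0.3 < r < 0.5) or weak. Quartile-stratified
comparisons use pooled cell-length quartile borders and Benjamini–Hochberg
correction across the four tests of one metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "QuartileSplit",
    "shapiro_wilk",
    "compare_groups",
    "classify_effect",
    "bh_adjust",
    "quartile_analysis",
    "pearson_correlation",
    "normal_qq",
    "significance_stars",
]

QUARTILE_NAMES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison.

    ``effect_r`` is present exactly when the (reporting) P-value is below
    alpha; ``p_adjusted`` is set only inside multiplicity-corrected families,
    in which case the effect is gated on the adjusted value.
    """

    test_used: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    normality_p1: float
    normality_p2: float
    effect_r: float | None
    effect_class: str
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.test_used not in ("student_t", "mann_whitney"):
            raise ValueError(f"unknown test {self.test_used!r}")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def reporting_p(self) -> float:
        return self.p_adjusted if self.p_adjusted is not None else self.p_value

    @property
    def stars(self) -> str:
        return significance_stars(self.reporting_p)


@dataclass
class QuartileSplit:
    """Quartile-stratified comparison of one metric between two groups."""

    borders: tuple[float, float, float]
    assignments: dict[str, str]
    per_quartile: dict[str, ComparisonResult | None]


def significance_stars(p: float) -> str:
    """Figure annotation convention: ``**`` for P<0.01, ``*`` for 0.01<=P<0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and P for 3 <= n <= 5000 non-constant samples."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def classify_effect(r: float) -> str:
    """Strength class for effect size r: strong >= 0.5, medium in (0.3, 0.5)."""
    if not 0 <= r <= 1:
        raise ValueError("effect size r must lie in [0, 1]")
    if r >= 0.5:
        return "strong"
    if r > 0.3:
        return "medium"
    return "weak"


def _mann_whitney_r(p: float, n: int) -> float:
    # |Z| recovered from the two-sided asymptotic P, consistent with the
    # tie/continuity-corrected statistic.
    z = abs(sps.norm.ppf(max(p, 1e-300) / 2))
    return min(z / np.sqrt(n), 1.0)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Compare two groups with a normality-gated test and effect size.

    Student's t (pooled variance; Welch behind the ``welch`` flag) is used
    only when BOTH groups pass Shapiro–Wilk at ``alpha``; otherwise the
    asymptotic Mann–Whitney U test. ``effect_r`` and its class are reported
    only when the comparison is significant at ``alpha``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need n >= 3")
    _, p_norm_x = shapiro_wilk(x)
    _, p_norm_y = shapiro_wilk(y)
    n1, n2 = len(x), len(y)
    if p_norm_x >= alpha and p_norm_y >= alpha:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        r = np.sqrt(stat**2 / (stat**2 + df))
        test = "student_t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        r = _mann_whitney_r(p, n1 + n2)
        test = "mann_whitney"
    significant = p < alpha
    return ComparisonResult(
        test_used=test,
        statistic=stat,
        p_value=p,
        n1=n1,
        n2=n2,
        normality_p1=p_norm_x,
        normality_p2=p_norm_y,
        effect_r=float(r) if significant else None,
        effect_class=classify_effect(float(r)) if significant else "not_reported",
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _regate_effect(result: ComparisonResult, p_adj: float, alpha: float) -> ComparisonResult:
    r: float
    if result.test_used == "mann_whitney":
        r = _mann_whitney_r(result.p_value, result.n1 + result.n2)
    else:
        df = result.n1 + result.n2 - 2
        r = float(np.sqrt(result.statistic**2 / (result.statistic**2 + df)))
    significant = p_adj < alpha
    result.p_adjusted = float(p_adj)
    result.effect_r = r if significant else None
    result.effect_class = classify_effect(r) if significant else "not_reported"
    return result


def quartile_analysis(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    metric: str,
    length_column: str = "cell_length_um",
    alpha: float = 0.05,
    quantile_method: str = "linear",
) -> QuartileSplit:
    """Quartile-stratified two-group comparison of one metric.

    Quartile borders are the 25/50/75% quantiles of the POOLED cell lengths
    (linear-interpolation rule by default); cells are binned left-closed
    (length <= border). Each quartile's groups are compared with
    :func:`compare_groups` and the four P-values are BH-adjusted jointly;
    the effect size is re-gated on the adjusted P. Quartiles in which either
    group is empty or too small are marked not-evaluable (``None``), excluded
    from the BH family, and warned about.
    """
    for df, name in ((cells_a, "cells_a"), (cells_b, "cells_b")):
        for col in ("cell_id", length_column, metric):
            if col not in df.columns:
                raise ValueError(f"{name} lacks column {col!r}")
    pooled = np.concatenate(
        [cells_a[length_column].to_numpy(float), cells_b[length_column].to_numpy(float)]
    )
    if len(pooled) < 8:
        raise ValueError("quartile analysis needs pooled n >= 8")
    borders = tuple(np.quantile(pooled, [0.25, 0.5, 0.75], method=quantile_method))

    def bin_of(length: float) -> str:
        for name, border in zip(QUARTILE_NAMES[:3], borders):
            if length <= border:
                return name
        return "Q4"

    assignments: dict[str, str] = {}
    for df in (cells_a, cells_b):
        for row in df.itertuples(index=False):
            assignments[str(getattr(row, "cell_id"))] = bin_of(
                float(getattr(row, length_column))
            )

    per_quartile: dict[str, ComparisonResult | None] = {}
    evaluable: list[str] = []
    for q in QUARTILE_NAMES:
        va = cells_a[cells_a[length_column].map(bin_of) == q][metric].dropna().to_numpy(float)
        vb = cells_b[cells_b[length_column].map(bin_of) == q][metric].dropna().to_numpy(float)
        if len(va) < 3 or len(vb) < 3:
            warnings.warn(
                f"quartile {q}: group sizes {len(va)}/{len(vb)} too small; not evaluable",
                stacklevel=2,
            )
            per_quartile[q] = None
            continue
        per_quartile[q] = compare_groups(va, vb, alpha=alpha)
        evaluable.append(q)
    if evaluable:
        adjusted = bh_adjust([per_quartile[q].p_value for q in evaluable])
        for q, p_adj in zip(evaluable, adjusted):
            per_quartile[q] = _regate_effect(per_quartile[q], p_adj, alpha)
    return QuartileSplit(borders=borders, assignments=assignments, per_quartile=per_quartile)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided P from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def normal_qq(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal QQ pairs for a sample.

    Returns ``(theoretical, sample)`` where the sample order statistics are
    standardized by the sample mean/SD and paired with normal quantiles at
    plotting positions ``(i - 0.5)/n``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError("QQ diagnostics need n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("QQ diagnostics undefined for constant input")
    theoretical = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, (x - x.mean()) / sd
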