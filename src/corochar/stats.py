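"""Statistical battery for cohort comparisons.

Continuous features are compared between patient groups with the two-sided
Mann-Whitney U test (exact enumeration for small samples without ties,
normal approximation with tie correction otherwise), across the three
anatomical zones with one-way ANOVA, and normality is assessed with
Shapiro-Wilk (which drives only the report formatting: mean +/- SD for
normal, median [min; max] otherwise).  Categorical tortuosity incidence is
compared with Pearson's chi-squared test without continuity correction,
paired with the odds ratio OR = (a d)/(b c).  Method agreement uses Pearson
correlation and Bland-Altman (bias +/- 1.96 SD limits of agreement).
Significance is read at p < 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "BlandAltman",
    "odds_ratio",
    "mann_whitney",
    "anova_oneway",
    "shapiro",
    "pearson",
    "bland_altman",
    "is_normal",
]

ALPHA = 0.05


@dataclass
class ContingencyTable2x2:
    """Counts for exposure x outcome: a=exp&out, b=unexp&out, c=exp&no-out, d=unexp&no-out."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def odds_ratio(t: ContingencyTable2x2) -> tuple[float, float]:
    """(OR, chi-squared p-value); OR = (a d)/(b c), chi2 without continuity
    correction.  A zero marginal in b or c makes the OR undefined (inf)."""
    if t.b == 0 or t.c == 0:
        or_val = float("inf")
    else:
        or_val = (t.a * t.d) / (t.b * t.c)
    chi2, p, _, _ = sps.chi2_contingency(t.as_array(), correction=False)
    return float(or_val), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration of the U null distribution when both samples have at
    most 8 observations and no ties; normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 8 and len(y) <= 8
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups) -> tuple[float, float]:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def shapiro(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def is_normal(x, alpha: float = ALPHA) -> bool:
    return shapiro(x)[1] >= alpha


def pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(scores_a, scores_b) -> BlandAltman:
    """Agreement between two paired score lists: differences a - b, bias =
    mean difference, limits of agreement = bias -/+ 1.96 sample SD."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd_diff=sd, n=len(a))
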