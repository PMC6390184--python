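"""Two-sample comparisons on group summaries: Welch's t and Pearson's chi-square.

Welch's unequal-variance t-test is computed directly from summary statistics
(mean, SD, n per group) so that comparisons can be reproduced from published
tables alone:

    t  = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    df = (v1 + v2)^2 / (v1^2/(n1-1) + v2^2/(n2-1)),   v_i = s_i^2 / n_i

The two-tailed p-value uses Student's t at the real-valued
Welch-Satterthwaite df (df is rounded only for display). The 2x2 chi-square
uses the standard Pearson statistic, with the Yates continuity correction
available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["WelchResult", "ChiSquareResult", "welch_t", "welch_from_users",
           "chi_square_2x2"]


@dataclass(frozen=True)
class WelchResult:
    """Welch t statistic, Welch-Satterthwaite df, and two-tailed p."""

    t: float
    df: float
    p_two_tailed: float

    @property
    def df_display(self) -> int:
        """df rounded to the nearest integer, as printed in report tables."""
        return round(self.df)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch's two-tailed two-sample t-test from group summaries.

    Raises ``ValueError`` when both SDs are zero (the statistic is undefined)
    or when either group has fewer than 2 observations.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("degenerate variance: both group SDs are zero")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    se = math.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_two_tailed=min(p, 1.0))


def welch_from_users(group1: Sequence[float], group2: Sequence[float]) -> WelchResult:
    """Welch's test from the raw per-user values of two groups.

    Agrees with :func:`welch_t` applied to the groups' own means/SDs
    (sample SD, n-1 denominator) to floating-point precision.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return welch_t(float(x.mean()), float(x.std(ddof=1)), x.size,
                   float(y.mean()), float(y.std(ddof=1)), y.size)


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Rows are groups, columns the binary outcome. All four margins must be
    positive. ``yates`` applies the continuity correction (off by default).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("degenerate 2x2 table: a margin is zero")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num * num / math.prod(margins)
    p = float(_sps.chi2.sf(chi2, 1))
    return ChiSquareResult(chi2=float(chi2), df=1, p=p)
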