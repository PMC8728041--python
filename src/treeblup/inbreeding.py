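"""Inbreeding-depression regression and dominance/inbreeding correlation.

A trait showing directional dominance declines linearly with the
inbreeding coefficient F; curvature (a significant quadratic term, via a
partial F-test of the nested linear vs quadratic OLS fits) points to
epistatic contributions instead.  The correlation between individual
dominance deviations (from an additive+dominance genomic fit) and F
measures how much of the dominance signal is inbreeding depression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class DepressionResult:
    linear_slope: float
    linear_t: float
    linear_p: float
    quadratic_coef: float
    quadratic_t: float
    quadratic_p: float
    partial_f: float
    partial_f_df: tuple[int, int]
    partial_f_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["linear", "quadratic", "partial_F"],
            "estimate": [self.linear_slope, self.quadratic_coef, self.partial_f],
            "statistic": [self.linear_t, self.quadratic_t, self.partial_f],
            "p": [self.linear_p, self.quadratic_p, self.partial_f_p],
        })


def depression_regression(y, f) -> DepressionResult:
    """OLS of trait on F (linear) and on F, F^2 (quadratic) + partial F-test.

    The partial F-test compares the nested models with df (1, n-3); for
    a single added regressor it equals the square of the quadratic
    coefficient's t statistic.

    With fewer than three distinct F values the quadratic term is
    collinear with the linear one; the quadratic and partial-F entries
    are then NaN (only the linear fit is identifiable).  A linear fit
    that is already numerically exact yields partial F = 0.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(f))
    y, f = y[keep], f[keep]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 paired observations")
    if np.var(f) == 0:
        raise ValueError("no variation in F")
    lin = sm.OLS(y, sm.add_constant(f)).fit()
    xq = sm.add_constant(np.column_stack([f, f ** 2]))
    if np.linalg.matrix_rank(xq) < 3:
        return DepressionResult(
            linear_slope=float(lin.params[1]), linear_t=float(lin.tvalues[1]),
            linear_p=float(lin.pvalues[1]),
            quadratic_coef=np.nan, quadratic_t=np.nan, quadratic_p=np.nan,
            partial_f=np.nan, partial_f_df=(1, n - 3), partial_f_p=np.nan)
    quad = sm.OLS(y, xq).fit()
    # partial F for the single added regressor F^2
    tiny = 1e-12 * max(1.0, n * float(np.var(y)))
    if lin.ssr <= tiny:  # linear model already exact: no possible improvement
        f_stat, p = 0.0, 1.0
    else:
        num = lin.ssr - quad.ssr
        den = quad.ssr / (n - 3)
        f_stat = num / den
        p = float(stats.f.sf(f_stat, 1, n - 3))
    return DepressionResult(
        linear_slope=float(lin.params[1]), linear_t=float(lin.tvalues[1]),
        linear_p=float(lin.pvalues[1]),
        quadratic_coef=float(quad.params[2]), quadratic_t=float(quad.tvalues[2]),
        quadratic_p=float(quad.pvalues[2]),
        partial_f=float(f_stat), partial_f_df=(1, n - 3), partial_f_p=p)


def dominance_F_correlation(dominance_deviations, f) -> tuple[float, float]:
    """Pearson correlation (r, p) between dominance deviations and F."""
    d = np.asarray(dominance_deviations, dtype=float)
    f = np.asarray(f, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(f))
    d, f = d[keep], f[keep]
    if np.var(d) == 0 or np.var(f) == 0:
        raise ValueError("zero variance in dominance deviations or F")
    r = stats.pearsonr(d, f)
    return float(r.statistic), float(r.pvalue)


def significance_flag(p: float) -> str:
    """Star at the p < 0.0001 reporting threshold, else 'NS'."""
    return "***" if p < 1e-4 else "NS"
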