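"""Study-level statistics: equality of proportions, variance ratio, OLS.

These mirror the base-R procedures a forensic analyst would reach for:
``prop.test`` (Yates-corrected two-sample test for equality of proportions
with a continuity-corrected Wald interval), ``var.test`` (F-test for
equality of variances), and ``lm`` with two predictors (accuracy regressed
on the pairwise distance between mixed haplotypes and the minimum distance
from the reference panel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class PropTestResult:
    chi2: float
    p_value: float
    conf_int: tuple[float, float]
    estimate: tuple[float, float]


@dataclass
class FTestResult:
    f: float
    p_value: float
    conf_int: tuple[float, float]
    df: tuple[int, int]


@dataclass
class RegressionResult:
    params: np.ndarray        # intercept, coef_m, coef_p
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    df_resid: int


def prop_test_2sample(
    x1: int, n1: int, x2: int, n2: int, correct: bool = True
) -> PropTestResult:
    """Two-tailed two-sample test for equality of proportions.

    Continuity-corrected as in R's ``prop.test``: the chi-square statistic
    on the pooled 2x2 table uses the Yates |O-E| - 0.5 correction (capped so
    it never exceeds |O-E|), and the 95% CI for p1 - p2 is the unpooled Wald
    interval widened by ``min(0.5 * (1/n1 + 1/n2), |diff|)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("success counts must lie within sample sizes")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    diff = p1 - p2

    # Yates-corrected chi-square on the 2x2 table of successes/failures
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=np.float64)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    dev = np.abs(observed - expected)
    cc = min(0.5, dev.min()) if correct else 0.0
    with np.errstate(invalid="ignore"):
        chi2 = float(np.nansum((dev - cc) ** 2 / expected))
    if pooled in (0.0, 1.0):
        chi2, p_value = 0.0, 1.0
    else:
        p_value = float(sps.chi2.sf(chi2, df=1))

    z = sps.norm.ppf(0.975)
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    width = z * se + (min(0.5 * (1 / n1 + 1 / n2), abs(diff)) if correct else 0.0)
    lo = max(diff - width, -1.0)
    hi = min(diff + width, 1.0)
    return PropTestResult(chi2, p_value, (float(lo), float(hi)), (p1, p2))


def var_f_test(v1: float, df1: int, v2: float, df2: int) -> FTestResult:
    """Two-sided F-test for equality of variances (as R's ``var.test``).

    ``F = v1/v2`` with a two-sided p-value ``2 * min(P(F <= f), P(F >= f))``
    and a 95% CI for the true variance ratio from F quantiles.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("variances must be positive")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    f = v1 / v2
    cdf = sps.f.cdf(f, df1, df2)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    lo = f / sps.f.ppf(0.975, df1, df2)
    hi = f / sps.f.ppf(0.025, df1, df2)
    return FTestResult(float(f), float(p), (float(lo), float(hi)), (df1, df2))


def ols2(
    y: Sequence[float], m: Sequence[float], p: Sequence[float]
) -> RegressionResult:
    """OLS fit of y on two predictors with intercept (``lm(A ~ M + P)``).

    In the panel-composition analysis, A is deconvolution accuracy, M the
    Hamming distance between the mixed haplotypes and P the minimum Hamming
    distance from the mixture to the reference panel.
    """
    y = np.asarray(y, dtype=np.float64)
    design = np.column_stack([np.asarray(m, np.float64), np.asarray(p, np.float64)])
    if y.size < 4:
        raise ValueError("need at least 4 observations for a 3-parameter fit")
    x = sm.add_constant(design)
    if np.linalg.matrix_rank(x) < 3:
        raise ValueError("singular design matrix (collinear predictors)")
    fit = sm.OLS(y, x).fit()
    return RegressionResult(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
    )
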