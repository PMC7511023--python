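"""Method-agreement and group-comparison statistics.

Validation of a counting method against a reference uses four tools:

- ordinary least-squares regression of the test method on the reference,
  reported as slope / intercept / R^2 against the identity line;
- Bland-Altman analysis on *relative* differences, r_i = (a_i - b_i) /
  pairwise mean, with bias = mean(r) and limits of agreement bias +/-
  1.96 sd(r). Pass the method under test first, so that underestimation
  yields a negative bias;
- the intraclass correlation ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — for inter-observer reproducibility;
- Welch's unequal-variance t-test for two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import StatError


@dataclass(frozen=True)
class Regression:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement of relative differences.

    In fractional units unless ``percent`` was requested at computation.
    """

    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class AgreementResult:
    """Bundled agreement of a test method against a reference."""

    regression: Regression
    bland_altman: BlandAltman
    n: int
    icc: float | None = None


def regress_identity(x, y) -> Regression:
    """OLS of y on x with R^2 = squared Pearson correlation.

    Used to compare a method (y) against reference values (x); perfect
    agreement is slope 1, intercept 0, R^2 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise StatError(f"need >= 3 pairs for regression, got {len(x)}")
    if np.ptp(x) == 0:
        raise StatError("x has no variance")
    if np.ptp(y) == 0:
        # constant y: zero slope, no explainable variance
        return Regression(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    fit = stats.linregress(x, y)
    return Regression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def bland_altman(a, b, percent: bool = False) -> BlandAltman:
    """Bland-Altman on relative differences r_i = (a_i - b_i)/mean_i.

    ``a`` is the method under test, ``b`` the reference; bias is then
    negative when the test method underestimates. With percent=True all
    three outputs are scaled by 100.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatError("a and b must be 1-D of equal length")
    if len(a) < 2:
        raise StatError(f"need >= 2 pairs, got {len(a)}")
    means = (a + b) / 2.0
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise StatError(
            f"pair {bad[0]} has non-positive average "
            f"({a[bad[0]]}, {b[bad[0]]}): relative difference undefined"
        )
    r = (a - b) / means
    bias = float(np.mean(r))
    sd = float(np.std(r, ddof=1))
    k = 100.0 if percent else 1.0
    return BlandAltman(
        bias=k * bias,
        loa_low=k * (bias - 1.96 * sd),
        loa_high=k * (bias + 1.96 * sd),
    )


def icc_absolute(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement.

    ``ratings`` is an (n subjects x k raters) complete matrix. From the
    two-way ANOVA mean squares (MSR between subjects, MSC between raters,
    MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise StatError("ratings must be a 2-D subjects x raters matrix")
    if np.isnan(m).any():
        raise StatError("ratings matrix must be complete (no missing cells)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise StatError("need >= 2 subjects and >= 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise StatError("degenerate ratings: zero total variance")
    return float((msr - mse) / denom)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t-test for unequal variances.

    Returns (t, Satterthwaite df, p). Each group needs n >= 2 and
    positive variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.ndim != 1 or len(g) < 2:
            raise StatError(f"group {name} needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise StatError("both groups are constant: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def method_agreement(
    test, reference, percent: bool = False, icc_matrix=None
) -> AgreementResult:
    """Full agreement of a method under test against reference values:
    regression (test on reference), Bland-Altman relative bias, and an
    optional ICC from a subjects x raters matrix."""
    reg = regress_identity(reference, test)
    ba = bland_altman(test, reference, percent=percent)
    icc = icc_absolute(icc_matrix) if icc_matrix is not None else None
    return AgreementResult(
        regression=reg, bland_altman=ba, n=len(np.asarray(test)), icc=icc
    )
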