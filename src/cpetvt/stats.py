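"""Method-comparison statistics: Bland–Altman agreement, paired TOST
equivalence, intraclass correlation, and Student t tests.

These are implemented from their defining formulas (with scipy providing
the t and F distributions) so every quantity in an agreement report is
traceable: bias and limits of agreement as mean ± 1.96·SD of paired
differences (sample SD, n−1); TOST as two one-sided paired t tests against
±bound with the larger one-sided p deciding equivalence; ICC in the
two-way random-effects, absolute-agreement, single-rater form ICC(2,1)
with a 95% CI from the F-distribution method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class TostResult:
    n: int
    df: int
    mean: float
    se: float
    bound: float
    alpha: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    p_equiv: float
    equivalent: bool


@dataclass(frozen=True)
class IccResult:
    n: int
    k: int
    icc: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    paired: bool


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman + TOST + ICC + t-test summary of one method comparison."""

    n: int
    direction: str
    bland_altman: BlandAltman
    tost: TostResult
    icc: IccResult
    t_test: TTestResult

    def to_dict(self) -> dict:
        ba, to, ic, tt = self.bland_altman, self.tost, self.icc, self.t_test
        return {
            "n": self.n,
            "difference_direction": self.direction,
            "bias": ba.bias,
            "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "tost": {
                "bound": to.bound,
                "alpha": to.alpha,
                "df": to.df,
                "t_lower": to.t_lower,
                "t_upper": to.t_upper,
                "p_equiv": to.p_equiv,
                "equivalent": to.equivalent,
            },
            "icc": {"value": ic.icc, "ci95": [ic.ci_low, ic.ci_high]},
            "t_test": {"t": tt.statistic, "df": tt.df, "p": tt.p_value},
        }


#: Classic limits-of-agreement multiplier (normal 97.5th percentile).
LOA_Z = 1.96


def bland_altman(x, y) -> BlandAltman:
    """Bias and 95% limits of agreement of paired differences ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    if len(x) < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(len(d), bias, sd, bias - LOA_Z * sd, bias + LOA_Z * sd)


def tost_paired(diffs, bound: float, alpha: float = 0.05) -> TostResult:
    """Two one-sided paired t tests of mean(diffs) against ±bound.

    Equivalence is declared when both one-sided tests reject, i.e. when
    ``max(p_lower, p_upper) < alpha``.  With zero variance the verdict is
    decided by whether the mean lies strictly inside the bounds.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise ValidationError("need at least 2 differences")
    if bound <= 0:
        raise ValidationError("bound must be positive")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        inside = -bound < m < bound
        t_lo = np.inf if m > -bound else -np.inf
        t_hi = -np.inf if m < bound else np.inf
        p = float(np.finfo(float).tiny) if inside else 1.0
        return TostResult(n, df, m, 0.0, bound, alpha, t_lo, t_hi, p, p, p, inside)
    se = sd / np.sqrt(n)
    t_lower = (m + bound) / se  # H0: mean <= -bound, reject for large t
    t_upper = (m - bound) / se  # H0: mean >= +bound, reject for small t
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    p_equiv = max(p_lower, p_upper)
    return TostResult(
        n, df, m, float(se), bound, alpha, float(t_lower), float(t_upper),
        p_lower, p_upper, p_equiv, p_equiv < alpha,
    )


def _anova_mean_squares(x: np.ndarray):
    """Two-way (subjects x raters) ANOVA mean squares without replication."""
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * float(((rows - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((cols - grand) ** 2).sum()) / (k - 1)
    resid = x - rows[:, None] - cols[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects x k raters) table with no missing cells;
    the coefficient is ``(MSR - MSE) / (MSR + (k-1)·MSE + k·(MSC - MSE)/n)``
    and the CI follows the F-distribution method of McGraw and Wong.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be an (n x k>=2) table")
    n, k = x.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValidationError("missing cells are not supported")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValidationError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-method CI (two-way random, absolute agreement, single measures)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = icc
    return IccResult(n, k, float(icc), float(lower), float(upper))


def t_tests(x, y, paired: bool) -> TTestResult:
    """Student t test: paired, or independent with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need at least 2 values per group")
    if paired:
        if x.shape != y.shape:
            raise ValidationError("paired test needs equal-length sequences")
        d = x - y
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            raise ValidationError("degenerate (zero-variance) differences")
        n = len(d)
        t = float(d.mean()) / (sd / np.sqrt(n))
        df = n - 1
    else:
        n1, n2 = len(x), len(y)
        s1 = float(x.var(ddof=1))
        s2 = float(y.var(ddof=1))
        sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        if sp2 == 0.0:
            raise ValidationError("degenerate (zero-variance) groups")
        t = (float(x.mean()) - float(y.mean())) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), min(p, 1.0), paired)


def agreement_report(
    visual,
    automated,
    bound: float = 25.0,
    alpha: float = 0.05,
    direction: str = "automated-visual",
) -> AgreementReport:
    """Full comparison of automated against visual threshold values.

    ``direction`` controls the sign of the differences; the default takes
    automated minus visual.
    """
    visual = np.asarray(visual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if direction == "automated-visual":
        x, y = automated, visual
    elif direction == "visual-automated":
        x, y = visual, automated
    else:
        raise ValidationError("direction must be 'automated-visual' or 'visual-automated'")
    ba = bland_altman(x, y)
    to = tost_paired(x - y, bound=bound, alpha=alpha)
    ic = icc_absolute_agreement(np.column_stack([visual, automated]))
    tt = t_tests(x, y, paired=True)
    return AgreementReport(len(x), direction, ba, to, ic, tt)
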