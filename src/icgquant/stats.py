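"""Classical statistics used in the pre/post perfusion comparison.

Descriptive summaries with t-based confidence intervals, the pooled
(equal-variance, unpaired) two-sample t-test, one-way unbalanced ANOVA, and
a Kolmogorov-Smirnov normality screen.  The pooled t form is deliberate:
group comparisons in this setting use df = n_a + n_b - 2 and a pooled
standard deviation, not Welch's correction.

The KS screen tests the sample against a normal distribution with the
sample's own mean and standard deviation.  Estimating the parameters from
the data makes the classical p-value conservative (the Lilliefors problem);
a Lilliefors-corrected variant is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    confidence: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "confidence": self.confidence,
        }


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t-test: group A mean minus group B mean."""

    mean_diff: float
    t_stat: float
    df: int
    p_two_sided: float
    ci_low: float
    ci_high: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff, "t_stat": self.t_stat, "df": self.df,
            "p_two_sided": self.p_two_sided,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "alpha": self.alpha,
        }


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat, "df_between": self.df_between,
            "df_within": self.df_within, "p": self.p,
        }


@dataclass(frozen=True)
class NormalityResult:
    ks_stat: float
    p: float
    n: int
    lilliefors: bool

    def to_dict(self) -> dict:
        return {"ks_stat": self.ks_stat, "p": self.p, "n": self.n,
                "lilliefors": self.lilliefors}


def describe(values: Sequence[float], confidence: float = 0.95) -> DescriptiveSummary:
    """Mean, sample SD and two-sided t-based CI for the mean.

    CI = mean +/- t(n-1, 1-alpha/2) * sd / sqrt(n).  Requires n >= 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"describe requires n >= 2, got n = {v.size}")
    n = int(v.size)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    tcrit = float(sps.t.ppf(1 - (1 - confidence) / 2, n - 1))
    half = tcrit * sd / math.sqrt(n)
    return DescriptiveSummary(n, mean, sd, mean - half, mean + half, confidence)


def pooled_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
) -> TTestResult:
    """Equal-variance unpaired two-sample t-test, two-sided.

    The difference is A minus B; its CI uses the pooled standard deviation
    with df = n_a + n_b - 2.  With zero pooled variance and unequal means
    the t statistic is infinite and p = 0 (flagged with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"each group needs n >= 2, got {a.size} and {b.size}"
        )
    na, nb = int(a.size), int(b.size)
    df = na + nb - 2
    diff = float(a.mean() - b.mean())
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, 0.0, df, 1.0, 0.0, 0.0, alpha)
        logger.warning("zero pooled variance with unequal means: t is infinite")
        t_inf = math.inf if diff > 0 else -math.inf
        return TTestResult(diff, t_inf, df, 0.0, diff, diff, alpha)
    res = sps.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return TTestResult(
        mean_diff=diff,
        t_stat=float(res.statistic),
        df=df,
        p_two_sided=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        alpha=alpha,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA; unbalanced group sizes allowed."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise InsufficientDataError(f"ANOVA needs >= 2 groups, got {k}")
    sizes = [g.size for g in gs]
    if any(s < 1 for s in sizes):
        raise InsufficientDataError("every ANOVA group needs at least one value")
    n_total = sum(sizes)
    if n_total <= k:
        raise InsufficientDataError(
            "within-group variance undefined: total N must exceed group count"
        )
    f, p = sps.f_oneway(*gs)
    return AnovaResult(
        f_stat=float(f), df_between=k - 1, df_within=n_total - k, p=float(p)
    )


def ks_normality(values: Sequence[float], lilliefors: bool = False) -> NormalityResult:
    """One-sample KS test against a normal fitted to the sample.

    With ``lilliefors=False`` the p-value is the classical KS p computed as
    if mean and SD were known; because they are estimated it overstates
    normality support.  ``lilliefors=True`` applies the correction (via
    statsmodels).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(f"KS screen requires n >= 4, got {v.size}")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        stat, p = sm_lilliefors(v, dist="norm")
        return NormalityResult(float(stat), float(p), int(v.size), True)
    mean, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("KS screen undefined for a constant sample")
    stat, p = sps.kstest(v, "norm", args=(mean, sd))
    logger.debug(
        "KS normality screen with estimated parameters: classical p is conservative"
    )
    return NormalityResult(float(stat), float(p), int(v.size), False)


def format_p(p: float, digits: int = 3) -> str:
    """Report-style p formatting (3 dp; full precision kept in results)."""
    return f"{p:.{digits}f}"
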