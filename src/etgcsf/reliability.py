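"""Test-retest reliability battery for paired scores.

Implements the agreement statistics used to validate repeated-administration
instruments: two-way absolute-agreement single-measures intraclass
correlation (ICC) with its F-based 95% CI, Bland-Altman bias and limits of
agreement, the coefficient of repeatability (CoR = 1.96 x SD of the
test-retest differences), a paired t test for learning effects, Fisher-Z
comparison of two independent ICCs, and fractional rank precision (FRP) —
the fraction of subject pairs whose ordering is preserved across the two
administrations (0.5 = chance, 1.0 = perfect rank preservation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PairedScores",
    "ICCResult",
    "BlandAltmanResult",
    "icc",
    "bland_altman",
    "coefficient_of_repeatability",
    "paired_t",
    "fisher_z_compare",
    "frp",
    "reliability_report",
]


@dataclass
class PairedScores:
    """Per-subject (test, retest) scores for one metric."""

    subject_ids: Sequence[str]
    test: np.ndarray
    retest: np.ndarray
    label: str = "score"
    units: str = ""

    def __post_init__(self) -> None:
        self.test = np.asarray(self.test, dtype=float)
        self.retest = np.asarray(self.retest, dtype=float)
        if not (len(self.subject_ids) == len(self.test) == len(self.retest)):
            raise ValueError("subject_ids, test and retest must align")
        if not (np.all(np.isfinite(self.test)) and np.all(np.isfinite(self.retest))):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.test)

    @property
    def differences(self) -> np.ndarray:
        return self.test - self.retest


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with 95% CI; model is ICC(A,1) (two-way,
    absolute agreement, single measures)."""

    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(A,1)"


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float


def _anova_mean_squares(pairs: PairedScores) -> Tuple[float, float, float]:
    """Two-way (subjects x sessions) ANOVA mean squares: MSR, MSC, MSE."""
    x = np.column_stack([pairs.test, pairs.retest])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(pairs: PairedScores, alpha: float = 0.05) -> ICCResult:
    """Two-way absolute-agreement single-measures ICC with F-based 95% CI.

    Point estimate from the ANOVA mean squares with k = 2 sessions::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    CI per McGraw & Wong (1996) using a Satterthwaite-type denominator df.
    Zero between-subject variance yields ICC 0 with a degenerate-variance
    warning (agreement is undefined when nothing distinguishes subjects).
    """
    if pairs.n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    k = 2
    n = pairs.n
    msr, msc, mse = _anova_mean_squares(pairs)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-15 * max(mse, 1.0) or denom <= 0:
        warnings.warn("zero between-subject variance; ICC degenerate", RuntimeWarning)
        return ICCResult(icc=0.0, ci_low=float("nan"), ci_high=float("nan"))
    est = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return ICCResult(icc=est, ci_low=est, ci_high=est)
    a = k * est / (n * (1.0 - est)) if est < 1 else float("inf")
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1 else float("inf")
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else float(n - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(icc=float(est), ci_low=float(lower), ci_high=float(upper))


def bland_altman(pairs: PairedScores) -> BlandAltmanResult:
    """Mean difference (bias) and 95% limits of agreement (bias +/- 1.96 SD)."""
    if pairs.n < 3:
        raise ValueError("Bland-Altman requires at least 3 subjects")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def coefficient_of_repeatability(pairs: PairedScores) -> float:
    """CoR = 1.96 x SD of the test-retest differences; lower is more repeatable."""
    if pairs.n < 3:
        raise ValueError("CoR requires at least 3 subjects")
    return float(1.96 * pairs.differences.std(ddof=1))


def paired_t(pairs: PairedScores) -> Tuple[float, int, float]:
    """One-sample t test of the differences against zero (learning effect).

    Returns (t, df, two-sided p).  Zero-variance differences with nonzero
    mean give an infinite t (p = 0); identical columns give t = 0, p = 1.
    """
    if pairs.n < 2:
        raise ValueError("paired t requires at least 2 subjects")
    d = pairs.differences
    df = pairs.n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return (0.0, df, 1.0)
        return (math.copysign(float("inf"), d.mean()), df, 0.0)
    res = stats.ttest_1samp(d, 0.0)
    return (float(res.statistic), df, float(res.pvalue))


def fisher_z_compare(icc_a: float, n_a: int, icc_b: float, n_b: int) -> Tuple[float, float]:
    """Compare two independent ICCs via the Fisher Z transformation.

    ``z = (atanh(icc_a) - atanh(icc_b)) / sqrt(1/(n_a-3) + 1/(n_b-3))``
    with a two-sided normal p value.  Operand order is the caller's choice;
    swapping operands negates z.
    """
    for icc_v, n_v in ((icc_a, n_a), (icc_b, n_b)):
        if abs(icc_v) >= 1:
            raise ValueError("|ICC| must be < 1 for the Fisher transform")
        if n_v <= 3:
            raise ValueError("Fisher-Z comparison requires n > 3 in both groups")
    z = (math.atanh(icc_a) - math.atanh(icc_b)) / math.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return (float(z), float(p))


def frp(pairs: PairedScores) -> float:
    """Fractional rank precision: pairwise rank concordance across sessions.

    Over all subject pairs, the fraction whose ordering agrees between test
    and retest; a tie in either session contributes 0.5.  Equals 1.0 for
    identical orderings, 0.0 for a full reversal, and 0.5 in expectation for
    independent scores.
    """
    if pairs.n < 2:
        raise ValueError("FRP requires at least 2 subjects")
    t = pairs.test
    r = pairs.retest
    iu = np.triu_indices(pairs.n, k=1)
    s1 = np.sign(t[:, None] - t[None, :])[iu]
    s2 = np.sign(r[:, None] - r[None, :])[iu]
    score = np.where((s1 == 0) | (s2 == 0), 0.5, (s1 == s2).astype(float))
    return float(score.mean())


def reliability_report(pairs: PairedScores) -> dict:
    """All battery statistics for one metric, as a JSON-ready dict."""
    res = icc(pairs)
    ba = bland_altman(pairs)
    t, df, p = paired_t(pairs)
    return {
        "metric": pairs.label,
        "units": pairs.units,
        "n": pairs.n,
        "icc": res.icc,
        "icc_ci": [res.ci_low, res.ci_high],
        "icc_model": res.model,
        "bias": ba.bias,
        "loa": [ba.loa_low, ba.loa_high],
        "cor": coefficient_of_repeatability(pairs),
        "t": t,
        "df": df,
        "p": p,
        "frp": frp(pairs),
    }
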