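"""Method-agreement statistics: Bland-Altman, ICC, normality-gated paired tests.

These mirror the standard toolbox for comparing a new quantitative imaging
method against a reference: Bland-Altman bias and 1.96-SD limits of agreement,
the single-measure two-way mixed-model intraclass correlation coefficient for
absolute agreement (ICC(A,1)) with the conventional classification bands, a
paired comparison that picks Student's paired t or the Wilcoxon signed-rank
test from a Shapiro-Wilk normality check of the differences, and relative
differences between repeated observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSample",
    "BlandAltmanResult",
    "ICCResult",
    "PairedTestResult",
    "bland_altman",
    "icc_absolute_agreement",
    "classify_icc",
    "paired_compare",
    "relative_difference",
]


@dataclass
class PairedSample:
    """Per-subject values from two methods (equal length, n >= 3)."""

    method_a: np.ndarray
    method_b: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise ValueError("paired samples must be 1D arrays of equal length")
        if self.method_a.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise ValueError("paired samples must be finite")


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class ICCResult:
    value: float
    classification: str


@dataclass
class PairedTestResult:
    test: str  # "paired t-test" | "wilcoxon" | "no difference"
    p_value: float
    significant: bool
    shapiro_p: float


def bland_altman(sample: PairedSample) -> BlandAltmanResult:
    """Bias = mean(a - b); limits of agreement = bias +- 1.96 * SD(a - b)."""
    d = sample.method_a - sample.method_b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd
    )


def icc_absolute_agreement(ratings: np.ndarray) -> ICCResult:
    """Single-measure two-way mixed-model ICC for absolute agreement.

    ``ratings`` is (n subjects x k raters), no missing cells.  From the
    two-way ANOVA mean squares (MSR subjects, MSC raters, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must have no missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        logger.info("zero total variance: ICC defined as 1.0")
        return ICCResult(value=1.0, classification=classify_icc(1.0))

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    value = float((msr - mse) / denom) if denom != 0 else 1.0
    return ICCResult(value=value, classification=classify_icc(value))


def classify_icc(value: float) -> str:
    """Conventional bands: <0.40 poor, [0.40,0.60) moderate, [0.60,0.80] good, >0.80 excellent."""
    if value > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "excellent"


def paired_compare(sample: PairedSample, alpha: float = 0.05) -> PairedTestResult:
    """Paired t-test if the differences pass Shapiro-Wilk (p >= 0.05), else Wilcoxon."""
    d = sample.method_a - sample.method_b
    if np.ptp(d) == 0:
        return PairedTestResult(test="no difference", p_value=1.0, significant=False,
                                shapiro_p=1.0)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= 0.05:
        res = stats.ttest_rel(sample.method_a, sample.method_b)
        test = "paired t-test"
    else:
        res = stats.wilcoxon(sample.method_a, sample.method_b)
        test = "wilcoxon"
    p = float(res.pvalue)
    return PairedTestResult(test=test, p_value=p, significant=p < alpha, shapiro_p=shapiro_p)


def relative_difference(first: np.ndarray, second: np.ndarray) -> float:
    """Mean difference of repeated observations as % of the initial observation."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    m = first.mean()
    if m == 0:
        raise ValueError("mean of the initial observation is zero")
    return float(100.0 * (second - first).mean() / m)
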