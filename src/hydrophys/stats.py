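"""Two-sample comparison workflow.

Shapiro-Wilk normality gate on each group, then Welch's t-test when both
groups look normal, otherwise a two-sided Wilcoxon rank-sum (Mann-Whitney U).
A classical variance-ratio F test is reported alongside but never changes
the test choice (Welch's t is already variance-robust). Everything is
reported as mean +/- 1 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = ["ComparisonResult", "compare_groups", "summary_row", "variance_ratio_test"]


@dataclass(frozen=True)
class ComparisonResult:
    trait: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    variance_p: float
    test_used: str  # "welch" | "wilcoxon"
    statistic: float
    p_value: float
    alpha: float

    def __post_init__(self) -> None:
        if self.test_used not in ("welch", "wilcoxon"):
            raise ValidationError(f"unknown test_used {self.test_used!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")


def summary_row(sample) -> tuple[float, Optional[float], int]:
    """(mean, sample SD with n-1 denominator, n); SD is None for a singleton."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValidationError("empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else None
    return float(np.mean(x)), sd, int(x.size)


def variance_ratio_test(a, b) -> tuple[float, float]:
    """Two-sided F test of equal variances (R's var.test).

    Returns (F, p) with F = var(a)/var(b), df (n_a - 1, n_b - 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 or va == 0:
        return float("inf") if vb == 0 else 0.0, 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    return float(f), float(2.0 * min(cdf, 1.0 - cdf))


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    trait: str = "",
) -> ComparisonResult:
    """Compare two samples with the normality-gated Welch/Wilcoxon workflow.

    The gate is conservative: either group failing Shapiro-Wilk at ``alpha``
    sends the comparison to the rank-sum test. Requires n >= 3 per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")

    sw_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    sw_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    fstat, var_p = variance_ratio_test(a, b)

    if sw_a > alpha and sw_b > alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        test_used = "welch"
    else:
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size < pooled.size:
            warnings.warn("ties present; Wilcoxon p-value is approximate")
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "wilcoxon"

    mean_a, sd_a, n_a = summary_row(a)
    mean_b, sd_b, n_b = summary_row(b)
    return ComparisonResult(
        trait=trait,
        label_a=labels[0],
        label_b=labels[1],
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        sd_a=sd_a if sd_a is not None else float("nan"),
        mean_b=mean_b,
        sd_b=sd_b if sd_b is not None else float("nan"),
        shapiro_p_a=sw_a,
        shapiro_p_b=sw_b,
        variance_p=var_p,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
    )
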