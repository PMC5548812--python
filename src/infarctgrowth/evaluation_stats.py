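"""Evaluation statistics for prediction methods.

The similarity statistic between a prediction vector and the measured
volumes is the Pearson product-moment correlation at lag zero (written CRR
here).  Distribution shape is summarized by *population* skewness and
*non-excess* kurtosis — uncorrected central moments, normal kurtosis = 3 —
and each method is compared with the ground truth by a two-tailed paired
t-test (Wilcoxon signed-rank available as an option).  These conventions,
rather than the bias-corrected ones, are what clinical packages such as
SPSS/MATLAB print for descriptive moment statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

__all__ = [
    "MethodEvaluation",
    "PairedTestResult",
    "crr",
    "population_skewness",
    "population_kurtosis",
    "paired_test",
    "summarize_method",
    "compare_groups",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _checked(x, min_len: int = 3, name: str = "input") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise UndefinedStatisticError(
            f"{name} needs at least {min_len} values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise UndefinedStatisticError(f"{name} contains non-finite values")
    return x


def crr(x, y) -> float:
    """Pearson correlation at lag zero between two equal-length vectors."""
    x = _checked(x, name="x")
    y = _checked(y, name="y")
    if x.size != y.size:
        raise UndefinedStatisticError("vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def population_skewness(x) -> float:
    """m3 / m2^(3/2) with uncorrected population central moments."""
    x = _checked(x)
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("skewness undefined for constant input")
    return float(sps.skew(x, bias=True))


def population_kurtosis(x) -> float:
    """m4 / m2^2, non-excess (a normal sample tends to 3)."""
    x = _checked(x)
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("kurtosis undefined for constant input")
    return float(sps.kurtosis(x, fisher=False, bias=True))


class PairedTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool  # True when the paired differences had zero variance


def paired_test(predicted, truth, kind: str = "t") -> PairedTestResult:
    """Two-tailed paired comparison of predictions against measurements.

    kind='t' is a paired t-test on the differences; kind='wilcoxon' the
    signed-rank test.  Zero-variance differences (including identical
    vectors) return p = 1 with the degenerate flag set.
    """
    predicted = _checked(predicted, name="predicted")
    truth = _checked(truth, name="truth")
    if predicted.size != truth.size:
        raise UndefinedStatisticError("vectors must have equal length")
    diffs = predicted - truth
    if np.ptp(diffs) == 0:
        return PairedTestResult(0.0, 1.0, True)
    if kind == "t":
        res = sps.ttest_rel(predicted, truth)
    elif kind == "wilcoxon":
        res = sps.wilcoxon(predicted, truth)
    else:
        raise ValueError(f"unknown paired test kind {kind!r}")
    return PairedTestResult(float(res.statistic), float(res.pvalue), False)


@dataclass(frozen=True)
class MethodEvaluation:
    """Summary-statistic block for one prediction method vs the ground truth."""

    method: str
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator
    crr: float
    skewness: float
    kurtosis: float
    p_value: float
    squared_errors: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.crr <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")
        if self.kurtosis < 1.0 - 1e-12:  # m4 >= m2^2 for any sample
            raise ValueError("population kurtosis below its lower bound of 1")

    @property
    def mse(self) -> float:
        return float(np.mean(self.squared_errors))


def summarize_method(
    method: str, predicted, truth, test_kind: str = "t"
) -> MethodEvaluation:
    """Assemble the full statistic block for one method."""
    predicted = _checked(predicted, name="predicted")
    truth = _checked(truth, name="truth")
    if predicted.size != truth.size:
        raise UndefinedStatisticError("vectors must have equal length")
    return MethodEvaluation(
        method=method,
        n=int(predicted.size),
        mean=float(np.mean(predicted)),
        sd=float(np.std(predicted, ddof=1)),
        crr=crr(predicted, truth),
        skewness=population_skewness(predicted),
        kurtosis=population_kurtosis(predicted),
        p_value=paired_test(predicted, truth, kind=test_kind).pvalue,
        squared_errors=tuple((predicted - truth) ** 2),
    )


def compare_groups(a, b=None, kind: str = "t") -> float:
    """Two-group comparison p-value for train-vs-test style contrasts.

    kind='t': Welch-free independent two-sample t-test (equal variances,
    matching the classic clinical default); kind='mannwhitney': two-sided
    Mann-Whitney U; kind='chi2': ``a`` is a 2x2 count table (b ignored),
    Pearson chi-square without continuity correction.
    """
    if kind == "chi2":
        table = np.asarray(a, dtype=float)
        if table.shape != (2, 2):
            raise UndefinedStatisticError("chi2 comparison needs a 2x2 table")
        res = sps.chi2_contingency(table, correction=False)
        return float(res[1])
    a = _checked(a, name="a")
    b = _checked(b, name="b")
    if kind == "t":
        return float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    if kind == "mannwhitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown comparison kind {kind!r}")
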