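"""Contingency-table and rank statistics with pinned conventions.

The pipeline attaches a small, fixed set of tests to its printed tables and
lesion distributions.  Conventions that differ between software packages are
made explicit here:

* Fisher's exact two-sided p is the sum of the point probabilities of all
  tables with the same margins that are no more probable than the observed
  one (the "minimum-likelihood" convention, not tail doubling).
* The chi-squared test exposes Yates continuity correction as a flag, with
  no correction as the default.
* The MAD is the raw median of absolute deviations from the median, with no
  normal-consistency scaling (no 1.4826 factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "chi_squared_2x2",
    "mann_whitney_u",
    "median_abs_deviation",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: row = group, column = event / non-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("grand total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @classmethod
    def from_array(cls, t: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = t
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    correction: bool = False
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "correction": self.correction,
        }


def fisher_exact_two_sided(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    A table with an empty margin carries no information about association;
    p = 1 is returned with a warning.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher_exact")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher_exact")


def chi_squared_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-squared test (df = 1) with optional Yates correction.

    Warns when any expected cell count is below 5, where the chi-squared
    approximation is unreliable.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined for a table with a zero margin")
    res = sps.chi2_contingency(arr, correction=continuity_correction)
    if (res.expected_freq < 5).any():
        warnings.warn(
            "expected count < 5 in 2x2 table; chi-squared approximation is poor",
            stacklevel=2,
        )
    return TestResult(
        float(res.statistic), float(res.pvalue), "chi_squared", continuity_correction
    )


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    continuity_correction: bool = True,
) -> TestResult:
    """Rank-sum Mann-Whitney U test.

    Exact enumeration is used for small samples without ties (both n <= 20);
    otherwise the tie-corrected normal approximation, with optional
    continuity correction.  Samples that are completely tied across groups
    carry no rank information: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(x.size * y.size / 2.0, 1.0, "mann_whitney_u")
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(x.size, y.size) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method,
        use_continuity=continuity_correction,
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), "mann_whitney_u",
        extra={"approximation": method},
    )


def median_abs_deviation(values: Sequence[float]) -> float:
    """Median of absolute deviations from the median, unscaled."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("MAD of an empty sample is undefined")
    return float(np.median(np.abs(v - np.median(v))))
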