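"""Validation statistics: pooled two-sample t-test and simple regression.

The pooled (Student) t-test is provided both from raw samples and from
printed group summaries (mean, standard error of the mean, n) — the form
needed to recompute published group comparisons from figure legends.
Standard errors are converted back to standard deviations via
SD = SE * sqrt(n) before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """A group's printed summary: mean +/- SE with sample size."""

    label: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.se <= 0:
            raise ValueError(f"group {self.label!r}: se must be > 0")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(label, float(values.mean()),
                   float(values.std(ddof=1) / np.sqrt(len(values))), len(values))


def pooled_t_from_summaries(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t-test from group summaries.

    Returns (t, df, p). t is positive when group a's mean is larger;
    swapping the groups negates t and preserves p.
    """
    var_a, var_b = a.sd ** 2, b.sd ** 2
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * var_a + (b.n - 1) * var_b) / df
    t = (a.mean - b.mean) / np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def pooled_t_test(values_a, values_b, labels: tuple[str, str] = ("a", "b")
                  ) -> tuple[float, int, float]:
    """Pooled t-test from raw values (equivalent to the summary form)."""
    a = GroupSummary.from_values(labels[0], values_a)
    b = GroupSummary.from_values(labels[1], values_b)
    return pooled_t_from_summaries(a, b)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def simple_regression(x, y) -> RegressionFit:
    """OLS of y on x with R^2 and the F-test p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    return RegressionFit(float(res.slope), float(res.intercept), r2,
                         float(res.pvalue), len(x))
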