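"""Inferential statistics applied to pipeline outputs.

Implements the small set of tests the analysis relies on: Benjamini-Hochberg
step-up adjustment, the two-sample z test for proportions, the exact binomial
test (used to benchmark decoding accuracy against the no-information rate),
Fisher's z comparison of two Pearson correlations, and the two-sample
Kolmogorov-Smirnov test.  Everything returns a :class:`TestResult` so results
serialize uniformly into JSON reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "two_proportion_z",
    "exact_binomial",
    "fisher_z_compare",
    "ks_two_sample",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    n: tuple[int, ...]
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "n": list(self.n),
            "method": self.method,
            **self.extra,
        }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1, returned in the
    input order.  Monotone in the ranks and never below the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest rank downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int, pooled: bool = True
) -> TestResult:
    """Two-sample z test comparing proportions k1/n1 vs k2/n2.

    Default pooled standard error sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    proportion p = (k1+k2)/(n1+n2); two-sided normal p-value.  The pooled
    statistic satisfies z**2 == Pearson chi-squared of the 2x2 table.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not (0 <= k <= n):
            raise ValueError("count must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    if pooled:
        p = (k1 + k2) / (n1 + n2)
        se = math.sqrt(p * (1.0 - p) * (1.0 / n1 + 1.0 / n2))
    else:
        se = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    if se == 0.0:
        z = 0.0
    else:
        z = (p1 - p2) / se
    p_value = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        statistic=z,
        p_value=min(p_value, 1.0),
        sidedness="two-sided",
        n=(n1, n2),
        method="two-proportion z" + (" (pooled)" if pooled else " (unpooled)"),
        extra={"p1": p1, "p2": p2},
    )


def exact_binomial(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> TestResult:
    """Exact binomial test of k successes in n trials against p0.

    Two-sided p sums all outcomes with point mass <= mass(k) (the standard
    exact convention).
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    res = sps.binomtest(k, n, p0, alternative=alternative)
    return TestResult(
        statistic=float(k),
        p_value=float(res.pvalue),
        sidedness=alternative,
        n=(n,),
        method="exact binomial",
        extra={"p0": p0, "estimate": k / n if n else float("nan")},
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two independent Pearson correlations via Fisher's z transform.

    statistic = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),
    two-sided normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("each sample needs n >= 4")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return TestResult(
        statistic=z,
        p_value=min(2.0 * sps.norm.sf(abs(z)), 1.0),
        sidedness="two-sided",
        n=(n1, n2),
        method="Fisher z correlation comparison",
    )


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sidedness="two-sided",
        n=(a.size, b.size),
        method="two-sample Kolmogorov-Smirnov",
    )
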