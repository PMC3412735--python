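"""Small-sample statistics for paired transit studies.

Group results are reported as mean ± sample SD; liquid-vs-solid contrasts
within the same animals use the paired Student t-test (two-sided); the
kill-and-measure validation uses the Pearson correlation; same-animal
repeatability across sessions is summarized as a coefficient of
variation.

The t-distribution tail probability is computed here from first
principles via the regularized incomplete beta function

    p = I_x(df/2, 1/2),    x = df / (df + t^2)

evaluated with the standard continued-fraction expansion (modified Lentz
iteration), so the p-values do not depend on any statistics runtime and
an external implementation can serve as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupSummary",
    "PairedTestResult",
    "summarize",
    "paired_t_test",
    "pearson_correlation",
    "repeatability_cv",
    "student_t_two_sided_p",
    "regularized_incomplete_beta",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (n-1 denominator) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n})"


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test outcome: t statistic, degrees of freedom, two-sided p."""

    t_statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")

    @property
    def significant(self) -> bool:
        """Conventional alpha = 0.05 verdict."""
        return self.p_value < 0.05


def summarize(values) -> GroupSummary:
    """Mean and sample standard deviation of a group of measurements."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to summarize")
    mean = float(np.mean(x))
    sd = float(np.sqrt(np.sum((x - mean) ** 2) / (x.size - 1)))
    return GroupSummary(n=int(x.size), mean=mean, sd=sd)


def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, 300):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            return h
    raise RuntimeError("incomplete beta continued fraction did not converge")


def regularized_incomplete_beta(a: float, b: float, x: float) -> float:
    """I_x(a, b) for a, b > 0 and x in [0, 1]."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must be in [0, 1]")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def student_t_two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t with ``df`` degrees of
    freedom: P(|T| >= |t|) = I_{df/(df+t^2)}(df/2, 1/2)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    x = df / (df + t * t)
    return regularized_incomplete_beta(df / 2.0, 0.5, x)


def paired_t_test(a, b) -> PairedTestResult:
    """Paired Student t-test on matched measurements ``a`` and ``b``.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b, df = n - 1, two-sided
    p-value.  Identically-constant differences (sd = 0) carry no paired
    information and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = summarize(d).sd
    if sd == 0:
        raise ValueError("degenerate paired differences (sd = 0)")
    n = d.size
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    return PairedTestResult(t_statistic=t, df=n - 1,
                            p_value=student_t_two_sided_p(t, n - 1))


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.sum(dx * dy) / math.sqrt(sxx * syy))
    return max(-1.0, min(1.0, r))


def repeatability_cv(repeats) -> float:
    """Coefficient of variation (percent) across repeated sessions."""
    s = summarize(repeats)
    if s.mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * s.sd / s.mean
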