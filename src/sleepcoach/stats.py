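"""Study statistics implemented from their defining formulas.

Covers exactly the inferential toolkit a feasibility report of this kind
uses: the Pearson chi-square on an r x c contingency table (no continuity
correction; the uncorrected statistic is the dialect that reproduces the
published group comparisons), the pooled-variance two-sample Student t from
summary statistics (df = n1 + n2 - 2), the paired t on difference scores,
the Pearson correlation with its t-based p-value, and conditional funnel
percentages.  Test statistics are computed here from first principles;
scipy supplies only the distribution tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square",
    "two_sample_t_pooled",
    "paired_t",
    "pearson_r",
    "funnel_percentages",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative counts with optional labels."""

    counts: Tuple[Tuple[int, ...], ...]
    row_labels: Optional[Tuple[str, ...]] = None
    col_labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (arr < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if arr.sum() <= 0:
            raise ValueError("contingency table grand total must be positive")
        object.__setattr__(
            self, "counts", tuple(tuple(int(v) for v in row) for row in arr)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    estimate: Optional[float] = None  # e.g. the correlation coefficient


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square of independence, no continuity correction.

    statistic = sum (O - E)^2 / E with E from the row/column margins,
    df = (r - 1)(c - 1), upper-tail p.  Raises ``ValueError`` when a
    margin is all zero (expected count of zero).
    """
    if isinstance(table, (list, tuple, np.ndarray)):
        table = ContingencyTable(tuple(tuple(r) for r in np.asarray(table)))
    obs = table.array
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margins: a row or column sums to zero")
    expected = row @ col / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=float(df), p_value=p, method="chi_square")


def two_sample_t_pooled(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Two-tailed pooled-variance Student t from group summaries.

    df = n1 + n2 - 2.  Raises ``ValueError`` on zero pooled variance with
    unequal means (undefined statistic).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group requires n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 != m2:
            raise ValueError("zero pooled variance with unequal means")
        return TestResult(0.0, float(df), 1.0, "two_sample_t_pooled")
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p, method="two_sample_t_pooled")


def paired_t(differences: Sequence[float]) -> TestResult:
    """Two-tailed paired t on difference scores: t = mean(d) sqrt(n) / sd(d),
    df = n - 1.  Constant differences are rejected (zero sd)."""
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t requires at least 2 differences")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("constant differences: sd of differences is zero")
    t = float(d.mean() * math.sqrt(n) / sd)
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p, method="paired_t")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with p from t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("correlation requires at least 3 pairs")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float((xc**2).sum())
    sy = float((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float((xc * yc).sum() / math.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p, method="pearson_r", estimate=r)


def funnel_percentages(counts: Sequence[int]) -> List[Dict[str, float]]:
    """Conditional and overall percentages along a monotone funnel.

    For each stage after the first: percent of the *previous* stage and of
    the first stage, both rounded to 1 decimal.  Raises ``ValueError`` when
    the counts increase along the funnel or a conditional denominator is
    zero while its numerator is not.
    """
    counts = [int(c) for c in counts]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("funnel counts must be monotone non-increasing")
    out: List[Dict[str, float]] = [
        {"count": counts[0], "pct_of_previous": 100.0, "pct_of_first": 100.0}
    ]
    first = counts[0]
    for prev, cur in zip(counts, counts[1:]):
        if prev == 0:
            if cur != 0:
                raise ValueError("non-zero stage after an empty upstream stage")
            cond = 0.0
        else:
            cond = round(100.0 * cur / prev, 1)
        overall = 0.0 if first == 0 else round(100.0 * cur / first, 1)
        out.append({"count": cur, "pct_of_previous": cond, "pct_of_first": overall})
    return out


def format_p(p: float) -> str:
    """Report-layer p formatting ("<.001" below a thousandth)."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.00"
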