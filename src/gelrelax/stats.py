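"""Cohort aggregation and the study's summary statistics.

Replicate-level results are aggregated to group summaries as mean with
sample standard deviation (n-1 denominator) and standard error of the mean;
group differences use a one-tailed two-sample t test (pooled-variance
Student's by default, Welch selectable). Collapse-flagged samples are
excluded from viscoelastic summaries and book-kept in the exclusion list.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import EmptyGroupError, GelRelaxError


@dataclasses.dataclass
class CohortSummary:
    group: str
    n: int
    mean: float
    sd: float  # nan + flag when n == 1
    sem: float
    dispersion_defined: bool = True
    excluded: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class TTestResult:
    t: float
    df: float
    p: float
    direction: str
    flag: str | None = None


def summarize(
    values: Sequence[float],
    by: Sequence[str] | None = None,
    excluded: Sequence[str] | None = None,
) -> list[CohortSummary]:
    """Per-group mean, sample SD and SEM (= SD/sqrt(n)).

    A single-value group keeps its mean but reports SD/SEM as undefined
    (NaN with ``dispersion_defined=False``).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyGroupError("no values to summarize")
    if by is None:
        by = ["all"] * values.size
    if values.size != len(by):
        raise GelRelaxError("values and grouping labels differ in length")
    out = []
    for group in dict.fromkeys(by):  # preserve first-seen order
        v = values[np.asarray([g == group for g in by])]
        if v.size == 0:
            raise EmptyGroupError(f"group {group!r} is empty")
        if v.size == 1:
            out.append(
                CohortSummary(group, 1, float(v[0]), math.nan, math.nan,
                              dispersion_defined=False, excluded=list(excluded or []))
            )
        else:
            sd = float(np.std(v, ddof=1))
            out.append(
                CohortSummary(group, int(v.size), float(v.mean()), sd,
                              sd / math.sqrt(v.size), excluded=list(excluded or []))
            )
    return out


def t_test_one_tailed(
    a: Sequence[float],
    b: Sequence[float],
    direction: str,
    equal_var: bool = True,
) -> TTestResult:
    """One-tailed two-sample t test of mean(a) vs mean(b).

    ``direction="greater"`` tests the alternative mean(a) > mean(b),
    ``"less"`` the opposite. Pooled-variance Student's t by default;
    ``equal_var=False`` gives the Welch variant. The direction of the
    alternative must be stated explicitly by the caller.
    """
    if direction not in ("greater", "less"):
        raise GelRelaxError("direction must be 'greater' or 'less'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GelRelaxError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 0.5, direction,
                               flag="zero variance in both groups")
        p = 0.0 if ((a.mean() > b.mean()) == (direction == "greater")) else 1.0
        return TTestResult(math.inf if p == 0 else -math.inf,
                           float(a.size + b.size - 2), p, direction,
                           flag="zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=direction)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), direction)
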