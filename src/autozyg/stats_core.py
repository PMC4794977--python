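"""Elementary statistics used throughout the pipeline.

2x2 chi-square (no continuity correction), one-sided Fisher's exact test,
Woolf odds-ratio confidence intervals, Benjamini-Hochberg FDR (with support
for an external total test count), Student's t-tests and Pearson correlation.

The chi-square intentionally applies **no** Yates correction: the printed
statistics the pipeline reproduces (e.g. homozygote/heterozygote tables,
ROH carrier tables) are plain Pearson chi-squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


class UndefinedTestError(ValueError):
    """A test statistic is undefined for the given input (e.g. zero marginal)."""


class ContingencyTable2x2(NamedTuple):
    """Cell counts ``a, b / c, d``: rows case/control, columns exposed/unexposed."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> "ContingencyTable2x2":
        if min(self) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if sum(self) == 0:
            raise ValueError("2x2 table total must be > 0")
        return self


@dataclass
class TestResult:
    """Generic hypothesis-test result.

    ``estimate`` holds the effect measure where one applies (odds ratio,
    mean difference or correlation); ``flag`` marks degenerate or
    untestable inputs.
    """

    statistic: float
    p_value: float
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    df: float | None = None
    flag: str | None = None


def _as_table(table) -> ContingencyTable2x2:
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    return table.validate()


def chi2_2x2(table) -> TestResult:
    """Pearson chi-square for a 2x2 table, 1 df, no continuity correction.

    statistic = n (ad - bc)^2 / (r1 r2 c1 c2).  Raises
    :class:`UndefinedTestError` when any marginal is zero.
    """
    a, b, c, d = _as_table(table)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedTestError("zero marginal: chi-square undefined")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p_value=p, df=1)


def _sample_or(a, b, c, d) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return a * d / (b * c)


def fisher_exact_one_sided(table, direction: str = "greater") -> TestResult:
    """One-sided Fisher's exact test (hypergeometric tail).

    ``direction='greater'`` tests for enrichment of the exposed column in the
    first row.  The reported estimate is the sample odds ratio ``ad/bc``
    (not the conditional MLE).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a, b, c, d = _as_table(table)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=direction)
    return TestResult(statistic=float(a), p_value=float(p),
                      estimate=_sample_or(a, b, c, d))


def odds_ratio_woolf(table, level: float = 0.95) -> TestResult:
    """Sample odds ratio with a Woolf (log-scale Wald) confidence interval.

    With any zero cell, 0.5 is added to every cell (Haldane-Anscombe) for
    both the estimate and the interval; the result is flagged.
    """
    a, b, c, d = _as_table(table)
    flag = None
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        flag = "continuity_adjusted"
    or_ = a * d / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    chi = chi2_2x2(ContingencyTable2x2(*(int(round(x)) for x in (a, b, c, d)))) \
        if flag is None else None
    p = chi.p_value if chi is not None else float("nan")
    return TestResult(statistic=float(np.log(or_) / se), p_value=p,
                      estimate=float(or_), ci_low=float(lo), ci_high=float(hi),
                      flag=flag)


def bh_fdr(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m_total`` is the total number of tests performed, which may exceed
    ``len(p_values)`` when q-values are computed for a reported top list
    (q_i = min_{j>=i} p_(j) * m_total / j, capped at 1; returned in the
    input order).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bonferroni(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (the naive multiple-testing alternative)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError("m_total smaller than number of p-values")
    return np.minimum(p * m, 1.0)


def two_sample_t(x, y, tails: int = 2, variance_mode: str = "pooled") -> TestResult:
    """Student's two-sample t-test, cases (``x``) versus controls (``y``).

    ``variance_mode='pooled'`` is the classical equal-variance Student test;
    ``'welch'`` uses the Welch-Satterthwaite correction.  With ``tails=1``
    the alternative is mean(x) > mean(y).  A zero pooled variance with equal
    means yields p = 1, flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample must have size >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError("variance_mode must be 'pooled' or 'welch'")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(statistic=0.0, p_value=1.0,
                              estimate=0.0, flag="degenerate")
    alternative = "greater" if tails == 1 else "two-sided"
    res = sps.ttest_ind(x, y, equal_var=(variance_mode == "pooled"),
                        alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      estimate=float(np.mean(x) - np.mean(y)),
                      df=float(res.df))


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedTestError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1e-300, 1 - r * r))
    return TestResult(statistic=float(t), p_value=float(res.pvalue),
                      estimate=r, df=float(n - 2))
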