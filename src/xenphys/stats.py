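"""Group summaries and the cohort-comparison statistical tests.

The testing policy mirrors common practice in small-cohort physiology:
every metric is first gated through Shapiro-Wilk normality; normal
metrics are compared with Welch's unequal-variance t-test, non-normal
ones with the Mann-Whitney U (unpaired) or Wilcoxon signed-rank
(paired) test.  ``compare_groups`` always computes both the parametric
and nonparametric test and records which one the gate selected.  All
tests are two-sided; no multiple-testing correction is applied.

Exact small-sample p-values: Mann-Whitney uses the exact null
distribution when min(n1, n2) <= 8 and there are no ties, Wilcoxon when
there are <= 12 nonzero pairs without tied absolute differences; both
fall back to the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_group",
    "mann_whitney_u",
    "welch_t",
    "wilcoxon_signed_rank",
    "shapiro_wilk_gate",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int


def summarize_group(values) -> GroupSummary:
    """Sample mean, SD (n-1 denominator) and SEM; NaN SD/SEM for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if v.size == 1:
        return GroupSummary(1, float(v[0]), float("nan"), float("nan"))
    sd = float(v.std(ddof=1))
    return GroupSummary(int(v.size), float(v.mean()), sd, sd / math.sqrt(v.size))


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact p for min(n1, n2) <= 8 without ties; tie-corrected normal
    approximation otherwise.  The statistic is U for the first sample
    (midrank convention under ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(a, b)
    res = _stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), a.size, b.size)


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's test needs n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means")
    res = _stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue), a.size, b.size)


def wilcoxon_signed_rank(before, after) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired samples.

    Zero differences are dropped; exact p for <= 12 nonzero pairs without
    tied |differences|, normal approximation otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size or before.size == 0:
        raise ValueError("paired samples must be non-empty and equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    exact = d.size <= 12 and not _has_ties(np.abs(d))
    res = _stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), int(d.size), int(d.size)
    )


def shapiro_wilk_gate(values, alpha: float = 0.05) -> bool:
    """True if the sample passes Shapiro-Wilk normality (use parametric).

    Samples of n < 3 cannot be tested and default to nonparametric.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return False
    return bool(_stats.shapiro(v).pvalue >= alpha)


def compare_groups(a, b, paired: bool = False, alpha: float = 0.05) -> dict:
    """Gate on normality, then report the selected and both tests."""
    use_parametric = shapiro_wilk_gate(a, alpha) and shapiro_wilk_gate(b, alpha)
    if paired:
        nonparam = wilcoxon_signed_rank(a, b)
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        t = _stats.ttest_rel(b, a)
        param = TestResult("paired_t", float(t.statistic), float(t.pvalue), len(d), len(d))
    else:
        nonparam = mann_whitney_u(a, b)
        try:
            param = welch_t(a, b)
        except ValueError:  # degenerate group; the gated choice is nonparametric anyway
            param = None
    selected = param if (use_parametric and param is not None) else nonparam
    return {
        "selected": selected,
        "parametric": param,
        "nonparametric": nonparam,
        "gate_parametric": use_parametric,
    }
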