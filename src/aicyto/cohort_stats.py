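"""Group-level DI summaries and pairwise one-tailed unpaired t-tests.

Each condition group is summarized over its samples' peak DIs (mean, sample
SD, range, and the fraction of samples called aneuploid).  Groups are then
compared pairwise with an unpaired t-test — pooled-variance by default,
Welch optionally — with a one-tailed alternative.  By default the
alternative follows the presumed neoplastic progression order
(NCT < L-HP < L-SA < TA < AC): the later condition is tested for the
greater mean DI.  Significance is declared at p < alpha (default 0.05),
with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .ploidy import DEFAULT_THRESHOLDS, PloidyThresholds, SampleResult, classify_ploidy

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PROGRESSION_ORDER",
    "DEFAULT_ALPHA",
    "summarize_group",
    "t_test_from_summary",
    "t_test_from_samples",
    "comparison_matrix",
]

#: Canonical condition order, from normal tissue through the polyp spectrum
#: to adenocarcinoma.
PROGRESSION_ORDER = ("NCT", "L-HP", "L-SA", "TA", "AC")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    n: int
    mean_di: float
    sd_di: float  # sample SD (n-1 denominator); nan when n < 2
    di_range: tuple[float, float]
    aneuploid_count: int

    @property
    def aneuploid_fraction(self) -> float:
        return self.aneuploid_count / self.n


@dataclass(frozen=True)
class TTestResult:
    group_a: str
    group_b: str
    variant: str  # pooled | welch
    alternative: str  # "b_greater" | "a_greater" | "two_sided"
    t: float
    df: float
    p_one_tailed: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_one_tailed < self.alpha


def summarize_group(
    sample_results: Sequence[SampleResult],
    thresholds: PloidyThresholds = DEFAULT_THRESHOLDS,
) -> GroupSummary:
    """Mean/SD/range of per-sample peak DIs and the aneuploid fraction."""
    if not sample_results:
        raise ValueError("empty group")
    conditions = {s.condition for s in sample_results}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in one group: {sorted(conditions)}")
    peaks = np.array([s.peak_di for s in sample_results], dtype=float)
    n = peaks.size
    aneuploid = sum(
        1 for p in peaks if classify_ploidy(float(p), thresholds) != "diploid"
    )
    return GroupSummary(
        condition=conditions.pop(),
        n=int(n),
        mean_di=float(peaks.mean()),
        sd_di=float(peaks.std(ddof=1)) if n >= 2 else float("nan"),
        di_range=(float(peaks.min()), float(peaks.max())),
        aneuploid_count=int(aneuploid),
    )


def t_test_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "pooled",
    alternative: str = "b_greater",
    alpha: float = DEFAULT_ALPHA,
    group_a: str = "A",
    group_b: str = "B",
) -> TTestResult:
    """Unpaired two-sample t-test from summary statistics.

    Pooled variant: sp^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2),
    t = (mean_b - mean_a) / (sp * sqrt(1/n_a + 1/n_b)), df = n_a + n_b - 2.
    Welch variant: per-group variances with Satterthwaite df.  The one-tailed
    p is the tail probability of Student's t in the direction of the
    alternative; ``"two_sided"`` doubles the smaller tail.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a**2, sd_b**2
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            raise ValueError("degenerate: zero variance and equal means")
        t = float("inf") if mean_b > mean_a else float("-inf")
        df = float(n_a + n_b - 2)
    elif variant == "pooled":
        df = float(n_a + n_b - 2)
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
        t = (mean_b - mean_a) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    elif variant == "welch":
        qa, qb = va / n_a, vb / n_b
        t = (mean_b - mean_a) / np.sqrt(qa + qb)
        df = (qa + qb) ** 2 / (
            qa**2 / (n_a - 1) + qb**2 / (n_b - 1)
        )
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")

    if alternative == "b_greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "a_greater":
        p = float(stats.t.cdf(t, df))
    elif alternative == "two_sided":
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return TTestResult(
        group_a=group_a,
        group_b=group_b,
        variant=variant,
        alternative=alternative,
        t=float(t),
        df=float(df),
        p_one_tailed=p,
        alpha=alpha,
    )


def t_test_from_samples(
    di_a: Sequence[float],
    di_b: Sequence[float],
    variant: str = "pooled",
    alternative: str = "b_greater",
    alpha: float = DEFAULT_ALPHA,
    group_a: str = "A",
    group_b: str = "B",
) -> TTestResult:
    """Unpaired t-test from the raw per-sample DI lists."""
    a = np.asarray(list(di_a), dtype=float)
    b = np.asarray(list(di_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return t_test_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        variant=variant, alternative=alternative, alpha=alpha,
        group_a=group_a, group_b=group_b,
    )


def comparison_matrix(
    groups: Sequence[GroupSummary],
    variant: str = "pooled",
    order: Sequence[str] | None = None,
    alternative_policy: str = "progression",
    alpha: float = DEFAULT_ALPHA,
) -> dict[tuple[str, str], TTestResult]:
    """All pairwise one-tailed t-tests, keyed by (earlier, later) condition.

    ``order`` fixes the condition sequence (default: the progression order
    for conditions that appear in it, otherwise input order).  Under the
    ``"progression"`` policy the alternative for each pair is that the later
    condition has the greater mean DI.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    by_label = {g.condition: g for g in groups}
    if len(by_label) != len(groups):
        raise ValueError("duplicate condition labels")
    if order is None:
        if set(by_label) <= set(PROGRESSION_ORDER):
            order = [c for c in PROGRESSION_ORDER if c in by_label]
        else:
            order = [g.condition for g in groups]
    else:
        unknown = set(order) - set(by_label)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
        order = list(order)

    if alternative_policy not in ("progression", "two_sided"):
        raise ValueError(f"unknown alternative_policy {alternative_policy!r}")
    alternative = "b_greater" if alternative_policy == "progression" else "two_sided"

    out: dict[tuple[str, str], TTestResult] = {}
    for la, lb in combinations(order, 2):
        ga, gb = by_label[la], by_label[lb]
        out[(la, lb)] = t_test_from_summary(
            ga.mean_di, ga.sd_di, ga.n,
            gb.mean_di, gb.sd_di, gb.n,
            variant=variant, alternative=alternative, alpha=alpha,
            group_a=la, group_b=lb,
        )
    return out
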