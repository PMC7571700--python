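"""Group comparison statistics for per-oocyte scalars (e.g. furrow counts).

Reproduces the comparison procedure used for cortical furrowing counts:
one-way ANOVA across genotypes, two-tailed F-tests on the variances, and
two-tailed Student's t-tests whose equal/unequal-variance variant is chosen
by the F-test outcome at a configurable alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "PairComparison",
    "ComparisonReport",
    "one_way_anova",
    "variance_f_test",
    "gated_t_test",
    "compare_groups",
]


@dataclass
class GroupData:
    """Per-oocyte scalar values for one genotype/condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PairComparison:
    label_a: str
    label_b: str
    f_test_p: float
    variance_equal: bool
    t_statistic: float
    t_p: float
    variant: str                # "pooled" | "unequal-variance"
    degenerate: bool = False    # zero-variance special case


@dataclass
class ComparisonReport:
    anova_F: float
    anova_p: float
    pairs: list[PairComparison] = field(default_factory=list)
    alpha_var: float = 0.05
    bonferroni: bool = False


def _require_groups(groups: Sequence[GroupData], min_n: int = 2) -> None:
    for g in groups:
        if g.n < min_n:
            raise ValueError(f"group {g.label!r} needs n >= {min_n}, got {g.n}")


def one_way_anova(groups: Sequence[GroupData]) -> tuple[float, float]:
    """Classical one-way ANOVA F and upper-tail p over k groups.

    Between/within mean squares with (k-1, N-k) degrees of freedom.  When
    every group is internally constant: if the group means also coincide the
    statistic is reported as F = 0, p = 1 (no signal, no noise); if the means
    differ the F ratio is undefined and an error is raised.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    _require_groups(groups)
    all_values = np.concatenate([g.values for g in groups])
    grand = all_values.mean()
    n_total = len(all_values)
    k = len(groups)
    ss_between = sum(g.n * (g.values.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means: F undefined")
    df_between = k - 1
    df_within = n_total - k
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def variance_f_test(a: GroupData, b: GroupData) -> float:
    """Two-tailed F-test p-value for equality of two sample variances.

    The ratio puts the larger sample variance on top, with degrees of
    freedom ordered accordingly; p = min(1, 2 * upper tail).
    """
    _require_groups([a, b])
    var_a = a.values.var(ddof=1)
    var_b = b.values.var(ddof=1)
    if var_a == 0 and var_b == 0:
        raise ValueError("both variances are zero; F-test undefined")
    if var_a >= var_b:
        ratio, df1, df2 = (np.inf if var_b == 0 else var_a / var_b), a.n - 1, b.n - 1
    else:
        ratio, df1, df2 = var_b / var_a, b.n - 1, a.n - 1
    return float(min(1.0, 2.0 * sps.f.sf(ratio, df1, df2)))


def gated_t_test(
    a: GroupData, b: GroupData, alpha_var: float = 0.05
) -> PairComparison:
    """Two-tailed t-test whose variant is gated by the variance F-test.

    If the F-test p-value is >= ``alpha_var`` the variances are treated as
    equal and the pooled-variance Student's t-test is used
    (df = n_a + n_b - 2); otherwise the unequal-variance (Welch) test with
    Satterthwaite degrees of freedom.  Degenerate inputs where both groups
    are constant and equal report t = 0, p = 1 with the degenerate flag.
    """
    _require_groups([a, b])
    var_a = a.values.var(ddof=1)
    var_b = b.values.var(ddof=1)
    if var_a == 0 and var_b == 0:
        equal_means = a.values.mean() == b.values.mean()
        return PairComparison(
            label_a=a.label,
            label_b=b.label,
            f_test_p=1.0,
            variance_equal=True,
            t_statistic=0.0 if equal_means else np.inf,
            t_p=1.0 if equal_means else 0.0,
            variant="pooled",
            degenerate=True,
        )
    f_p = variance_f_test(a, b)
    equal = f_p >= alpha_var
    t_stat, t_p = sps.ttest_ind(a.values, b.values, equal_var=equal)
    return PairComparison(
        label_a=a.label,
        label_b=b.label,
        f_test_p=f_p,
        variance_equal=bool(equal),
        t_statistic=float(t_stat),
        t_p=float(t_p),
        variant="pooled" if equal else "unequal-variance",
    )


def compare_groups(
    groups: Sequence[GroupData],
    alpha_var: float = 0.05,
    bonferroni: bool = False,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ComparisonReport:
    """Full comparison report: ANOVA plus F-test-gated pairwise t-tests.

    ``pairs`` restricts the pairwise comparisons (default: all unordered
    pairs).  Raw pairwise p-values are reported by default; ``bonferroni``
    multiplies them by the number of comparisons (capped at 1).
    """
    groups = list(groups)
    by_label = {g.label: g for g in groups}
    if len(by_label) != len(groups):
        raise ValueError("group labels must be unique")
    f_stat, p = one_way_anova(groups)
    if pairs is None:
        pair_labels = list(combinations([g.label for g in groups], 2))
    else:
        pair_labels = [tuple(p_) for p_ in pairs]
    results = [
        gated_t_test(by_label[la], by_label[lb], alpha_var=alpha_var)
        for la, lb in pair_labels
    ]
    if bonferroni and results:
        m = len(results)
        for r in results:
            r.t_p = min(1.0, r.t_p * m)
    return ComparisonReport(
        anova_F=f_stat,
        anova_p=p,
        pairs=results,
        alpha_var=alpha_var,
        bonferroni=bonferroni,
    )
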