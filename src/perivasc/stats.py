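"""Group statistics: Jarque-Bera normality gate and two-sample comparison.

Group values (one per vessel/cell) are summarised as mean +/- SD.  Each
group is first checked for normality with the Jarque-Bera moment test,

    JB = (n / 6) * (S**2 + (K - 3)**2 / 4)

with S the sample skewness and K the (non-excess) sample kurtosis, and p
from the chi-squared(2) tail.  If both groups pass at alpha = 0.05, the
groups are compared with a t-test (Welch by default); otherwise a rank-sum
test is used, and the test actually applied is always reported.
Significance is declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    jb_statistic: float | None
    jb_p: float | None
    normal: bool


@dataclass
class ComparisonResult:
    group_a: GroupSummary
    group_b: GroupSummary
    test_used: str  # "t_test" | "rank_sum"
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def jarque_bera(sample) -> tuple[float, float]:
    """Jarque-Bera statistic and chi-squared(2) tail p-value.

    Uses population moment estimators (skewness m3/m2^1.5, kurtosis
    m4/m2^2), matching the classical JB formula; JB = 0 exactly iff the
    sample has zero skewness and kurtosis exactly 3.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"Jarque-Bera needs n >= 4, got n = {n}")
    m = x.mean()
    d = x - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero sample variance")
    s = np.mean(d**3) / m2**1.5
    k = np.mean(d**4) / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    p = float(sps.chi2.sf(jb, df=2))
    return float(jb), p


def summarize(sample, label: str = "") -> GroupSummary:
    """Mean +/- SD and normality verdict for one group.

    Groups too small for the moment test (n < 4) are treated as normal
    (the gate cannot reject), which keeps the comparison on the t-test.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("group needs at least 2 values")
    if n >= 4 and np.var(x) > 0:
        jb, p = jarque_bera(x)
        normal = p >= ALPHA
    else:
        jb, p = None, None
        normal = True
    return GroupSummary(
        label=label,
        n=n,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        jb_statistic=jb,
        jb_p=p,
        normal=normal,
    )


def compare_groups(
    a,
    b,
    label_a: str = "a",
    label_b: str = "b",
    paired: bool = False,
    equal_var: bool = False,
) -> ComparisonResult:
    """Compare two groups with the normality-gated test.

    Both normal (Jarque-Bera p >= 0.05): t-test — Welch by default
    (``equal_var=True`` for the pooled-variance variant), paired when
    requested.  Otherwise: rank-sum (Wilcoxon signed-rank when paired).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty group")
    sa = summarize(xa, label_a)
    sb = summarize(xb, label_b)

    if sa.normal and sb.normal:
        test_used = "t_test"
        if paired:
            res = sps.ttest_rel(xa, xb)
        else:
            res = sps.ttest_ind(xa, xb, equal_var=equal_var)
        stat, p = res.statistic, res.pvalue
        if np.isnan(stat):  # identical constant samples
            stat, p = 0.0, 1.0
    else:
        test_used = "rank_sum"
        if paired:
            res = sps.wilcoxon(xa, xb)
            stat, p = res.statistic, res.pvalue
        else:
            res = sps.ranksums(xa, xb)
            stat, p = res.statistic, res.pvalue
    return ComparisonResult(
        group_a=sa,
        group_b=sb,
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
    )
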