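"""Normality/homoscedasticity-driven test selection, applied package-wide.

Two samples: Shapiro-Wilk on each sample and a two-sided F-test for equal
variances, both at 0.05.  Both normal with equal variance -> Student's t
(paired variant for paired designs); normal with unequal variance ->
Welch's t; otherwise the two-sample Wilcoxon test (rank-sum unpaired,
signed-rank paired).

Three or more groups: Kolmogorov-Smirnov normality per group (against a
normal with the sample's estimated mean/SD; a Lilliefors-corrected variant
is available behind a switch) and Bartlett's test, both at 0.05.  All
normal with equal variance -> pairwise Student's t with Bonferroni; normal
with unequal variance -> Welch with Bonferroni; otherwise the Steel
many-one rank test against a designated reference group.

Every result carries a ``branch_trace`` recording each decision taken, so
the selected test is always auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as spstats

ALPHA_ASSUMPTIONS = 0.05


class DegenerateInputError(ValueError):
    """A branch's test is undefined for the given input (e.g. zero variance)."""


@dataclass
class TestResult:
    """Outcome of one comparison plus the decision path that selected it."""

    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    branch_trace: list[str] = field(default_factory=list)
    comparison: tuple[int, int] | None = None


def _f_test_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F-test."""
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("F-test branch: a sample has zero variance")
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = spstats.f.cdf(f, dfx, dfy)
    return float(f), float(2 * min(cdf, 1 - cdf))


def compare_two(
    x,
    y,
    paired: bool = False,
    alpha: float = ALPHA_ASSUMPTIONS,
    strict: bool = False,
) -> TestResult:
    """Two-sample comparison with automatic test selection.

    ``strict=True`` replaces the F-test on raw samples by Shapiro on the
    paired differences when ``paired`` (variance equality is immaterial for
    a paired t-test); the default follows the raw-sample decision tree
    uniformly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs >= 3 observations")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            "normality branch: zero-variance sample; no dispatch possible"
        )
    trace: list[str] = []
    sh_x = spstats.shapiro(x)
    sh_y = spstats.shapiro(y)
    trace.append(f"shapiro_x p={sh_x.pvalue:.4g}")
    trace.append(f"shapiro_y p={sh_y.pvalue:.4g}")
    normal = sh_x.pvalue > alpha and sh_y.pvalue > alpha

    if normal and strict and paired:
        d = x - y
        if np.ptp(d) == 0:
            raise DegenerateInputError("paired t branch: zero-variance differences")
        sh_d = spstats.shapiro(d)
        trace.append(f"shapiro_diff p={sh_d.pvalue:.4g} (strict mode)")
        if sh_d.pvalue > alpha:
            res = spstats.ttest_rel(x, y)
            return TestResult("student_t_paired", float(res.statistic), float(res.pvalue), branch_trace=trace)
        res = spstats.wilcoxon(x, y)
        return TestResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), branch_trace=trace)

    if normal:
        f_stat, f_p = _f_test_two_sided(x, y)
        trace.append(f"f_test p={f_p:.4g}")
        if f_p > alpha:
            if paired:
                d = x - y
                if np.ptp(d) == 0:
                    raise DegenerateInputError("paired t branch: zero-variance differences")
                res = spstats.ttest_rel(x, y)
                return TestResult("student_t_paired", float(res.statistic), float(res.pvalue), branch_trace=trace)
            res = spstats.ttest_ind(x, y, equal_var=True)
            return TestResult("student_t", float(res.statistic), float(res.pvalue), branch_trace=trace)
        res = spstats.ttest_ind(x, y, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.pvalue), branch_trace=trace)

    trace.append("non-normal -> wilcoxon")
    if paired:
        d = x - y
        if np.ptp(d) == 0:
            raise DegenerateInputError("wilcoxon branch: all paired differences zero")
        res = spstats.wilcoxon(x, y)
        return TestResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), branch_trace=trace)
    res = spstats.ranksums(x, y)
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), branch_trace=trace)


def _ks_normal(g: np.ndarray, lilliefors: bool) -> float:
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(g, dist="norm")[1])
    return float(
        spstats.kstest(g, "norm", args=(np.mean(g), np.std(g, ddof=1))).pvalue
    )


def steel_test(groups: list[np.ndarray], reference_index: int = 0) -> list[TestResult]:
    """Steel many-one rank test: each treatment group vs one control.

    For each treatment, the control-vs-treatment rank sum is standardized
    (with tie correction) into a z statistic; the familywise two-sided
    p-value is taken from the joint asymptotic multivariate normal of all
    treatment statistics, whose correlations follow from the shared
    control group (Dunnett-type correlation structure).
    """
    control = np.asarray(groups[reference_index], dtype=float)
    treatments = [
        (i, np.asarray(g, dtype=float))
        for i, g in enumerate(groups)
        if i != reference_index
    ]
    n0 = len(control)
    zs = []
    for _, g in treatments:
        ni = len(g)
        combined = np.concatenate([control, g])
        ranks = spstats.rankdata(combined)
        w = ranks[n0:].sum()
        n = n0 + ni
        mean_w = ni * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var_w = n0 * ni / 12.0 * (n + 1 - tie_term)
        if var_w <= 0:
            zs.append(0.0)
            continue
        zs.append((w - mean_w) / np.sqrt(var_w))
    k = len(treatments)
    lam = np.array([len(g) / (len(g) + n0) for _, g in treatments])
    corr = np.sqrt(np.outer(lam, lam))
    np.fill_diagonal(corr, 1.0)
    mvn = spstats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    results = []
    for j, ((i, _), z) in enumerate(zip(treatments, zs)):
        c = abs(z)
        inside = float(mvn.cdf(np.full(k, c), lower_limit=np.full(k, -c))) if c > 0 else 0.0
        p = min(1.0, max(0.0, 1.0 - inside))
        results.append(
            TestResult(
                "steel",
                float(z),
                p,
                adjusted_p=p,  # joint MVN p is already familywise
                comparison=(reference_index, i),
            )
        )
    return results


def compare_many(
    groups,
    reference_index: int | None = None,
    alpha: float = ALPHA_ASSUMPTIONS,
    lilliefors: bool = False,
    steel_min_n: int = 6,
) -> list[TestResult]:
    """Many-group comparison with automatic test selection.

    Parametric branches run pairwise tests — many-one against
    ``reference_index`` when given, otherwise all pairs — with Bonferroni
    adjustment over the comparisons actually made.  The nonparametric
    branch is the Steel test and requires ``reference_index``; with any
    group smaller than ``steel_min_n`` the asymptotic Steel approximation
    is replaced by pairwise rank-sum tests with Bonferroni (flagged in the
    trace).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_many needs >= 3 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs >= 3 observations")
    trace: list[str] = []
    normal = True
    for i, g in enumerate(groups):
        if np.ptp(g) == 0:
            raise DegenerateInputError(f"normality branch: group {i} has zero variance")
        p = _ks_normal(g, lilliefors)
        trace.append(f"ks_group{i} p={p:.4g}")
        normal &= p > alpha
    if normal:
        bart = spstats.bartlett(*groups)
        trace.append(f"bartlett p={bart.pvalue:.4g}")
        equal_var = bart.pvalue > alpha
        if reference_index is not None:
            pairs = [(reference_index, j) for j in range(len(groups)) if j != reference_index]
        else:
            pairs = list(combinations(range(len(groups)), 2))
        m = len(pairs)
        name = "student_t_bonferroni" if equal_var else "welch_t_bonferroni"
        results = []
        for i, j in pairs:
            res = spstats.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            results.append(
                TestResult(
                    name,
                    float(res.statistic),
                    float(res.pvalue),
                    adjusted_p=min(1.0, float(res.pvalue) * m),
                    branch_trace=list(trace),
                    comparison=(i, j),
                )
            )
        return results
    trace.append("non-normal -> steel")
    if reference_index is None:
        raise ValueError("the Steel branch requires reference_index")
    if min(len(g) for g in groups) < steel_min_n:
        trace.append("small-sample fallback: rank-sum + bonferroni")
        pairs = [(reference_index, j) for j in range(len(groups)) if j != reference_index]
        m = len(pairs)
        results = []
        for i, j in pairs:
            res = spstats.ranksums(groups[j], groups[i])
            results.append(
                TestResult(
                    "wilcoxon_rank_sum_bonferroni",
                    float(res.statistic),
                    float(res.pvalue),
                    adjusted_p=min(1.0, float(res.pvalue) * m),
                    branch_trace=list(trace),
                    comparison=(i, j),
                )
            )
        return results
    results = steel_test(groups, reference_index)
    for r in results:
        r.branch_trace = list(trace)
    return results
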