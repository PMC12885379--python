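"""Group-comparison statistics used across the assays.

Thin, contract-stable wrappers around scipy for the standard tests, plus
hand-rolled Welch and Brown–Forsythe ANOVA (scipy has neither). Two-sided
Fisher uses the probability-ordering rule: the p-value is the sum of
hypergeometric probabilities of all tables sharing the observed margins
whose probability does not exceed the observed table's (with a small
relative slack for float ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class ContingencyTable2x2:
    """Counts with rows = groups, columns = outcome / failed outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        self.a, self.b, self.c, self.d = int(self.a), int(self.b), int(self.c), int(self.d)
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class TestResult:
    test_name: str
    statistic: float | None
    p_value: float
    group_ns: list[int] = field(default_factory=list)
    alpha: float = ALPHA
    df: tuple | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_ns": self.group_ns,
            "alpha": self.alpha,
            "df": list(self.df) if self.df is not None else None,
            "flags": self.flags,
        }


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test (probability-ordering rule)."""
    arr = table.to_array()
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        test_name="fisher_exact",
        statistic=None,
        p_value=min(float(p), 1.0),
        group_ns=[int(arr[0].sum()), int(arr[1].sum())],
    )


def rank_tests(groups: list[list[float]]) -> TestResult:
    """Mann–Whitney U for 2 groups, Kruskal–Wallis H for >=2 (mid-rank ties)."""
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("each group needs >=1 value")
    ns = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across groups; p = 1", stacklevel=2)
        return TestResult("rank_degenerate", statistic=0.0, p_value=1.0, group_ns=ns, flags=["all_identical"])
    if len(arrays) == 2:
        stat, p = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return TestResult("mann_whitney_u", float(stat), float(p), group_ns=ns)
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p), group_ns=ns)


def welch_anova(groups: list[list[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA."""
    arrays = _check_variance_groups(groups)
    k = len(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    flags = []
    if np.any(variances == 0):
        flags.append("zero_variance_group")
    with np.errstate(invalid="ignore", divide="ignore"):
        w = ns / variances  # inf weights propagate per the standard formulas
        mw = np.sum(w * means) / np.sum(w)
        tmp = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
        num = np.sum(w * (means - mw) ** 2) / (k - 1)
        den = 1 + 2 * (k - 2) * tmp / (k**2 - 1)
        f = num / den
        df2 = (k**2 - 1) / (3 * tmp)
    if not np.isfinite(f):
        return TestResult("welch_anova", None, 1.0, group_ns=[int(n) for n in ns], flags=flags + ["degenerate"])
    p = float(sps.f.sf(f, k - 1, df2))
    return TestResult(
        "welch_anova", float(f), p, group_ns=[int(n) for n in ns], df=(k - 1, float(df2)), flags=flags
    )


def brown_forsythe_anova(groups: list[list[float]]) -> TestResult:
    """Brown–Forsythe F* test for equality of means under unequal variances."""
    arrays = _check_variance_groups(groups)
    k = len(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    n_total = ns.sum()
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    flags = []
    if np.any(variances == 0):
        flags.append("zero_variance_group")
    grand = np.concatenate(arrays).mean()
    num = np.sum(ns * (means - grand) ** 2)
    den = np.sum((1 - ns / n_total) * variances)
    if den == 0:
        return TestResult(
            "brown_forsythe_anova", None, 1.0, group_ns=[int(n) for n in ns], flags=flags + ["degenerate"]
        )
    f = num / den
    c = (1 - ns / n_total) * variances / den
    df2 = 1.0 / np.sum(c**2 / (ns - 1))
    p = float(sps.f.sf(f, k - 1, df2))
    return TestResult(
        "brown_forsythe_anova", float(f), p, group_ns=[int(n) for n in ns], df=(k - 1, float(df2)), flags=flags
    )


def variance_tests(groups: list[list[float]]) -> dict[str, TestResult]:
    """Welch ANOVA and Brown–Forsythe ANOVA with their df corrections."""
    return {"welch": welch_anova(groups), "brown_forsythe": brown_forsythe_anova(groups)}


def _check_variance_groups(groups: list[list[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >=2 values")
    return arrays


def paired_ttest(x: list[float], y: list[float]) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need >=2 pairs")
    if np.ptp(x - y) == 0 and np.all(x == y):
        return TestResult("paired_t", 0.0, 1.0, group_ns=[len(x)], flags=["zero_deltas"])
    stat, p = sps.ttest_rel(x, y)
    if np.isnan(p):  # constant nonzero deltas: sd of deltas is 0
        return TestResult("paired_t", None, 0.0 if np.any(x != y) else 1.0, group_ns=[len(x)], flags=["zero_delta_sd"])
    return TestResult("paired_t", float(stat), float(p), group_ns=[len(x)], df=(len(x) - 1,))


def chisq_test(table: np.ndarray) -> TestResult:
    """Pearson chi-squared on an R×C table, no continuity correction."""
    table = np.asarray(table)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("need a non-negative R×C table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(
        "chi_squared",
        float(res.statistic),
        float(res.pvalue),
        group_ns=[int(n) for n in table.sum(axis=1)],
        df=(int(res.dof),),
    )


def paired_and_chisq(pairs: tuple | None = None, table: np.ndarray | None = None) -> TestResult:
    """Dispatch: paired vectors → paired t; R×C table → Pearson chi-squared."""
    if (pairs is None) == (table is None):
        raise ValueError("supply exactly one of pairs or table")
    if pairs is not None:
        return paired_ttest(pairs[0], pairs[1])
    return chisq_test(table)
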