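"""Nonparametric group-comparison statistics with exact small-sample paths.

The study design this package emulates compares small groups (n = 6–8
eyes): unpaired contrasts use the two-sided Mann–Whitney U test, paired
OHT-vs-contralateral contrasts the Wilcoxon signed-rank test, and
retinal-zone contrasts a one-way ANOVA with Bonferroni-corrected
pairwise comparisons.  Summaries are reported as mean ± SD.

At these sample sizes asymptotic p-values are unreliable, so both rank
tests switch to exact null distributions (computed by dynamic
programming over rank assignments / sign patterns, equivalent to full
enumeration) when the combined sample is small; the method actually
used is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from itertools import product

import numpy as np
from scipy import stats as sps

from .types import GliaquantError

__all__ = [
    "GroupSummary",
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "anova_bonferroni",
    "summarize",
    "EXACT_CROSSOVER",
]

#: Largest combined sample size for which the exact enumeration path is
#: used (Mann–Whitney: n_x + n_y; Wilcoxon: nonzero pairs).
EXACT_CROSSOVER = 12


class StatsError(GliaquantError):
    """Raised on degenerate statistical input."""


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one metric in one group."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float
    single_observation: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approximation" or "f_distribution"
    pairwise: list[tuple[str, float]] = dc_field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# exact null distributions (dynamic programming == full enumeration)

@lru_cache(maxsize=None)
def _mwu_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of label assignments yielding each U value, tie-free case.

    Standard recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u);
    equivalent to enumerating all C(n1+n2, n1) assignments.
    """
    max_u = n1 * n2
    table = {(0, 0): np.array([1], dtype=object)}

    def counts(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            out = np.array([1], dtype=object)
        else:
            ca = counts(a - 1, b)
            cb = counts(a, b - 1)
            out = np.zeros(a * b + 1, dtype=object)
            out[b : b + len(ca)] += ca
            out[: len(cb)] += cb
        table[(a, b)] = out
        return out

    full = np.zeros(max_u + 1, dtype=object)
    c = counts(n1, n2)
    full[: len(c)] = c
    return tuple(int(v) for v in full)


@lru_cache(maxsize=None)
def _wilcoxon_null_counts(ranks2: tuple[int, ...]) -> tuple[int, ...]:
    """Distribution of 2·W+ over all sign patterns for doubled ranks.

    Ranks are doubled so midranks from ties in |d| stay integral; the
    DP is equivalent to enumerating all 2^m sign patterns.
    """
    total = sum(ranks2)
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return tuple(int(v) for v in counts)


def _two_sided_from_counts(counts, stat: float) -> float:
    """Two-sided p = min(1, 2·min(P(T ≤ t), P(T ≥ t))) from a discrete
    null distribution given as per-value counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    k = int(round(stat))
    lo = counts[: k + 1].sum() / total
    hi = counts[k:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# tests

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test for two independent samples.

    Exact p by enumeration of label assignments when n_x + n_y ≤
    :data:`EXACT_CROSSOVER` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie correction
    (delegated to scipy).  The U statistic reported is U for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < pooled.size
    if n1 + n2 <= EXACT_CROSSOVER and not has_ties:
        p = _two_sided_from_counts(_mwu_null_counts(n1, n2), u1)
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approximation"
    return TestResult("mann_whitney_u", u1, p, method)


def wilcoxon_signed_rank(paired_x, paired_y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's original convention,
    recorded in the result note).  Exact p by enumeration of sign
    patterns when the number of nonzero pairs is ≤
    :data:`EXACT_CROSSOVER`, otherwise the normal approximation with
    tie correction.  The statistic is W+ (sum of positive-difference
    ranks on |d|).
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired samples must have equal length")
    d = x - y
    n_zero = int(np.count_nonzero(d == 0))
    d = d[d != 0]
    if d.size == 0:
        raise StatsError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    note = f"{n_zero} zero difference(s) dropped" if n_zero else ""
    if d.size <= EXACT_CROSSOVER:
        ranks2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        p = _two_sided_from_counts(_wilcoxon_null_counts(ranks2), 2 * w_plus)
        method = "exact"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", correction=False,
                           method="approx")
        p = float(res.pvalue)
        method = "normal_approximation"
    return TestResult("wilcoxon_signed_rank", w_plus, p, method, note=note)


def anova_bonferroni(
    groups: dict[str, np.ndarray] | list, labels: list[str] | None = None
) -> TestResult:
    """One-way ANOVA with Bonferroni-corrected pairwise comparisons.

    ``groups`` is a mapping label → sample (or a list of samples with
    ``labels``).  Pairwise comparisons are pooled-MSE t tests on all
    group pairs with raw p multiplied by the number of pairs and capped
    at 1.  Requires ≥ 2 groups of n ≥ 2 and positive pooled
    within-group variance.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
        labels = labels or [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise StatsError("need at least two groups")
    for s in samples:
        if s.size < 2:
            raise StatsError("every group needs n >= 2")
    k = len(samples)
    ns = np.array([s.size for s in samples])
    means = np.array([s.mean() for s in samples])
    big_n = int(ns.sum())
    sse = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    if sse == 0.0:
        raise StatsError("zero within-group variance everywhere")
    grand = float(np.concatenate(samples).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    df_b, df_w = k - 1, big_n - k
    f_stat = (ssb / df_b) / (sse / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w)) if f_stat > 0 else 1.0

    mse = sse / df_w
    n_pairs = k * (k - 1) // 2
    pairwise: list[tuple[str, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            t = (means[i] - means[j]) / se
            raw = float(2.0 * sps.t.sf(abs(t), df_w))
            pairwise.append((f"{labels[i]} vs {labels[j]}", min(1.0, raw * n_pairs)))
    return TestResult(
        "anova_bonferroni", float(f_stat), p, "f_distribution", pairwise=pairwise
    )


def summarize(values, group: str, metric: str) -> GroupSummary:
    """Mean ± SD (n−1 denominator) summary; a single observation is
    reported with sd 0 and flagged."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("cannot summarize an empty sample")
    single = v.size == 1
    sd = 0.0 if single else float(v.std(ddof=1))
    return GroupSummary(group, metric, int(v.size), float(v.mean()), sd, single)


# ---------------------------------------------------------------------------
# brute-force oracles (used by the acceptance harness; tests carry their
# own independent copies)

def enumerate_mwu_p(x, y) -> float:
    """Two-sided exact Mann–Whitney p by literal enumeration of all
    label assignments (tie-free samples only)."""
    from itertools import combinations

    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
            1.0 for a in xs for b in ys if a == b
        )

    observed = u_of(tuple(range(n1)))
    us = [u_of(idx) for idx in combinations(range(len(pooled)), n1)]
    total = len(us)
    lo = sum(1 for u in us if u <= observed) / total
    hi = sum(1 for u in us if u >= observed) / total
    return min(1.0, 2.0 * min(lo, hi))


def enumerate_wilcoxon_p(diffs) -> float:
    """Two-sided exact signed-rank p by literal enumeration of all
    2^m sign patterns."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in product((-1, 1), repeat=len(d))
    ]
    total = len(ws)
    lo = sum(1 for w in ws if w <= observed) / total
    hi = sum(1 for w in ws if w >= observed) / total
    return min(1.0, 2.0 * min(lo, hi))
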