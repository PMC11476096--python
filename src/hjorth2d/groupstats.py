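"""Rank-based comparison of descriptor distributions across groups.

The differentiation procedure is: per descriptor, check normality per
group (Shapiro–Wilk) and variance homogeneity (Levene); since small
grouped texture samples typically fail both, decide with the
nonparametric Kruskal–Wallis rank ANOVA, and localize the difference
with Dunn's pairwise z-tests on rank means under a Bonferroni
correction over the k(k-1)/2 comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError

__all__ = [
    "GroupedSample",
    "RankSummary",
    "TestResult",
    "LeveneResult",
    "PosthocMatrix",
    "rank_all",
    "kruskal_wallis_from_ranks",
    "kruskal_wallis",
    "dunn_posthoc",
    "dunn_from_rank_summary",
    "levene",
    "shapiro_wilk",
]


@dataclass(frozen=True)
class GroupedSample:
    """Named groups of scalar values for one descriptor."""

    descriptor_name: str
    groups: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InputError("need at least 2 groups")
        labels = [lab for lab, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate group labels in {labels}")
        norm = tuple((lab, tuple(float(v) for v in vals)) for lab, vals in self.groups)
        for lab, vals in norm:
            if len(vals) == 0:
                raise InputError(f"group {lab!r} is empty")
        object.__setattr__(self, "groups", norm)

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "GroupedSample":
        return cls(name, tuple((k, tuple(v)) for k, v in d.items()))

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.groups]

    @property
    def sizes(self) -> list[int]:
        return [len(vals) for _, vals in self.groups]

    @property
    def total_n(self) -> int:
        return sum(self.sizes)

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(vals) for _, vals in self.groups])


@dataclass(frozen=True)
class RankSummary:
    """Per-group mid-rank bookkeeping over the pooled sample."""

    labels: tuple[str, ...]
    sizes: tuple[int, ...]
    rank_sums: tuple[float, ...]
    tie_groups: tuple[int, ...] = ()  # multiplicity of each tied block

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))

    @property
    def rank_averages(self) -> tuple[float, ...]:
        return tuple(r / n for r, n in zip(self.rank_sums, self.sizes))

    @property
    def tie_correction(self) -> float:
        """1 - sum(t^3 - t) / (N^3 - N); 1.0 when there are no ties."""
        n = self.total_n
        if not self.tie_groups or n < 2:
            return 1.0
        return 1.0 - sum(t**3 - t for t in self.tie_groups) / (n**3 - n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    distribution: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class LeveneResult:
    """Levene test with its full one-way ANOVA decomposition."""

    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    statistic: float
    p_value: float
    center: str = "mean"


@dataclass(frozen=True, eq=False)
class PosthocMatrix:
    """Pairwise Dunn z-scores and Bonferroni-adjusted two-sided p-values."""

    labels: tuple[str, ...]
    z: np.ndarray
    p_adj: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.p_adj[i, j])


def rank_all(sample: GroupedSample) -> RankSummary:
    """Pooled mid-ranks (ties averaged) summed per group.

    Rank conservation holds exactly: sum of rank sums = N(N+1)/2.
    """
    pooled = sample.pooled()
    ranks = stats.rankdata(pooled, method="average")
    sums, start = [], 0
    for n in sample.sizes:
        sums.append(float(ranks[start : start + n].sum()))
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    ties = tuple(int(c) for c in counts if c > 1)
    return RankSummary(
        labels=tuple(sample.labels),
        sizes=tuple(sample.sizes),
        rank_sums=tuple(sums),
        tie_groups=ties,
    )


def kruskal_wallis_from_ranks(
    sizes, rank_sums, tie_correction: float = 1.0, tol: float = 1e-9
) -> TestResult:
    """H from per-group sizes and rank sums.

    H = [12 / (N(N+1)) * sum R_i^2 / n_i - 3(N+1)] / tie_correction,
    referred to the chi-square distribution with k-1 degrees of freedom.
    The rank sums must conserve the total N(N+1)/2.
    """
    sizes = [int(n) for n in sizes]
    rank_sums = [float(r) for r in rank_sums]
    n_total = sum(sizes)
    expected = n_total * (n_total + 1) / 2
    if abs(sum(rank_sums) - expected) > max(tol, 1e-9 * expected):
        raise InputError(
            f"rank sums {sum(rank_sums)} violate conservation N(N+1)/2 = {expected}"
        )
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r * r / n for r, n in zip(rank_sums, sizes)
    ) - 3.0 * (n_total + 1)
    h /= tie_correction
    df = len(sizes) - 1
    p = float(stats.chi2.sf(h, df))
    return TestResult(statistic=float(h), p_value=p, distribution=f"chi2(df={df})")


def kruskal_wallis(sample: GroupedSample, method: str = "chi2") -> TestResult:
    """Kruskal–Wallis rank ANOVA across the sample's groups.

    method='chi2' uses the asymptotic chi-square reference with the
    standard tie correction; method='permutation' computes the exact
    null by full enumeration of group assignments (feasible only for
    small total N) and is exact by construction.
    """
    pooled = sample.pooled()
    if np.ptp(pooled) == 0:
        raise DegenerateInputError("all values identical: H undefined")
    summary = rank_all(sample)
    result = kruskal_wallis_from_ranks(
        summary.sizes, summary.rank_sums, summary.tie_correction
    )
    if method == "chi2":
        return result
    if method != "permutation":
        raise InputError(f"unknown method {method!r}")

    ranks = stats.rankdata(pooled, method="average")
    sizes = sample.sizes
    n_total = summary.total_n

    def h_of(rank_groups):
        h = 12.0 / (n_total * (n_total + 1)) * sum(
            sum(g) ** 2 / len(g) for g in rank_groups
        ) - 3.0 * (n_total + 1)
        return h / summary.tie_correction

    h_obs = h_of(
        [ranks[sum(sizes[:i]) : sum(sizes[: i + 1])] for i in range(len(sizes))]
    )
    count = total = 0
    for groups in _assignments(ranks, sizes):
        total += 1
        if h_of(groups) >= h_obs - 1e-12:
            count += 1
    return TestResult(
        statistic=float(h_obs),
        p_value=count / total,
        distribution=f"exact permutation ({total} assignments)",
    )


def _assignments(values: np.ndarray, sizes: list[int]):
    """All distinct partitions of ``values`` (by index) into ordered groups."""
    idx = tuple(range(len(values)))

    def rec(remaining, k):
        if k == len(sizes) - 1:
            yield [np.asarray([values[i] for i in remaining])]
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(combo))
            head = np.asarray([values[i] for i in combo])
            for tail in rec(rest, k + 1):
                yield [head] + tail

    yield from rec(idx, 0)


def dunn_from_rank_summary(summary: RankSummary) -> PosthocMatrix:
    """Dunn's pairwise z-tests on rank means, Bonferroni-adjusted.

    z_ij = |Rbar_i - Rbar_j| / sqrt(N(N+1)/12 * (1/n_i + 1/n_j));
    raw two-sided normal p is multiplied by k(k-1)/2 and clipped at 1.
    """
    k = len(summary.labels)
    n_total = summary.total_n
    n_comp = k * (k - 1) / 2
    ra = summary.rank_averages
    z = np.zeros((k, k))
    p_adj = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / summary.sizes[i] + 1.0 / summary.sizes[j])
        )
        zij = abs(ra[i] - ra[j]) / se
        praw = 2.0 * float(stats.norm.sf(zij))
        z[i, j] = z[j, i] = zij
        p_adj[i, j] = p_adj[j, i] = min(1.0, n_comp * praw)
    return PosthocMatrix(labels=summary.labels, z=z, p_adj=p_adj)


def dunn_posthoc(sample: GroupedSample | RankSummary) -> PosthocMatrix:
    """Dunn post hoc matrix from raw grouped values or a rank summary."""
    summary = sample if isinstance(sample, RankSummary) else rank_all(sample)
    return dunn_from_rank_summary(summary)


def levene(sample: GroupedSample, center: str = "mean") -> LeveneResult:
    """Levene's variance-homogeneity test with full ANOVA decomposition.

    One-way ANOVA on absolute deviations |x - center(group)|; center
    'mean' is the classic Levene statistic, 'median' the Brown–Forsythe
    variant. Reports between-group SS/df/MS, residual SS*/df*/MS*,
    F = MS/MS* and the F(k-1, N-k) p-value.
    """
    if center not in ("mean", "median"):
        raise InputError(f"center must be 'mean' or 'median', got {center!r}")
    if any(n < 2 for n in sample.sizes):
        raise InputError("every group needs >= 2 values for the Levene test")
    centerfn = np.mean if center == "mean" else np.median
    devs = [np.abs(np.asarray(vals) - centerfn(vals)) for _, vals in sample.groups]
    n_total = sample.total_n
    k = len(devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        raise DegenerateInputError("zero residual spread: Levene F undefined")
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return LeveneResult(
        ss_between=float(ss_between),
        df_between=df_between,
        ms_between=float(ms_between),
        ss_within=float(ss_within),
        df_within=df_within,
        ms_within=float(ms_within),
        statistic=float(f),
        p_value=p,
        center=center,
    )


def shapiro_wilk(values) -> TestResult:
    """Shapiro–Wilk normality test (delegated to scipy)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise InputError(f"Shapiro–Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InputError(f"Shapiro–Wilk limited to n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample: Shapiro–Wilk W undefined")
    w, p = stats.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), distribution="Shapiro-Wilk W")
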