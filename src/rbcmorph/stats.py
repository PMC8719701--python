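"""Group summaries and significance tests.

The comparison design: per-parameter one-way ANOVA across the solution
groups followed by Bonferroni-adjusted pairwise Student's t-tests, with the
conventional star annotation (* p<0.05, ** p<0.01, *** p<0.001).

F and t statistics are computed from sums of squares here; tail
probabilities go through the regularized incomplete beta function
(``scipy.special.betainc``) rather than lookup tables:

    P(T > |t|) * 2 = I_{df/(df+t^2)}(df/2, 1/2)
    P(F > f)       = I_{d2/(d2+d1 f)}(d2/2, d1/2)
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TTestResult",
    "GroupComparison",
    "summarize",
    "one_way_anova",
    "students_t",
    "welch_t",
    "pairwise_bonferroni",
    "star_annotation",
    "compare_groups",
    "null_rejection_rate",
]


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float  # sample (n-1) SD; NaN when n < 2


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class GroupComparison:
    """Per-parameter ANOVA + Bonferroni post-hoc bundle.

    ``pairwise_p`` maps (group_a, group_b) to the Bonferroni-adjusted p of
    the pooled t-test; ``stars`` carries the matching annotation.
    """

    parameter: str
    summaries: list[GroupSummary]
    anova: AnovaResult
    pairwise_p: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        k = len(self.summaries)
        n_total = sum(s.n for s in self.summaries)
        assert self.anova.df_between == k - 1
        assert self.anova.df_within == n_total - k


def _t_sf2(t: float | np.ndarray, df: float) -> float | np.ndarray:
    """Two-sided tail probability of Student's t via the incomplete beta."""
    t = np.asarray(t, dtype=float)
    p = betainc(df / 2.0, 0.5, df / (df + t**2))
    return float(p) if p.ndim == 0 else p


def _f_sf(f: float, d1: int, d2: int) -> float:
    return float(betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * f)))


def summarize(values_by_group: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Per-group n, mean and sample SD (mean ± SD reporting convention)."""
    out = []
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        n = vals.size
        if n == 0:
            raise ValueError(f"group {name!r} is empty")
        if n < 2:
            logger.warning("group %r has n=1: SD undefined", name)
            sd = math.nan
        else:
            sd = float(vals.std(ddof=1))
        out.append(GroupSummary(name=name, n=n, mean=float(vals.mean()), sd=sd))
    return out


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA from between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    all_vals = np.concatenate(groups)
    k, n_total = len(groups), all_vals.size
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all values identical: F undefined")
        logger.warning("zero within-group variance with nonzero between: p = 0")
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    f = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w, p=_f_sf(f, df_b, df_w))


def students_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 == 0.0:
        raise ValueError("zero pooled variance: t undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    return TTestResult(t=float(t), df=df, p=_t_sf2(t, df))


def welch_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Welch's unequal-variance t-test (alternative to the pooled default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0.0:
        raise ValueError("zero variance: t undefined")
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TTestResult(t=float(t), df=float(df), p=_t_sf2(t, df))


def pairwise_bonferroni(
    values_by_group: dict[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """All-pairs pooled t-tests with Bonferroni adjustment.

    p_adj = min(1, m * p) with m = C(k, 2), the number of pairwise
    comparisons.
    """
    names = list(values_by_group)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        try:
            p_raw = students_t(values_by_group[a], values_by_group[b]).p
        except ValueError:
            # identical constant groups: no evidence of a difference
            p_raw = 1.0
        out[(a, b)] = min(1.0, m * p_raw)
    return out


def star_annotation(p: float) -> str:
    """Figure-caption stars: '' p>=0.05, * p<0.05, ** p<0.01, *** p<0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(values_by_group: dict[str, np.ndarray], parameter: str) -> GroupComparison:
    """Full comparison bundle for one morphometric parameter."""
    summaries = summarize(values_by_group)
    anova = one_way_anova([np.asarray(v, dtype=float) for v in values_by_group.values()])
    pw = pairwise_bonferroni(values_by_group)
    stars = {pair: star_annotation(p) for pair, p in pw.items()}
    return GroupComparison(
        parameter=parameter, summaries=summaries, anova=anova, pairwise_p=pw, stars=stars
    )


def null_rejection_rate(
    n_per_group: int = 40,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the pooled t-test under a true null
    (both groups standard normal).  Vectorized over replicates."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    df = 2 * n_per_group - 2
    sp2 = (
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / df
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (2.0 / n_per_group))
    p = _t_sf2(t, df)
    return float(np.mean(p < alpha))
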