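"""Group-level inference: paired drug-effect tests, one-way ANOVA, Tukey HSD.

Two routes are provided.  Raw-data routes delegate to scipy
(``ttest_rel``, ``f_oneway``, ``tukey_hsd`` — the latter applies the
Tukey-Kramer correction for unequal group sizes).  A summary-statistics
route (:func:`anova_from_summary`) reconstructs the sums of squares from
per-group (n, mean, SEM) triples and computes Tukey p-values from the
studentized-range distribution directly, so printed mean +/- SEM tables can
be analysed without raw values; on matching data the two routes agree to
floating-point error.  All tests are two-sided with the conventional
starring at p < 0.05 (*) and p < 0.01 (**).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and SEM of one group of per-slice values."""

    label: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @property
    def variance(self) -> float:
        return self.sem ** 2 * self.n


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test: statistic, degrees of freedom, p-value."""

    method: str                      # paired_t | anova | tukey
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    comparison: tuple[str, ...] = ("omnibus",)
    qc: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        if math.isnan(self.p_value):
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def summarize_group(values: Sequence[float], label: str = "group") -> GroupSummary:
    """Mean and SEM (sample SD / sqrt(n)) of one group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty group")
    if v.size == 1:
        return GroupSummary(label=label, n=1, mean=float(v[0]), sem=0.0)
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size))
    return GroupSummary(label=label, n=int(v.size), mean=float(np.mean(v)),
                        sem=sem)


def paired_t_test(x: Sequence[float], y: Sequence[float],
                  labels: tuple[str, str] = ("x", "y")) -> StatResult:
    """Two-sided paired t-test on differences ``y - x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = y - x
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return StatResult("paired_t", 0.0, n - 1, 1.0, labels)
        return StatResult("paired_t", math.copysign(math.inf, float(d[0])),
                          n - 1, 0.0, labels, qc=("zero-variance-differences",))
    res = sps.ttest_rel(y, x)
    return StatResult("paired_t", float(res.statistic), n - 1,
                      float(res.pvalue), labels)


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None) -> StatResult:
    """Classical one-way fixed-effects ANOVA (F = MSbetween / MSwithin)."""
    gs = _check_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    res = sps.f_oneway(*gs)
    f = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(f):  # all values identical -> no variance anywhere
        f, p = 0.0, 1.0
    elif f < 0 or math.isnan(p):
        # between-group sum of squares cancelled to a tiny negative value
        f = max(f, 0.0)
        p = float(sps.f.sf(f, k - 1, n_total - k))
    return StatResult("anova", f, (k - 1, n_total - k), p,
                      tuple(labels) if labels else ("omnibus",))


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None) -> list[StatResult]:
    """All pairwise Tukey HSD comparisons (Tukey-Kramer for unequal n)."""
    gs = _check_groups(groups)
    labels = list(labels) if labels else [f"g{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels/groups length mismatch")
    n_total = sum(g.size for g in gs)
    k = len(gs)
    dfw = n_total - k
    ms_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs) / dfw
    res = sps.tukey_hsd(*gs)
    out = []
    for i, j in combinations(range(k), 2):
        if ms_within == 0:
            diff = abs(gs[i].mean() - gs[j].mean())
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(gs[i].mean() - gs[j].mean()) / math.sqrt(
                ms_within * (1.0 / gs[i].size + 1.0 / gs[j].size) / 2.0)
            p = float(res.pvalue[i, j])
        out.append(StatResult("tukey", q, dfw, p, (labels[i], labels[j])))
    return out


def anova_from_summary(summaries: Sequence[GroupSummary],
                       ) -> tuple[StatResult, list[StatResult]]:
    """Omnibus ANOVA and Tukey HSD from per-group (n, mean, SEM) summaries.

    Reconstructs ``s_i^2 = sem_i^2 * n_i``, ``SSwithin = sum (n_i-1) s_i^2``
    and ``SSbetween = sum n_i (m_i - grand mean)^2``; results are identical
    to the raw-data routes on any data having these summaries.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 group summaries")
    for s in summaries:
        if s.n < 2:
            raise ValueError(f"group {s.label!r} has n < 2; inference unavailable")
    k = len(summaries)
    n_total = sum(s.n for s in summaries)
    grand = sum(s.n * s.mean for s in summaries) / n_total
    ss_between = sum(s.n * (s.mean - grand) ** 2 for s in summaries)
    ss_within = sum((s.n - 1) * s.variance for s in summaries)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    omnibus = StatResult("anova", f, (df_b, df_w), p,
                         tuple(s.label for s in summaries))
    pairs = []
    for a, b in combinations(summaries, 2):
        if ms_w == 0:
            diff = abs(a.mean - b.mean)
            q = 0.0 if diff == 0 else math.inf
            p_q = 1.0 if diff == 0 else 0.0
        else:
            q = abs(a.mean - b.mean) / math.sqrt(
                ms_w * (1.0 / a.n + 1.0 / b.n) / 2.0)
            p_q = float(sps.studentized_range.sf(q, k, df_w))
        pairs.append(StatResult("tukey", q, df_w, p_q, (a.label, b.label)))
    return omnibus, pairs
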