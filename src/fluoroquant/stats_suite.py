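"""One-way ANOVA, the Student-Newman-Keuls step-down procedure with compact
letter display, Pearson correlation, and mean +/- SE aggregation.

The ANOVA decomposition, the SNK step-down logic, the letter assignment,
Pearson's r and the SE formula are implemented here directly; only the
reference distributions (F, studentized range) come from :mod:`scipy.stats`.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ZeroVarianceError,
)

__all__ = [
    "GroupSample",
    "AnovaResult",
    "SnkComparison",
    "SnkResult",
    "CorrelationResult",
    "one_way_anova",
    "studentized_range_quantile",
    "snk_test",
    "pearson",
    "mean_se",
]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of real observations from one treatment group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InsufficientDataError(f"group {self.label!r}: values must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise InsufficientDataError(f"group {self.label!r}: non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    ms_between: float

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "ms_within": self.ms_within,
            "ms_between": self.ms_between,
        }


@dataclass(frozen=True)
class SnkComparison:
    """One pairwise comparison from the step-down procedure.

    ``tested`` is False when the pair lies inside a span already accepted as
    homogeneous, in which case the step-down rule forbids testing it and the
    pair is declared non-significant by implication.
    """

    high_label: str
    low_label: str
    span: int
    q_stat: float | None
    q_critical: float | None
    significant: bool
    tested: bool


@dataclass(frozen=True)
class SnkResult:
    labels: tuple[str, ...]          # sorted by descending mean
    ordered_means: tuple[float, ...]
    comparisons: tuple[SnkComparison, ...]
    letters: Mapping[str, str]       # label -> compact letter display
    alpha: float
    ms_within: float
    df_within: int
    n_effective: float
    used_harmonic_n: bool

    def same_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "ordered_means": list(self.ordered_means),
            "letters": dict(self.letters),
            "alpha": self.alpha,
            "ms_within": self.ms_within,
            "df_within": self.df_within,
            "n_effective": self.n_effective,
            "used_harmonic_n": self.used_harmonic_n,
            "comparisons": [
                {
                    "high": c.high_label,
                    "low": c.low_label,
                    "span": c.span,
                    "q_stat": c.q_stat,
                    "q_critical": c.q_critical,
                    "significant": c.significant,
                    "tested": c.tested,
                }
                for c in self.comparisons
            ],
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n}


def _check_groups(groups: Sequence[GroupSample]) -> None:
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(
                f"group {g.label!r} has n={g.n}; variance-based procedures need n >= 2"
            )


def one_way_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    Between/within sums of squares are computed directly; the p-value comes
    from the F distribution. Zero within-group variance with equal group
    means leaves F undefined and raises :class:`DegenerateDataError`; zero
    within-group variance with unequal means yields ``F = inf, p = 0``.
    """
    _check_groups(groups)
    k = len(groups)
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    n_total = int(ns.sum())
    grand = float(np.concatenate([g.values for g in groups]).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g.values - g.mean) ** 2) for g in groups))
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0.0:
        if ss_between == 0.0:
            raise DegenerateDataError(
                "all observations identical: F statistic undefined"
            )
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(_sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(f_stat, df_between, df_within, p, ms_within, ms_between)


def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Upper-tail quantile of the studentized range: q with P(Q_{k,df} > q) = p."""
    if not 0.0 < p < 1.0:
        raise InsufficientDataError(f"tail probability must be in (0, 1), got {p}")
    if k < 2:
        raise InsufficientDataError(f"span size must be >= 2, got {k}")
    if df < 1:
        raise InsufficientDataError(f"error df must be >= 1, got {df}")
    q = float(_sps.studentized_range.ppf(1.0 - p, k, df))
    if not np.isfinite(q) or q <= 0:
        raise DegenerateDataError(
            f"studentized-range quantile did not converge for p={p}, k={k}, df={df}"
        )
    return q


def _letters_from_intervals(k: int, intervals: list[tuple[int, int]]) -> list[str]:
    # Keep maximal homogeneous rank intervals only, then letter them in rank order.
    maximal = [
        iv
        for iv in intervals
        if not any(
            other != iv and other[0] <= iv[0] and iv[1] <= other[1]
            for other in intervals
        )
    ]
    maximal.sort()
    alphabet = string.ascii_lowercase
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(maximal):
        sym = alphabet[idx % 26] * (idx // 26 + 1)
        for rank in range(a, b + 1):
            letters[rank] += sym
    return letters


def snk_test(groups: Sequence[GroupSample], alpha: float = 0.05) -> SnkResult:
    """Student-Newman-Keuls step-down multiple comparison with letter display.

    Means are sorted descending (ties keep input order); spans are tested
    largest-first against ``q(alpha, span, df_within) * sqrt(ms_within / n)``.
    Once a span is accepted as homogeneous no pair inside it is tested.
    Unequal group sizes fall back to the harmonic mean n (Kramer adjustment)
    with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise InsufficientDataError(f"alpha must be in (0, 1), got {alpha}")
    _check_groups(groups)
    anova = one_way_anova(groups)  # propagates degeneracies
    ms_within, df_within = anova.ms_within, anova.df_within

    ns = np.array([g.n for g in groups], dtype=float)
    if np.all(ns == ns[0]):
        n_eff, harmonic = float(ns[0]), False
    else:
        n_eff = float(len(ns) / np.sum(1.0 / ns))
        harmonic = True
        warnings.warn(
            "unequal group sizes: SNK uses the harmonic mean n (Kramer adjustment)",
            stacklevel=2,
        )

    means = np.array([g.mean for g in groups])
    order = np.argsort(-means, kind="stable")  # descending, ties in input order
    labels = tuple(groups[i].label for i in order)
    sorted_means = means[order]
    k = len(groups)
    se = float(np.sqrt(ms_within / n_eff))

    comparisons: list[SnkComparison] = []
    accepted: list[tuple[int, int]] = []  # homogeneous rank intervals
    significant = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        crit = studentized_range_quantile(alpha, span, df_within)
        for i in range(0, k - span + 1):
            j = i + span - 1
            inside = any(a <= i and j <= b for a, b in accepted)
            if inside:
                comparisons.append(
                    SnkComparison(labels[i], labels[j], span, None, None, False, False)
                )
                continue
            diff = float(sorted_means[i] - sorted_means[j])
            if se > 0:
                q_stat = diff / se
            else:  # zero pooled error: any difference is infinitely significant
                q_stat = float("inf") if diff > 0 else 0.0
            sig = q_stat > crit
            comparisons.append(
                SnkComparison(labels[i], labels[j], span, q_stat, crit, sig, True)
            )
            if sig:
                significant[i, j] = True
            else:
                accepted.append((i, j))

    intervals: list[tuple[int, int]] = []
    for i in range(k):
        reach = i
        for j in range(k - 1, i, -1):
            if not significant[i, j]:
                reach = j
                break
        intervals.append((i, reach))
    letters_by_rank = _letters_from_intervals(k, intervals)
    letters = {labels[r]: letters_by_rank[r] for r in range(k)}

    return SnkResult(
        labels=labels,
        ordered_means=tuple(float(m) for m in sorted_means),
        comparisons=tuple(comparisons),
        letters=letters,
        alpha=alpha,
        ms_within=ms_within,
        df_within=df_within,
        n_effective=n_eff,
        used_harmonic_n=harmonic,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation of two paired sequences."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InsufficientDataError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise InsufficientDataError("non-finite values in correlation input")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("correlation undefined: a variable has zero variance")
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    return CorrelationResult(r=float(np.clip(r, -1.0, 1.0)), n=int(xa.size))


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n))."""
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise InsufficientDataError("mean_se needs at least 2 observations")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))
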