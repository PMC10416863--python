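"""Group comparison statistics.

One-way ANOVA with the efficiency group as the main effect, pooled-variance
Student's t mean separation with letter display (a = highest mean),
arcsine-square-root transformation for percentage variables, pooled
SEM / CV summaries, and Pearson correlation between fitted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsInputError(ValueError):
    """The grouped data cannot support the requested statistic."""


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float  # within-group mean square


@dataclass
class GroupComparison:
    """One compared variable: per-group means, pooled SEM, CV (%), ANOVA p,
    and mean-separation letters (groups sharing a letter do not differ)."""

    variable: str
    age: int | None
    means: dict[str, float]
    sem: float
    cv: float
    p_value: float
    letters: dict[str, str]


def arcsine_sqrt(p) -> float | np.ndarray:
    """Arcsine-square-root transform of a percentage: asin(sqrt(p/100)), radians."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise StatsInputError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard between/within decomposition.

    For exactly two groups F equals the square of the pooled-variance t
    statistic.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise StatsInputError("need at least 2 groups")
    for name, v in groups.items():
        if v.size < 2:
            raise StatsInputError(f"group {name!r} has n < 2")
    arrays = list(groups.values())
    n_total = sum(v.size for v in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays)
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays)
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0.0:
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), p=p, df_between=df_b, df_within=df_w, mse=float(mse))


def _pairwise_p(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance Student's t, two-sided."""
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def mean_separation(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Letter display from all pairwise pooled-t comparisons.

    Groups are ordered by descending mean ('a' = highest); every maximal
    contiguous run of groups in which no pair differs at ``alpha`` shares
    one letter.  Two groups share at least one letter iff they are not
    significantly different.
    """
    groups = _as_groups(values_by_group)
    names = sorted(groups, key=lambda g: -float(groups[g].mean()))
    k = len(names)
    differs = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            p = _pairwise_p(groups[names[i]], groups[names[j]])
            differs[i, j] = differs[j, i] = p < alpha

    # maximal contiguous intervals with no internal significant difference
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not differs[i: j + 2, i: j + 2].any():
            j += 1
        intervals.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in dict.fromkeys(intervals)
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in intervals)
    ]
    letters = {name: "" for name in names}
    for letter_idx, (i, j) in enumerate(sorted(maximal)):
        ch = chr(ord("a") + letter_idx)
        for m in range(i, j + 1):
            letters[names[m]] += ch
    return letters


def summarize(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Per-group means plus pooled SEM and CV.

    Pooled ``SEM = sqrt(MSE / n_harmonic)`` with the harmonic mean of group
    sizes; ``CV = 100 * sqrt(MSE) / grand mean`` (%).  A zero within-group
    variance yields SEM = 0 with a flag; a zero grand mean makes CV
    undefined.
    """
    groups = _as_groups(values_by_group)
    anova = one_way_anova(groups)
    grand = np.concatenate(list(groups.values())).mean()
    if grand == 0.0:
        raise StatsInputError("zero grand mean: CV undefined")
    n_harm = len(groups) / sum(1.0 / v.size for v in groups.values())
    sem = math.sqrt(anova.mse / n_harm)
    return {
        "means": {k: float(v.mean()) for k, v in groups.items()},
        "sem": sem,
        "cv": 100.0 * math.sqrt(anova.mse) / abs(float(grand)),
        "mse": anova.mse,
        "zero_variance": anova.mse == 0.0,
    }


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    variable: str,
    age: int | None = None,
    alpha: float = 0.05,
    percentage: bool = False,
) -> GroupComparison:
    """Full Table-style comparison of one variable between groups.

    Percentage variables are arcsine-square-root transformed for the test
    and the letters while the displayed means, SEM and CV stay on the raw
    percent scale.
    """
    raw = _as_groups(values_by_group)
    tested = {k: arcsine_sqrt(v) for k, v in raw.items()} if percentage else raw
    anova = one_way_anova(tested)
    letters = mean_separation(tested, alpha=alpha)
    summ = summarize(raw)
    return GroupComparison(
        variable=variable,
        age=age,
        means=summ["means"],
        sem=summ["sem"],
        cv=summ["cv"],
        p_value=anova.p,
        letters=letters,
    )


def correlate_estimates(param_a, param_b) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value."""
    a = np.asarray(param_a, dtype=float)
    b = np.asarray(param_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsInputError("need two equal-length 1-D vectors")
    if a.size < 3:
        raise StatsInputError("need n >= 3 for a correlation p-value")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise StatsInputError("zero variance: correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
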