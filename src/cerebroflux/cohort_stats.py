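"""Group-level descriptive summaries and nonparametric tests.

Summaries are medians with interquartile ranges (quartiles by linear
interpolation between order statistics) plus the unscaled median absolute
deviation used as an error bar.  Inference follows the study's scheme: a
Shapiro-Wilk screen is reported descriptively, but the pipeline is always
nonparametric -- Wilcoxon rank-sum between the two arms at each timepoint and
Wilcoxon signed-rank within an arm against the T-30 reference.  Exact p-values
(full enumeration of rank assignments / sign patterns) are used whenever the
sample sizes permit and there are no ties; otherwise a mid-rank normal
approximation with tie and continuity corrections is used, and each result
records which branch produced it.  P-values are displayed to four decimals,
with full precision kept internally, and no multiplicity adjustment is applied
across timepoints (each timepoint is flagged at two-sided 0.05 on its own).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .autoregulation_indices import OK, IndexSeries, cpp_series
from .experiment_model import CohortTable, Group, ValidationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "rank_sum_test",
    "signed_rank_test",
    "normality_screen",
    "compare_groups_over_time",
    "within_group_vs_baseline",
    "format_p",
]

RANK_SUM_EXACT_LIMIT = 16   # exact enumeration when n1 + n2 <= 16 and no ties
SIGNED_RANK_EXACT_LIMIT = 14  # exact enumeration when n <= 14 and no tied |d|


@dataclass(frozen=True)
class GroupSummary:
    """Median / IQR / MAD of one variable in one group at one timepoint."""

    variable: str
    group: str
    time: float
    n: int
    median: float
    q1: float
    q3: float
    mad: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``exact`` is True only when the p-value comes from full enumeration.
    ``n2`` is 0 for one-sample / paired tests; ``n_dropped`` counts zero
    differences removed before a signed-rank test.
    """

    method: str
    statistic: float
    p_two_sided: float
    exact: bool
    n1: int
    n2: int = 0
    n_dropped: int = 0


def format_p(p: float) -> str:
    """Render a p-value to exactly four decimals (half-up rounding)."""
    return str(Decimal(repr(float(p))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def _summary_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    med = float(np.median(values))
    q1 = float(np.percentile(values, 25))  # linear interpolation between order stats
    q3 = float(np.percentile(values, 75))
    mad = float(np.median(np.abs(values - med)))  # unscaled: error bar, not a sigma
    return med, q1, q3, mad


def summarize(
    cohort: CohortTable,
    variable: str,
    indices: Optional[dict[str, IndexSeries]] = None,
) -> list[GroupSummary]:
    """Per-(group, time) median, quartiles and MAD of a variable.

    ``variable`` is a raw channel (``pmap``, ``icp``, ``cvp``, ``hr``), the
    derived ``cpp``, or the name of a derived index supplied through
    ``indices`` (a mapping animal_id -> IndexSeries).  Missing values are
    excluded and ``n`` reports the count actually used.
    """
    per_animal: dict[str, tuple[Group, np.ndarray, np.ndarray]] = {}
    if indices is not None:
        group_of = {a.animal_id: a.group for a in cohort.animals}
        for animal_id, series in indices.items():
            if animal_id not in group_of:
                raise ValidationError(f"index series for unknown animal {animal_id!r}")
            vals = np.where(series.ok_mask, series.values, np.nan)
            per_animal[animal_id] = (group_of[animal_id], series.times, vals)
    elif variable.lower() == "cpp":
        for a in cohort.animals:
            s = cpp_series(a)
            vals = np.where(s.ok_mask, s.values, np.nan)
            per_animal[a.animal_id] = (a.group, s.times, vals)
    elif variable.lower() in ("pmap", "icp", "cvp", "hr"):
        for a in cohort.animals:
            per_animal[a.animal_id] = (a.group, a.times(), a.channel(variable.lower()))
    else:
        raise ValidationError(
            f"unknown variable {variable!r}; pass raw channel, 'cpp', or supply `indices`"
        )

    buckets: dict[tuple[Group, float], list[float]] = {}
    for _, (group, times, vals) in per_animal.items():
        for t, v in zip(times, vals):
            if not math.isnan(v):
                buckets.setdefault((group, float(t)), []).append(float(v))
    out = []
    for (group, t) in sorted(buckets, key=lambda k: (k[0].value, k[1])):
        vals = np.asarray(buckets[(group, t)])
        med, q1, q3, mad = _summary_stats(vals)
        out.append(GroupSummary(variable, group.value, t, len(vals), med, q1, q3, mad))
    return out


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    The statistic is the rank-sum of the first sample.  With no ties and
    combined size at most 16 the p-value is exact (full enumeration of rank
    assignments); otherwise a mid-rank normal approximation with tie
    correction and a directional continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test requires two nonempty samples")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)  # mid-ranks under ties
    w = float(ranks[:n1].sum())
    ties = _tie_counts(combined)
    if ties.size == 0 and n1 + n2 <= RANK_SUM_EXACT_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return TestResult("rank_sum", w, float(res.pvalue), True, n1, n2)
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float((ties**3 - ties).sum()) if ties.size else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    u1 = w - n1 * (n1 + 1) / 2.0
    diff = u1 - mean_u
    if var_u <= 0:
        return TestResult("rank_sum", w, 1.0, False, n1, n2)
    z = (diff - math.copysign(0.5, diff) if diff != 0 else 0.0) / math.sqrt(var_u)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("rank_sum", w, p, False, n1, n2)


def signed_rank_test(paired_diffs: Sequence[float]) -> TestResult:
    """One-sample Wilcoxon signed-rank test on paired differences, two-sided.

    Zero differences are dropped (counted in ``n_dropped``).  The statistic is
    the positive-rank sum W+.  With at most 14 usable differences and no tied
    absolute values the p-value is exact (enumeration of all sign patterns);
    otherwise the tie- and continuity-corrected normal approximation is used.
    All-zero input yields the degenerate result p = 1.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValidationError("signed_rank_test requires a nonempty sample")
    nonzero = d[d != 0.0]
    n_dropped = d.size - nonzero.size
    n = nonzero.size
    if n == 0:
        return TestResult("signed_rank", 0.0, 1.0, True, 0, 0, n_dropped)
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    ties = _tie_counts(np.abs(nonzero))
    if ties.size == 0 and n <= SIGNED_RANK_EXACT_LIMIT:
        res = sps.wilcoxon(nonzero, alternative="two-sided", method="exact")
        return TestResult("signed_rank", w_plus, float(res.pvalue), True, n, 0, n_dropped)
    mean_w = n * (n + 1) / 4.0
    tie_term = float((ties**3 - ties).sum()) if ties.size else 0.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    diff = w_plus - mean_w
    if var_w <= 0:
        return TestResult("signed_rank", w_plus, 1.0, False, n, 0, n_dropped)
    z = (diff - math.copysign(0.5, diff) if diff != 0 else 0.0) / math.sqrt(var_w)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("signed_rank", w_plus, p, False, n, 0, n_dropped)


def normality_screen(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality screen (descriptive only).

    The pipeline proceeds nonparametrically regardless of the outcome; the
    screen documents why.  Requires 3 <= n <= 5000.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    res = sps.shapiro(v)
    return TestResult("shapiro_wilk", float(res.statistic), float(res.pvalue), False, int(v.size))


def _values_by_group_time(
    cohort: CohortTable,
    variable: str,
    indices: Optional[dict[str, IndexSeries]],
) -> dict[float, dict[Group, np.ndarray]]:
    summaries_input: dict[float, dict[Group, list[float]]] = {}
    if indices is not None:
        group_of = {a.animal_id: a.group for a in cohort.animals}
        items = [(group_of[aid], s.times, np.where(s.ok_mask, s.values, np.nan))
                 for aid, s in indices.items()]
    elif variable.lower() == "cpp":
        items = []
        for a in cohort.animals:
            s = cpp_series(a)
            items.append((a.group, s.times, np.where(s.ok_mask, s.values, np.nan)))
    else:
        items = [(a.group, a.times(), a.channel(variable.lower())) for a in cohort.animals]
    for group, times, vals in items:
        for t, v in zip(times, vals):
            if not math.isnan(v):
                summaries_input.setdefault(float(t), {}).setdefault(group, []).append(float(v))
    return {
        t: {g: np.asarray(v) for g, v in d.items()} for t, d in sorted(summaries_input.items())
    }


def compare_groups_over_time(
    cohort: CohortTable,
    variable: str,
    indices: Optional[dict[str, IndexSeries]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum test NICPG vs EICPG at every gridded timepoint.

    Returns a DataFrame with the internal-precision p-value, its 4-decimal
    display form, the exact/approximate flag and a per-timepoint significance
    flag at two-sided ``alpha`` (no multiplicity adjustment, by design).
    """
    by_time = _values_by_group_time(cohort, variable, indices)
    rows = []
    for t, groups in by_time.items():
        if Group.NICPG not in groups or Group.EICPG not in groups:
            continue
        res = rank_sum_test(groups[Group.NICPG], groups[Group.EICPG])
        rows.append(
            {
                "variable": variable,
                "time_min": t,
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "p": res.p_two_sided,
                "p_4dp": format_p(res.p_two_sided),
                "exact": res.exact,
                "significant": res.p_two_sided < alpha,
            }
        )
    return pd.DataFrame(rows)


def within_group_vs_baseline(
    cohort: CohortTable,
    variable: str,
    group: Group | str,
    baseline_time: float = -30.0,
    indices: Optional[dict[str, IndexSeries]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed-rank test of each timepoint against the T-30 reference, one arm.

    Differences are paired within animal (value at t minus value at the
    baseline reference); animals missing either member of a pair are dropped
    at that timepoint.
    """
    group = Group.parse(group) if not isinstance(group, Group) else group
    if indices is not None:
        group_of = {a.animal_id: a.group for a in cohort.animals}
        items = [(aid, s.times, np.where(s.ok_mask, s.values, np.nan))
                 for aid, s in indices.items() if group_of[aid] is group]
    elif variable.lower() == "cpp":
        items = []
        for a in cohort.by_group(group):
            s = cpp_series(a)
            items.append((a.animal_id, s.times, np.where(s.ok_mask, s.values, np.nan)))
    else:
        items = [(a.animal_id, a.times(), a.channel(variable.lower()))
                 for a in cohort.by_group(group)]
    baselines: dict[str, float] = {}
    per_time: dict[float, dict[str, float]] = {}
    for aid, times, vals in items:
        for t, v in zip(times, vals):
            if math.isnan(v):
                continue
            if math.isclose(t, baseline_time):
                baselines[aid] = v
            per_time.setdefault(float(t), {})[aid] = v
    rows = []
    for t in sorted(per_time):
        if math.isclose(t, baseline_time):
            continue
        diffs = [v - baselines[aid] for aid, v in per_time[t].items() if aid in baselines]
        if not diffs:
            continue
        res = signed_rank_test(diffs)
        rows.append(
            {
                "variable": variable,
                "group": group.value,
                "time_min": t,
                "n": res.n1,
                "n_dropped": res.n_dropped,
                "statistic": res.statistic,
                "p": res.p_two_sided,
                "p_4dp": format_p(res.p_two_sided),
                "exact": res.exact,
                "significant": res.p_two_sided < alpha,
            }
        )
    return pd.DataFrame(rows)
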