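"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and, where practical, the libraries)
used by the package: the Pearson oracle is the raw sum-of-products formula,
and the Wilcoxon oracles enumerate every rank assignment / sign pattern.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence


def pearson_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r by the direct sum-of-products formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def rank_sum_exact_oracle(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n1+n2, n1) assignments.

    Assumes no ties.  p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    n1, n2 = len(a), len(b)
    combined = sorted(list(a) + list(b))
    assert len(set(combined)) == n1 + n2, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in a)
    sums = [sum(c) for c in itertools.combinations(range(1, n1 + n2 + 1), n1)]
    total = len(sums)
    p_le = sum(s <= w_obs for s in sums) / total
    p_ge = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_exact_oracle(diffs: Sequence[float]) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no tied absolute values.
    """
    d = [v for v in diffs if v != 0.0]
    n = len(d)
    mags = sorted(abs(v) for v in d)
    assert len(set(mags)) == n, "oracle requires tie-free absolute values"
    rank_of = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(rank_of[abs(v)] for v in d if v > 0)
    ranks = [rank_of[m] for m in mags]
    sums = []
    for signs in itertools.product((0, 1), repeat=n):
        sums.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(sums)
    p_le = sum(s <= w_obs for s in sums) / total
    p_ge = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
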