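"""Independent reference implementations used only to cross-check the package.

Everything here is written from the mathematical definitions, deliberately
not sharing code with the implementation under test: a literal per-cell
pairing-matrix evaluator, a classic Nussinov maximum-matching DP, and a
structure-counting recurrence.
"""

from __future__ import annotations

import math

WOBBLE = 0.8

_PAIR_WEIGHTS = {
    frozenset("AU"): 2.0,
    frozenset("GC"): 3.0,
}


def pair_weight(a: str, b: str, x: float = WOBBLE) -> float:
    key = frozenset((a, b))
    if key in _PAIR_WEIGHTS:
        return _PAIR_WEIGHTS[key]
    if key == frozenset("GU"):
        return x
    return 0.0


def naive_matrix(bases: str, x: float = WOBBLE, sigma: float = 1.0, t_max: int = 30):
    """Literal 1-based evaluation of the Gaussian stem-weighted matrix.

    The stem sums are direction-dependent, so the formula is evaluated on
    the i < j half (outward = towards the ends, inward = towards the
    diagonal) and mirrored — the matrix is symmetric by definition.
    """
    n = len(bases)

    def p(i: int, j: int) -> float:  # 1-based, 0 outside bounds
        if not (1 <= i <= n and 1 <= j <= n):
            return 0.0
        return pair_weight(bases[i - 1], bases[j - 1], x)

    def g(t: int) -> float:
        return math.exp(-(t**2) / (2.0 * sigma**2))

    w = [[0.0] * n for _ in range(n)]
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            if p(i, j) == 0.0:
                continue
            total = 0.0
            for t in range(0, t_max + 1):  # outward, includes the centre
                if i - t < 1 or j + t > n or p(i - t, j + t) == 0.0:
                    break
                total += g(t) * p(i - t, j + t)
            for t in range(1, t_max + 1):  # inward
                if i + t >= j - t or p(i + t, j - t) == 0.0:
                    break
                total += g(t) * p(i + t, j - t)
            w[i - 1][j - 1] = w[j - 1][i - 1] = total
    return w


def can_pair(a: str, b: str) -> bool:
    return frozenset((a, b)) in (frozenset("AU"), frozenset("GC"), frozenset("GU"))


def nussinov_max_pairs(bases: str, min_loop: int = 0) -> int:
    """Classic Nussinov DP: maximum number of nested allowed base pairs."""
    n = len(bases)
    dp = [[0] * n for _ in range(n)]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + 1, j + 1):  # i paired with k
                if k - i - 1 >= min_loop and can_pair(bases[i], bases[k]):
                    inside = dp[i + 1][k - 1] if k - 1 > i else 0
                    outside = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inside + outside)
            dp[i][j] = best
    return dp[0][n - 1] if n else 0


def count_structures(bases: str, min_loop: int = 3) -> int:
    """Number of valid nested structures, by the counting recurrence

    C(i, j) = C(i+1, j) + sum over admissible k of C(i+1, k-1) * C(k+1, j).
    """
    n = len(bases)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:  # 0-based closed interval
        if i >= j:
            return 1
        total = c(i + 1, j)
        for k in range(i + 1 + min_loop, j + 1):
            if can_pair(bases[i], bases[k]):
                total += c(i + 1, k - 1) * c(k + 1, j)
        return total

    return c(0, n - 1)
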