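"""Maximum probability sum decoding of per-base label probabilities.

Given per-base probabilities for the labels "(", ")" and ".", find the
valid nested secondary structure maximising the summed probability of each
base's assigned label.  This is a Nussinov-style interval dynamic program
in which the classic pair count is replaced by label probabilities:

    N(i, j) = max of
        N(i+1, j)   + p_point(R_i)                 (leave i unpaired)
        N(i, j-1)   + p_point(R_j)                 (leave j unpaired)
        N(i+1, j-1) + delta(R_i, R_j)              (close pair i.j)
        max over i < k < j of N(i, k) + N(k+1, j)  (bifurcation)

with delta = p_left(R_i) + p_right(R_j) when bases i, j form an allowed
pair (A-U, G-C, G-U) separated by at least ``min_loop`` unpaired bases, and
p_point(R_i) + p_point(R_j) otherwise.  Base cases: N(i, i) = p_point(R_i)
and N(i, j) = 0 for j < i.  Probabilities are taken as given (no internal
renormalisation), so any non-negative per-base scores work.

Traceback is deterministic: cases are tried in the order written above,
bifurcation at the smallest split point, first maximiser wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .structures import Structure, Sequence, labels_from_structure, Label

__all__ = [
    "FoldConfig",
    "FoldResult",
    "enumerate_structures",
    "mps_fold",
    "score_structure",
]

_DEFAULT_PAIRS = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)

# Traceback recomputes candidate scores with the same float operations the
# DP used, so the achieving case matches the stored maximum exactly; any
# nonzero slack could instead select a near-tied suboptimal case.
_EPS = 0.0


@dataclass(frozen=True)
class FoldConfig:
    """Structural constraints of the decoder.

    min_loop       minimum unpaired bases enclosed by a hairpin pair
                   (default 3; 0 gives the unconstrained recursion).
    allowed_pairs  admissible base combinations, symmetric.
    """

    min_loop: int = 3
    allowed_pairs: frozenset = _DEFAULT_PAIRS

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def can_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.allowed_pairs


@dataclass(frozen=True)
class FoldResult:
    """Optimal structure, its score N(1, n), and the filled DP table.

    ``table[i-1, j-1]`` holds N(i, j) for i <= j (upper triangle).
    """

    structure: Structure
    score: float
    table: np.ndarray


def _check_probs(seq: Sequence, probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (seq.n, 3):
        raise ValueError(
            f"probabilities shape {probs.shape} does not match (n, 3) = ({seq.n}, 3)"
        )
    return probs


def mps_fold(
    seq: Sequence, probs: np.ndarray, cfg: FoldConfig = FoldConfig()
) -> FoldResult:
    """Fold a sequence by maximising the summed label probability.

    ``probs`` is an (n, 3) array of (p_left, p_right, p_point) per base.
    """
    probs = _check_probs(seq, probs)
    n = seq.n
    pl, pr, pp = probs[:, 0], probs[:, 1], probs[:, 2]

    pairable = np.zeros((n, n), dtype=bool)  # 0-based, i<j
    for i in range(n):
        for j in range(i + 1 + cfg.min_loop, n):
            pairable[i, j] = cfg.can_pair(seq.bases[i], seq.bases[j])
    # delta matrix (0-based): paired score where admissible, else point+point
    delta = np.where(
        pairable, pl[:, None] + pr[None, :], pp[:, None] + pp[None, :]
    )

    # N with 0-based [i, j]; N[i, j] = 0 for j < i handled by zero init
    N = np.zeros((n + 1, n + 1))
    np.fill_diagonal(N, np.append(pp, 0.0))
    for span in range(2, n + 1):
        i = np.arange(0, n - span + 1)
        j = i + span - 1
        best = np.maximum(N[i + 1, j] + pp[i], N[i, j - 1] + pp[j])
        inner = N[i + 1, j - 1] if span > 2 else np.zeros_like(best)
        best = np.maximum(best, inner + delta[i, j])
        for off in range(1, span - 1):  # bifurcation at k = i + off
            best = np.maximum(best, N[i, i + off] + N[i + off + 1, j])
        N[i, j] = best

    pairs = _traceback(N, pp, delta, pairable, n)
    structure = Structure(pairs=frozenset(pairs), n=n)
    return FoldResult(structure=structure, score=float(N[0, n - 1]), table=N[:n, :n].copy())


def _traceback(
    N: np.ndarray,
    pp: np.ndarray,
    delta: np.ndarray,
    pairable: np.ndarray,
    n: int,
) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        if i == j:
            continue
        target = N[i, j]
        if N[i + 1, j] + pp[i] >= target - _EPS:
            stack.append((i + 1, j))
            continue
        if N[i, j - 1] + pp[j] >= target - _EPS:
            stack.append((i, j - 1))
            continue
        inner = N[i + 1, j - 1] if j - i >= 2 else 0.0
        if inner + delta[i, j] >= target - _EPS:
            if pairable[i, j]:
                pairs.add((i + 1, j + 1))  # report 1-based
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if N[i, k] + N[k + 1, j] >= target - _EPS:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP table and cases are exhaustive
            raise RuntimeError(f"traceback failed at interval ({i + 1}, {j + 1})")
    return pairs


def score_structure(
    seq: Sequence, probs: np.ndarray, s: Structure
) -> float:
    """Sum over bases of the probability of the label assigned by ``s``."""
    probs = _check_probs(seq, probs)
    if s.n != seq.n:
        raise ValueError(f"structure length {s.n} != sequence length {seq.n}")
    labels = labels_from_structure(s)
    return float(sum(probs[i, lab.value] for i, lab in enumerate(labels)))


def enumerate_structures(
    seq: Sequence, cfg: FoldConfig = FoldConfig(), guard: int = 16
) -> Iterator[Structure]:
    """Yield every valid nested structure of ``seq`` exactly once.

    Brute-force oracle for small n (guarded at ``guard`` bases): recursion
    on intervals — base i is either unpaired, or paired with some admissible
    k, splitting the interval into an inside and an outside part.
    """
    n = seq.n
    if n > guard:
        raise ValueError(f"enumeration guarded at n <= {guard}, got n = {n}")
    bases = seq.bases

    def rec(i: int, j: int) -> Iterator[frozenset]:
        # all pair sets on the 0-based closed interval [i, j]
        if i > j:
            yield frozenset()
            return
        # i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # i paired with k
        for k in range(i + 1 + cfg.min_loop, j + 1):
            if cfg.can_pair(bases[i], bases[k]):
                for inside in rec(i + 1, k - 1):
                    for outside in rec(k + 1, j):
                        yield inside | outside | {(i + 1, k + 1)}

    for pairset in rec(0, n - 1):
        yield Structure(pairs=frozenset(pairset), n=n)
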