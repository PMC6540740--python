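"""Base-pair-level evaluation of predicted structures.

Sensitivity is the fraction of reference pairs that are predicted (recall);
specificity — in the naming convention of the RNA structure prediction
literature — is the fraction of predicted pairs that are correct (precision
/ PPV, not the true-negative rate).  The F-score is their harmonic mean.
Matching is exact on (i, j) index pairs by default; an optional slip
tolerance accepts a predicted pair whose one endpoint is displaced by one
position, a convention some benchmarks use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence as PySequence

from .structures import Structure

__all__ = ["EvalReport", "PairCounts", "compare_pairs", "evaluate", "f_score"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCounts:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_score(self) -> float:
        return f_score(self.sensitivity, self.specificity)


def compare_pairs(
    predicted: Structure, reference: Structure, slip: bool = False
) -> PairCounts:
    """Count true/false positives and false negatives over base pairs.

    With ``slip`` a predicted pair (i, j) also matches a reference pair
    whose one index differs by 1 ((i±1, j) or (i, j±1)); each reference
    pair is consumed at most once.
    """
    if predicted.n != reference.n:
        raise ValueError(
            f"length mismatch: predicted n={predicted.n}, reference n={reference.n}"
        )
    pred, ref = set(predicted.pairs), set(reference.pairs)
    if not slip:
        tp = len(pred & ref)
        return PairCounts(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)
    remaining = set(ref)
    tp = 0
    for i, j in sorted(pred):
        for cand in ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if cand in remaining:
                remaining.discard(cand)
                tp += 1
                break
    return PairCounts(tp=tp, fp=len(pred) - tp, fn=len(remaining))


def f_score(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0)."""
    if sensitivity + specificity == 0:
        warnings.warn("both sensitivity and specificity are 0; F-score set to 0")
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


@dataclass(frozen=True)
class EvalReport:
    """Per-sequence counts plus pooled (micro) and averaged (macro) scores.

    Micro pools tp/fp/fn over the whole set before computing ratios; macro
    averages per-sequence sensitivities/specificities/F-scores.  Both are
    reported because published benchmark tables rarely say which they use.
    """

    per_sequence: tuple[PairCounts, ...]

    @property
    def pooled(self) -> PairCounts:
        return PairCounts(
            tp=sum(c.tp for c in self.per_sequence),
            fp=sum(c.fp for c in self.per_sequence),
            fn=sum(c.fn for c in self.per_sequence),
        )

    @property
    def micro(self) -> dict[str, float]:
        c = self.pooled
        return {
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "f_score": c.f_score,
        }

    @property
    def macro(self) -> dict[str, float]:
        m = len(self.per_sequence)
        if m == 0:
            return {"sensitivity": 0.0, "specificity": 0.0, "f_score": 0.0}
        return {
            "sensitivity": sum(c.sensitivity for c in self.per_sequence) / m,
            "specificity": sum(c.specificity for c in self.per_sequence) / m,
            "f_score": sum(c.f_score for c in self.per_sequence) / m,
        }


def evaluate(
    predicted: PySequence[Structure],
    reference: PySequence[Structure],
    slip: bool = False,
) -> EvalReport:
    """Pair-level evaluation of matched predicted/reference structure lists."""
    if len(predicted) != len(reference):
        raise ValueError(
            f"{len(predicted)} predictions vs {len(reference)} references"
        )
    return EvalReport(
        per_sequence=tuple(
            compare_pairs(p, r, slip=slip) for p, r in zip(predicted, reference)
        )
    )
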