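"""Synthetic sequence / structure / probability fixtures.

Every pipeline stage is testable offline: a recursive generator draws valid
nested structures with a tunable pairing density and minimum hairpin loop,
sequences are filled in to be fully compatible with their structure (with a
controllable fraction of G-U wobble pairs), and per-base label probability
tables are derived from the true labels with a single interpretable noise
knob epsilon (0 = exact one-hot, towards 1 = uninformative), roughened by
seeded Dirichlet jitter.  All draws are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DatasetRecord
from .structures import Sequence, Structure, labels_from_structure

__all__ = [
    "SynthConfig",
    "generate_dataset",
    "hairpin_record",
    "probs_from_structure",
    "random_structure",
    "sequence_for_structure",
]

# Dirichlet concentration of the probability jitter; high = mild roughening.
_DIRICHLET_CONC = 50.0

_WC_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_GU_PAIRS = [("G", "U"), ("U", "G")]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for synthetic data.

    n_range       inclusive sequence-length interval.
    min_loop      minimum unpaired bases inside a hairpin (steric default 3).
    pair_density  propensity to open a pair where feasible, in [0, 1].
    gu_fraction   fraction of paired positions drawn as G-U wobbles.
    label_noise   epsilon mixed away from the true one-hot label.
    seed          master seed; all draws derive from it.
    """

    n_range: tuple[int, int] = (40, 120)
    min_loop: int = 3
    pair_density: float = 0.55
    gu_fraction: float = 0.1
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad n_range {self.n_range}")
        for name in ("pair_density", "gu_fraction", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_structure(
    n: int,
    min_loop: int = 3,
    pair_density: float = 0.55,
    seed=0,
    stem_extend: float = 0.8,
    max_stem: int | None = None,
) -> Structure:
    """Draw a valid nested structure on n bases.

    Walks each interval left to right; at each position, with probability
    ``pair_density`` (if a feasible partner exists) opens a pair to a
    uniformly drawn partner at least ``min_loop + 1`` ahead and stacks
    further pairs onto it with probability ``stem_extend`` each (so helices
    have roughly geometric length, as in real structures), then recurses
    into the enclosed and the remaining interval.  ``max_stem`` caps helix
    length.  Validity is by construction.
    """
    rng = _rng(seed)
    pairs: set[tuple[int, int]] = set()
    cap = max_stem if max_stem is not None else n

    # intervals carry the length of the helix ending at (i-1, j+1), so a
    # nested pair opened exactly at the interval corners counts towards the
    # same stack and max_stem stays a strict bound
    stack = [(1, n, 0)]
    while stack:
        i, j, carry = stack.pop()
        while i <= j:
            lo = i + min_loop + 1
            if lo <= j and pair_density > 0 and rng.random() < pair_density:
                hi = j - 1 if carry >= cap else j
                if hi < lo:
                    i, carry = i + 1, 0
                    continue
                k = int(rng.integers(lo, hi + 1))
                run = carry if k == j else 0  # stacking onto the enclosing helix?
                pairs.add((i, k))
                s = 1  # stack the helix inward while feasible
                while (
                    run + s < cap
                    and (k - s) - (i + s) - 1 >= min_loop
                    and rng.random() < stem_extend
                ):
                    pairs.add((i + s, k - s))
                    s += 1
                if k + 1 <= j:
                    stack.append((k + 1, j, 0))
                i, j, carry = i + s, k - s, run + s  # descend inside
            else:
                i, carry = i + 1, 0
    return Structure(pairs=frozenset(pairs), n=n)


def hairpin_record(
    stem_len: int,
    loop_len: int = 4,
    flank: int = 0,
    gu_fraction: float = 0.0,
    seed=0,
    id: str = "hairpin",
) -> DatasetRecord:
    """A record with exactly one planted perfect hairpin stem.

    ``stem_len`` stacked pairs enclose ``loop_len`` unpaired bases, with
    ``flank`` unpaired bases on each side — ground truth for stem-length
    statistics and the stem signature of the encoding.
    """
    if stem_len < 1 or loop_len < 0 or flank < 0:
        raise ValueError("stem_len >= 1, loop_len >= 0, flank >= 0 required")
    n = 2 * stem_len + loop_len + 2 * flank
    pairs = frozenset(
        (flank + t + 1, n - flank - t) for t in range(stem_len)
    )
    s = Structure(pairs=pairs, n=n)
    seq = sequence_for_structure(s, gu_fraction=gu_fraction, seed=seed, id=id)
    return DatasetRecord(seq=seq, structure=s, family="hairpin")


def sequence_for_structure(
    s: Structure, gu_fraction: float = 0.1, seed=0, id: str = "synth"
) -> Sequence:
    """Fill bases compatible with a structure.

    Paired positions get a Watson-Crick pair with probability
    1 - gu_fraction and a G-U wobble otherwise; unpaired positions are
    uniform over A/U/G/C.
    """
    rng = _rng(seed)
    bases = [""] * s.n
    for i, j in sorted(s.pairs):
        pool = _GU_PAIRS if rng.random() < gu_fraction else _WC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        bases[i - 1], bases[j - 1] = a, b
    unpaired = [k for k in range(s.n) if not bases[k]]
    draws = rng.integers(0, 4, size=len(unpaired))
    for k, d in zip(unpaired, draws):
        bases[k] = "AUGC"[d]
    return Sequence(id=id, bases="".join(bases))


def probs_from_structure(s: Structure, label_noise: float = 0.0, seed=0) -> np.ndarray:
    """Per-base (p_left, p_right, p_point) centred on the true labels.

    Each base's triple puts 1 - epsilon on its true label and epsilon/2 on
    each other label, then (for epsilon > 0) is jittered by a Dirichlet
    draw concentrated around that target.  epsilon = 0 returns the exact
    one-hot encoding.
    """
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must be in [0, 1]")
    labels = np.array([lab.value for lab in labels_from_structure(s)])
    probs = np.full((s.n, 3), label_noise / 2.0)
    probs[np.arange(s.n), labels] = 1.0 - label_noise
    if label_noise == 0.0:
        return probs
    rng = _rng(seed)
    alpha = _DIRICHLET_CONC * probs + 1e-3
    jittered = np.vstack([rng.dirichlet(a) for a in alpha])
    return jittered / jittered.sum(axis=1, keepdims=True)


def generate_dataset(
    count: int, cfg: SynthConfig = SynthConfig(), family: str = "synthetic"
) -> list[DatasetRecord]:
    """Draw ``count`` compatible (sequence, structure) records."""
    rng = _rng(cfg.seed)
    lo, hi = cfg.n_range
    records = []
    for k in range(count):
        n = int(rng.integers(lo, hi + 1))
        s = random_structure(n, cfg.min_loop, cfg.pair_density, seed=rng)
        seq = sequence_for_structure(
            s, cfg.gu_fraction, seed=rng, id=f"{family}_{k:04d}"
        )
        records.append(DatasetRecord(seq=seq, structure=s, family=family))
    return records
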