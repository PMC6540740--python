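"""Pairing-matrix encoding of RNA sequences.

A sequence of length n becomes an n x n matrix W in which entry (i, j)
scores how plausibly bases i and j pair *as part of a contiguous stem*.
The base weight reflects hydrogen-bond count (A-U: 2, G-C: 3, G-U wobble:
a tunable x, default 0.8); each pairable (i, j) is then augmented by its
stem context: neighbouring pairs (i-t, j+t) outward and (i+t, j-t) inward
contribute with Gaussian weight g(t) = exp(-t^2 / (2 sigma^2)), each
direction truncated at the first offset that leaves the sequence, crosses
the diagonal, or hits a non-pairable combination.  A real stem therefore
shows up as an anti-diagonal ridge, highest in the stem interior.

Per-base model inputs are d-row sliding windows over W (centred on the
base's own row, zero-padded at the ends), resampled along the length axis
to a fixed L columns by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as PySequence

import numpy as np

from .structures import Sequence

__all__ = [
    "EncodingConfig",
    "PairingMatrix",
    "base_pair_weight",
    "encode_matrix",
    "encode_windows",
    "length_interp_matrix",
    "normalize_window",
    "slide_windows",
]

# Base-pair weights by hydrogen-bond count; G-U wobble weight is the knob x.
_AU, _GC = 2.0, 3.0


@dataclass(frozen=True)
class EncodingConfig:
    """Knobs of the pairing-matrix encoding.

    gu_weight       wobble-pair weight x, constrained to (0, 2); 0.8 is the
                    empirically best value reported for this encoding.
    gaussian_sigma  width of the stem-context Gaussian g(t).
    max_offset      hard truncation horizon T for the stem sums.
    window_height   d, rows per sliding window (odd; 11 suits 5S rRNA-scale
                    stems, 19 the longest stems of mixed-family data).
    target_length   L, columns after length normalization (mean sequence
                    length of the training family: 120 or 128).
    """

    gu_weight: float = 0.8
    gaussian_sigma: float = 1.0
    max_offset: int = 30
    window_height: int = 11
    target_length: int = 120

    def __post_init__(self) -> None:
        if not 0.0 < self.gu_weight < 2.0:
            raise ValueError(f"gu_weight must be in (0, 2), got {self.gu_weight}")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.max_offset < 1:
            raise ValueError("max_offset must be >= 1")
        if self.window_height < 1 or self.window_height % 2 == 0:
            raise ValueError(
                f"window_height must be odd and >= 1, got {self.window_height}"
            )
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")

    def to_dict(self) -> dict:
        return {
            "gu_weight": self.gu_weight,
            "gaussian_sigma": self.gaussian_sigma,
            "max_offset": self.max_offset,
            "window_height": self.window_height,
            "target_length": self.target_length,
        }


@dataclass(frozen=True)
class PairingMatrix:
    """The n x n stem-weighted pairing encoding of one sequence."""

    values: np.ndarray
    seq: Sequence

    @property
    def n(self) -> int:
        return self.seq.n


def base_pair_weight(a: str, b: str, x: float = 0.8) -> float:
    """Pairing weight between two bases: 2 (A-U), 3 (G-C), x (G-U), else 0."""
    pair = frozenset((a, b))
    if not pair <= frozenset("AUGC"):
        raise ValueError(f"invalid base in pair ({a!r}, {b!r})")
    if pair == frozenset("AU"):
        return _AU
    if pair == frozenset("GC"):
        return _GC
    if pair == frozenset("GU"):
        return float(x)
    return 0.0


def _weight_table(x: float) -> np.ndarray:
    """4x4 pair-weight lookup over base codes A=0, U=1, G=2, C=3."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = _AU
    w[2, 3] = w[3, 2] = _GC
    w[2, 1] = w[1, 2] = float(x)
    return w


_BASE_CODE = {"A": 0, "U": 1, "G": 2, "C": 3}


def encode_matrix(seq: Sequence, cfg: EncodingConfig = EncodingConfig()) -> PairingMatrix:
    """Build the symmetric n x n pairing matrix with Gaussian stem weighting.

    W[i, j] = 0 where bases i, j cannot pair; otherwise

        W[i, j] = sum_{t=0..} g(t) P(R_{i-t}, R_{j+t})   (outward)
                + sum_{t=1..} g(t) P(R_{i+t}, R_{j-t})   (inward)

    with g(t) = exp(-t^2 / (2 sigma^2)) and each directional sum stopping at
    the first offset whose indices leave [1, n], cross (i+t >= j-t inward),
    or whose pair weight P is zero, and never exceeding t = max_offset.
    """
    codes = np.fromiter((_BASE_CODE[b] for b in seq.bases), dtype=np.intp)
    n = len(codes)
    ptab = _weight_table(cfg.gu_weight)
    pmat = ptab[codes[:, None], codes[None, :]]  # P(R_i, R_j), 0-based

    g = np.exp(-np.arange(cfg.max_offset + 1) ** 2 / (2.0 * cfg.gaussian_sigma**2))
    w = np.zeros((n, n))
    ii, jj = np.nonzero(np.triu(pmat))  # includes diagonal; P there is 0 anyway
    for i, j in zip(ii, jj):
        total = 0.0
        # outward: (i-t, j+t); t=0 is the centre pair itself
        for t in range(cfg.max_offset + 1):
            a, b = i - t, j + t
            if a < 0 or b >= n:
                break
            p = pmat[a, b]
            if p == 0.0:
                break
            total += g[t] * p
        # inward: (i+t, j-t), t >= 1, stop before indices meet or cross
        for t in range(1, cfg.max_offset + 1):
            a, b = i + t, j - t
            if a >= b:
                break
            p = pmat[a, b]
            if p == 0.0:
                break
            total += g[t] * p
        w[i, j] = w[j, i] = total
    return PairingMatrix(values=w, seq=seq)


def slide_windows(matrix: PairingMatrix | np.ndarray, d: int) -> np.ndarray:
    """Per-base d x n sliding windows over the rows of W.

    Window k (1-based base index) holds rows k-(d-1)/2 .. k+(d-1)/2, the
    base's own row centred; rows outside the matrix are zero.  Returns an
    array of shape (n, d, n).
    """
    if d < 1 or d % 2 == 0:
        raise ValueError(f"window height d must be odd and >= 1, got {d}")
    w = matrix.values if isinstance(matrix, PairingMatrix) else np.asarray(matrix)
    n = w.shape[0]
    half = (d - 1) // 2
    padded = np.zeros((n + 2 * half, n))
    padded[half : half + n] = w
    return np.stack([padded[k : k + d] for k in range(n)])


def length_interp_matrix(n: int, L: int) -> np.ndarray:
    """(n, L) corner-aligned bilinear interpolation matrix.

    Right-multiplying a row vector of n samples by this matrix resamples it
    to L samples; columns sum to 1, so constants are preserved exactly.
    """
    m = np.zeros((n, L))
    if n == 1:
        m[0, :] = 1.0
        return m
    # target column c samples source coordinate c * (n-1) / (L-1)
    pos = np.linspace(0.0, n - 1.0, L) if L > 1 else np.array([0.0])
    lo = np.clip(np.floor(pos).astype(int), 0, n - 2)
    frac = pos - lo
    m[lo, np.arange(L)] = 1.0 - frac
    m[lo + 1, np.arange(L)] += frac
    return m


def normalize_window(window: np.ndarray, L: int) -> np.ndarray:
    """Resample a d x n window to d x L columns by bilinear interpolation."""
    window = np.asarray(window, dtype=float)
    return window @ length_interp_matrix(window.shape[1], L)


def encode_windows(
    seq: Sequence, cfg: EncodingConfig = EncodingConfig()
) -> np.ndarray:
    """Full encoding of one sequence: (n, d, L) normalized model inputs."""
    pm = encode_matrix(seq, cfg)
    wins = slide_windows(pm, cfg.window_height)
    interp = length_interp_matrix(seq.n, cfg.target_length)
    return wins @ interp


def encode_dataset(
    seqs: PySequence[Sequence], cfg: EncodingConfig = EncodingConfig()
) -> list[np.ndarray]:
    """Encode several sequences; one (n_i, d, L) array per sequence."""
    return [encode_windows(s, cfg) for s in seqs]
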