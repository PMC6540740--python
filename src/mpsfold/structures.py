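"""RNA sequences and nested secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` with 1-based indices
``i < j``; each base has at most one partner.  Structures without crossing
pairs (pseudoknots) round-trip through dot-bracket notation, the per-base
string over ``(``, ``)`` and ``.`` used throughout this package as the label
alphabet for structure prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

__all__ = [
    "Label",
    "MalformedStructureError",
    "Sequence",
    "Structure",
    "is_pseudoknotted",
    "labels_from_structure",
    "parse_dotbracket",
    "to_dotbracket",
]

_VALID_BASES = frozenset("AUGC")


class MalformedStructureError(ValueError):
    """Raised for unbalanced brackets, crossing pairs or index clashes."""


class Label(IntEnum):
    """Per-base structural class: an opening base, a closing base, or unpaired."""

    LEFT = 0
    RIGHT = 1
    POINT = 2

    @property
    def char(self) -> str:
        return "()."[self.value]


@dataclass(frozen=True)
class Sequence:
    """An RNA sequence over {A, U, G, C} with an identifier.

    ``T`` (and lowercase input) is normalised to the RNA alphabet on
    construction; any other character is rejected.  Indices are 1-based in
    all public interfaces.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        cleaned = self.bases.upper().replace("T", "U")
        bad = set(cleaned) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid base(s) {sorted(bad)}; "
                "expected A/U/G/C (T is accepted and mapped to U)"
            )
        if not cleaned:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "bases", cleaned)

    @property
    def n(self) -> int:
        return len(self.bases)

    def base(self, i: int) -> str:
        """The i-th base, 1-based."""
        return self.bases[i - 1]

    def __len__(self) -> int:
        return len(self.bases)


def is_pseudoknotted(pairs: Iterable[tuple[int, int]]) -> bool:
    """True iff two pairs (i,j), (k,l) cross: i < k < j < l.

    All-pairs O(p^2) check; p is small for realistic structures.
    """
    plist = sorted(pairs)
    for a, (i, j) in enumerate(plist):
        for k, l in plist[a + 1 :]:
            if k >= j:
                break
            if i < k < j < l:
                return True
    return False


@dataclass(frozen=True)
class Structure:
    """A set of base pairs on a sequence of length ``n``.

    Validates one-partner-per-index and, unless ``pseudoknotted`` is set,
    the nestedness (no crossing pairs) required for dot-bracket output.
    """

    pairs: frozenset[tuple[int, int]]
    n: int
    pseudoknotted: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(map(tuple, self.pairs)))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise MalformedStructureError(
                    f"pair ({i},{j}) out of range for n={self.n}"
                )
            if i in seen or j in seen:
                raise MalformedStructureError(
                    f"index in pair ({i},{j}) already paired"
                )
            seen.update((i, j))
        if not self.pseudoknotted and is_pseudoknotted(self.pairs):
            raise MalformedStructureError(
                "crossing pairs present; construct with pseudoknotted=True"
            )

    @property
    def partner(self) -> dict[int, int]:
        """Map index -> partner index (both directions)."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def parse_dotbracket(text: str) -> Structure:
    """Parse a dot-bracket string into a Structure by stack matching.

    Raises :class:`MalformedStructureError` with the offending 1-based
    position for unbalanced brackets or foreign characters.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise MalformedStructureError(
                    f"unmatched ')' at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise MalformedStructureError(
                f"invalid character {ch!r} at position {pos}"
            )
    if stack:
        raise MalformedStructureError(f"unmatched '(' at position {stack[-1]}")
    return Structure(pairs=frozenset(pairs), n=len(text))


def to_dotbracket(s: Structure) -> str:
    """Serialize a nested structure to dot-bracket notation."""
    if s.pseudoknotted:
        raise MalformedStructureError(
            "pseudoknotted structures have no dot-bracket serialization"
        )
    chars = ["."] * s.n
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def labels_from_structure(s: Structure) -> list[Label]:
    """Per-base labels LEFT/RIGHT/POINT matching the dot-bracket string."""
    return [
        {"(": Label.LEFT, ")": Label.RIGHT, ".": Label.POINT}[c]
        for c in to_dotbracket(s)
    ]
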