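"""File formats and dataset preparation.

Readers/writers for FASTA (via Biopython), CT (6-column), BPSEQ (3-column)
and dot-bracket record files, plus the preparation steps applied to a
training corpus: removal of identical/similar sequences, deletion of
pseudoknotted structures, stratified 7:2:1 train/validation/test splitting,
and the dataset statistics (maximum stem length, mean sequence length) that
drive the choice of window height d and target length L.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as PySequence

import edlib
import numpy as np
from Bio import SeqIO

from .structures import (
    MalformedStructureError,
    Sequence,
    Structure,
    is_pseudoknotted,
    parse_dotbracket,
    to_dotbracket,
)

__all__ = [
    "DatasetRecord",
    "FormatError",
    "dataset_stats",
    "filter_pseudoknots",
    "read_bpseq",
    "read_ct",
    "read_dotbracket_file",
    "read_fasta",
    "read_probs_tsv",
    "remove_redundant",
    "sequence_identity",
    "split_dataset",
    "write_ct",
    "write_dotbracket_file",
    "write_fasta",
    "write_probs_tsv",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed structure file (bad columns, asymmetric partners...)."""


@dataclass(frozen=True)
class DatasetRecord:
    seq: Sequence
    structure: Structure
    family: str = field(default="")

    def __post_init__(self) -> None:
        if self.seq.n != self.structure.n:
            raise ValueError(
                f"{self.seq.id}: sequence length {self.seq.n} != structure "
                f"length {self.structure.n}"
            )


# ------------------------------------------------------------ file formats


def read_fasta(path) -> list[Sequence]:
    """Sequences from a FASTA file, normalised to the A/U/G/C alphabet."""
    seqs = [Sequence(id=rec.id, bases=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        logger.warning("no records in FASTA file %s", path)
    return seqs


def write_fasta(seqs: Iterable[Sequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.bases}\n")


def _pairs_from_partner(partners: dict[int, int], path) -> frozenset:
    pairs = set()
    for i, j in partners.items():
        if j == 0:
            continue
        if partners.get(j, -1) != i:
            raise FormatError(
                f"{path}: partner asymmetry between lines for bases {i} and {j} "
                f"({i} -> {j} but {j} -> {partners.get(j)})"
            )
        if i < j:
            pairs.add((i, j))
    return frozenset(pairs)


def read_ct(path, family: str = "") -> DatasetRecord:
    """One record from a standard 6-column CT file (0 partner = unpaired)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad CT header {lines[0]!r}") from exc
    title = " ".join(header[1:]) or path.stem
    bases: list[str] = []
    partners: dict[int, int] = {}
    for lineno, ln in enumerate(lines[1 : n + 1], start=2):
        cols = ln.split()
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 CT columns, got {len(cols)}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        if idx != len(bases) + 1:
            raise FormatError(f"{path}:{lineno}: base index {idx} out of order")
        if not 0 <= partner <= n:
            raise FormatError(f"{path}:{lineno}: partner {partner} exceeds n={n}")
        bases.append(base)
        partners[idx] = partner
    if len(bases) != n:
        raise FormatError(f"{path}: header says {n} bases, found {len(bases)}")
    pairs = _pairs_from_partner(partners, path)
    pk = is_pseudoknotted(pairs)
    return DatasetRecord(
        seq=Sequence(id=title, bases="".join(bases)),
        structure=Structure(pairs=pairs, n=n, pseudoknotted=pk),
        family=family,
    )


def write_ct(record: DatasetRecord, path) -> None:
    partner = record.structure.partner
    n = record.seq.n
    with open(path, "w") as fh:
        fh.write(f"{n} {record.seq.id}\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i} {record.seq.base(i)} {i - 1} {(i + 1) % (n + 1)} "
                f"{partner.get(i, 0)} {i}\n"
            )


def read_bpseq(path, family: str = "") -> DatasetRecord:
    """One record from a 3-column BPSEQ file (index, base, partner)."""
    path = Path(path)
    bases: list[str] = []
    partners: dict[int, int] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 BPSEQ columns")
        idx, base, partner = int(cols[0]), cols[1], int(cols[2])
        if idx != len(bases) + 1:
            raise FormatError(f"{path}:{lineno}: base index {idx} out of order")
        bases.append(base)
        partners[idx] = partner
    if not bases:
        raise FormatError(f"{path}: empty BPSEQ file")
    n = len(bases)
    if any(p > n for p in partners.values()):
        raise FormatError(f"{path}: partner index exceeds n={n}")
    pairs = _pairs_from_partner(partners, path)
    return DatasetRecord(
        seq=Sequence(id=path.stem, bases="".join(bases)),
        structure=Structure(pairs=pairs, n=n, pseudoknotted=is_pseudoknotted(pairs)),
        family=family,
    )


def read_dotbracket_file(path, family: str = "") -> list[DatasetRecord]:
    """Records of the form ``>id`` / sequence line / structure line."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        logger.warning("empty dot-bracket file %s", path)
        return []
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>id' line, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {lines[i]!r}")
        seq = Sequence(id=lines[i][1:].split()[0], bases=lines[i + 1])
        structure = parse_dotbracket(lines[i + 2])
        records.append(DatasetRecord(seq=seq, structure=structure, family=family))
        i += 3
    return records


def write_dotbracket_file(records: Iterable[DatasetRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f">{rec.seq.id}\n{rec.seq.bases}\n{to_dotbracket(rec.structure)}\n"
            )


def write_probs_tsv(rows: Iterable[tuple], path) -> None:
    """Per-base probability table: id, position, base, p_left, p_right, p_point."""
    with open(path, "w") as fh:
        fh.write("id\tposition\tbase\tp_left\tp_right\tp_point\n")
        for rid, pos, base, pl, pr, pp in rows:
            fh.write(f"{rid}\t{pos}\t{base}\t{pl:.6f}\t{pr:.6f}\t{pp:.6f}\n")


def read_probs_tsv(path) -> dict[str, np.ndarray]:
    """Read a probability table back into per-id (n, 3) arrays."""
    per_id: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise FormatError(f"{path}: missing probability TSV header")
        for lineno, ln in enumerate(fh, start=2):
            if not ln.strip():
                continue
            cols = ln.rstrip("\n").split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            per_id.setdefault(cols[0], []).append(
                (int(cols[1]), float(cols[3]), float(cols[4]), float(cols[5]))
            )
    out = {}
    for rid, rows in per_id.items():
        rows.sort()
        out[rid] = np.array([[pl, pr, pp] for _, pl, pr, pp in rows])
    return out


# ------------------------------------------------------ dataset preparation


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - editDistance / max(len)."""
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def remove_redundant(
    records: PySequence[DatasetRecord], identity_threshold: float = 1.0
) -> list[DatasetRecord]:
    """Drop identical (and, below threshold 1.0, similar) sequences.

    Greedy keep-first pass in input order: a record is dropped if its
    sequence is identical to an already-kept one, or (when the threshold is
    below 1.0) if its alignment identity to any kept sequence reaches the
    threshold.  Deterministic given input order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    kept: list[DatasetRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.seq.bases in seen:
            continue
        if identity_threshold < 1.0 and any(
            sequence_identity(rec.seq.bases, k.seq.bases) >= identity_threshold
            for k in kept
        ):
            continue
        kept.append(rec)
        seen.add(rec.seq.bases)
    return kept


def filter_pseudoknots(
    records: PySequence[DatasetRecord],
) -> list[DatasetRecord]:
    """Keep only records with nested (pseudoknot-free) structures.

    Logs a per-family before/after count table.
    """
    kept = [r for r in records if not is_pseudoknotted(r.structure.pairs)]
    before = Counter(r.family for r in records)
    after = Counter(r.family for r in kept)
    for fam in sorted(before):
        logger.info(
            "pseudoknot filter: family %s %d -> %d", fam or "-", before[fam], after[fam]
        )
    return kept


def split_dataset(
    records: PySequence[DatasetRecord],
    ratios: tuple[float, float, float] = (7, 2, 1),
    seed: int = 0,
    stratify_by_family: bool = True,
) -> tuple[list[DatasetRecord], list[DatasetRecord], list[DatasetRecord]]:
    """Disjoint exhaustive train/validation/test split at the given ratios.

    Within each stratum records are shuffled (seeded) and part sizes chosen
    by largest remainder, so 100 records at 7:2:1 give exactly (70, 20, 10).
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(records) < len(ratios):
        raise ValueError(
            f"cannot split {len(records)} records into {len(ratios)} parts"
        )
    rng = np.random.default_rng(seed)
    strata: dict[str, list[DatasetRecord]] = {}
    for rec in records:
        strata.setdefault(rec.family if stratify_by_family else "", []).append(rec)
    parts: tuple[list, list, list] = ([], [], [])
    total = sum(ratios)
    for fam in sorted(strata):
        group = list(strata[fam])
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        exact = [len(group) * r / total for r in ratios]
        sizes = [int(e) for e in exact]
        rema = sorted(
            range(3), key=lambda k: (exact[k] - sizes[k], ratios[k]), reverse=True
        )
        for k in rema[: len(group) - sum(sizes)]:
            sizes[k] += 1
        pos = 0
        for part, size in zip(parts, sizes):
            part.extend(group[pos : pos + size])
            pos += size
    return parts


def max_stem_length(structure: Structure) -> int:
    """Longest run of stacked pairs (i,j), (i+1,j-1), ... in a structure."""
    pairs = set(structure.pairs)
    best = 0
    for i, j in pairs:
        if (i - 1, j + 1) in pairs:
            continue  # not a stem start
        run = 1
        while (i + run, j - run) in pairs:
            run += 1
        best = max(best, run)
    return best


def dataset_stats(records: PySequence[DatasetRecord]) -> dict:
    """Corpus statistics guiding the encoding configuration.

    Returns the maximum stem length (window height candidate d), the mean
    sequence length rounded to the nearest integer (target length L), and a
    per-family histogram of sequence lengths.
    """
    if not records:
        return {"max_stem_length": 0, "mean_sequence_length": 0, "length_histograms": {}}
    hist: dict[str, Counter] = {}
    for rec in records:
        hist.setdefault(rec.family, Counter())[rec.seq.n] += 1
    return {
        "max_stem_length": max(max_stem_length(r.structure) for r in records),
        "mean_sequence_length": round(
            float(np.mean([r.seq.n for r in records]))
        ),
        "length_histograms": hist,
    }
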