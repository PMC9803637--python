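"""Detection of perfect trinucleotide-repeat tracts and read classification.

A "tract of n nt" is any n-nt window of the infinite repetition of a 3-nt
unit, in any phase — so a 10-nt tract like ``GCAGCAGCAG`` counts as a CAG
tract even though 10 is not a multiple of 3.  Reads are classified once
each, into the length class of their longest tract, mirroring how expanded
CAG-repeat reads are binned by repeat length in small-RNA and RNA-seq
libraries from repeat-expansion disease samples.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

_VALID = set("ACGTUN")


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert to the internal DNA alphabet (U -> T).

    Raises ``ValueError`` on characters outside ``{A,C,G,T,U,N}``.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"non-nucleotide characters {sorted(bad)} in sequence "
            f"(expected A/C/G/T/U/N): {sequence[:40]!r}"
        )
    return seq


@dataclass(frozen=True)
class RepeatTract:
    """A maximal perfect repeat tract within a sequence.

    ``phase`` is the offset into ``unit`` at which the tract starts, so the
    tract substring equals the infinite repetition of ``unit`` read from
    ``unit[phase]`` onward.
    """

    unit: str
    start: int
    length_nt: int
    phase: int

    @property
    def end(self) -> int:
        return self.start + self.length_nt


@dataclass(frozen=True)
class ReadRecord:
    """A (possibly collapsed) sequencing read with multiplicity."""

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")


@dataclass
class ReadClassTable:
    """Per-tract-length read totals; each read counted once at its longest class."""

    unit: str
    min_len: int
    max_len: int
    class_counts: dict[int, int] = field(default_factory=dict)
    unclassified: int = 0

    @property
    def total(self) -> int:
        return sum(self.class_counts.values()) + self.unclassified

    def to_rows(self) -> list[tuple[int, int, float]]:
        """(class_nt, read_count, fraction) rows for every class in range."""
        total = self.total
        return [
            (n, self.class_counts.get(n, 0),
             self.class_counts.get(n, 0) / total if total else 0.0)
            for n in range(self.min_len, self.max_len + 1)
        ]


def longest_repeat_tract(sequence: str, unit: str) -> RepeatTract | None:
    """Find the longest perfect tract of ``unit`` in ``sequence``.

    The tract may start at any phase of the unit.  Ties are broken by the
    smallest start offset.  Returns ``None`` when no tract of at least 3 nt
    exists.  ``N`` never extends a tract.
    """
    if len(unit) != 3:
        raise ValueError(f"unit must be a triplet, got {unit!r}")
    seq = normalize_sequence(sequence)
    u = normalize_sequence(unit)
    n = len(seq)
    best: RepeatTract | None = None
    # Phase class p: position i matches iff seq[i] == u[(i + p) % 3].
    for p in range(3):
        run_start = None
        for i in range(n + 1):
            ok = i < n and seq[i] == u[(i + p) % 3]
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                length = i - run_start
                if length >= 3 and (
                    best is None
                    or length > best.length_nt
                    or (length == best.length_nt and run_start < best.start)
                ):
                    best = RepeatTract(u, run_start, length, (run_start + p) % 3)
                run_start = None
    return best


def classify_reads(
    reads: Iterable[ReadRecord],
    unit: str,
    min_len: int = 10,
    max_len: int = 50,
) -> ReadClassTable:
    """Bin reads by longest-tract length, clamped to ``max_len``.

    Each read contributes its multiplicity to exactly one class (the length
    of its longest tract) or to ``unclassified`` when that length is below
    ``min_len``; totals are conserved exactly.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    table = ReadClassTable(unit=unit, min_len=min_len, max_len=max_len)
    for read in reads:
        tract = longest_repeat_tract(read.sequence, unit)
        length = tract.length_nt if tract else 0
        if length < min_len:
            table.unclassified += read.count
        else:
            cls = min(length, max_len)
            table.class_counts[cls] = table.class_counts.get(cls, 0) + read.count
    return table


def is_pure_repeat(sequence: str, unit: str) -> bool:
    """True iff the sequence equals a prefix of the phase-0 infinite repetition."""
    seq = normalize_sequence(sequence)
    u = normalize_sequence(unit)
    return all(seq[i] == u[i % 3] for i in range(len(seq)))


def count_pure_repeat_reads(
    reads: Iterable[ReadRecord],
    units: tuple[str, str, str] = ("CAG", "AGC", "GCA"),
    read_len: int = 50,
) -> dict[str, int]:
    """Count reads that are pure phase-0 repeats of each unit rotation.

    Only reads of exactly ``read_len`` nt are considered; others are skipped
    with a logged tally.  A read can match at most one rotation (the three
    phase-0 repetitions of distinct rotations differ at the first position).
    """
    rots = {units[0][i:] + units[0][:i] for i in range(3)}
    if set(normalize_sequence(u) for u in units) != {normalize_sequence(r) for r in rots}:
        raise ValueError(f"units {units} are not the three rotations of one triplet")
    counts = {normalize_sequence(u): 0 for u in units}
    skipped = 0
    for read in reads:
        if len(read.sequence) != read_len:
            skipped += 1
            continue
        for u in counts:
            if is_pure_repeat(read.sequence, u):
                counts[u] += read.count
                break
    if skipped:
        logger.info("count_pure_repeat_reads: skipped %d reads of length != %d",
                    skipped, read_len)
    return counts


def read_length_histogram(reads: Iterable[ReadRecord]) -> Counter:
    """Count-weighted histogram of read lengths."""
    hist: Counter = Counter()
    for read in reads:
        hist[len(read.sequence)] += read.count
    return hist


def brute_force_longest_tract(sequence: str, unit: str) -> RepeatTract | None:
    """Quadratic reference scanner: test every substring for membership in
    the infinite unit repetition.  Used as an independent oracle in tests.
    """
    seq = normalize_sequence(sequence)
    u = normalize_sequence(unit)
    n = len(seq)
    best: RepeatTract | None = None

    def window_phase(sub: str) -> int | None:
        for p in range(3):
            if all(sub[k] == u[(k + p) % 3] for k in range(len(sub))):
                return p
        return None

    for start in range(n):
        for end in range(start + 3, n + 1):
            sub = seq[start:end]
            p = window_phase(sub)
            if p is None:
                continue
            length = end - start
            # maximality: neither neighbour extends the same phase class
            if start > 0 and seq[start - 1] == u[(p - 1) % 3]:
                continue
            if end < n and seq[end] == u[(p + length) % 3]:
                continue
            if best is None or length > best.length_nt or (
                length == best.length_nt and start < best.start
            ):
                best = RepeatTract(u, start, length, p)
    return best
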