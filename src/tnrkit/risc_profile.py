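"""Grouping of RISC-bound small-RNA reads by repeat 19-mer content.

Ago-pulldown libraries from hairpin-transfected cells are partitioned into
group 1 (reads containing any of the three 19-nt CAG-phase k-mers), group 2
(the three CCG-phase 19-mers) and group 3 (everything else).  Reads
matching both repeat groups are assigned to group 1 and tallied as
ambiguous so the precedence choice stays auditable.  Counts are reported
raw and as reads-per-million of the library total, with per-group length
histograms and species (distinct sequence) tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from tnrkit.repeat_scan import (
    ReadRecord,
    longest_repeat_tract,
    normalize_sequence,
)

GROUP1_KMERS = (
    "CAGCAGCAGCAGCAGCAGC",
    "AGCAGCAGCAGCAGCAGCA",
    "GCAGCAGCAGCAGCAGCAG",
)
GROUP2_KMERS = (
    "CCGCCGCCGCCGCCGCCGC",
    "CGCCGCCGCCGCCGCCGCC",
    "GCCGCCGCCGCCGCCGCCG",
)


@dataclass(frozen=True)
class GroupDefinition:
    group1_kmers: tuple[str, ...] = GROUP1_KMERS
    group2_kmers: tuple[str, ...] = GROUP2_KMERS

    def __post_init__(self) -> None:
        for kmer in (*self.group1_kmers, *self.group2_kmers):
            if len(kmer) != 19:
                raise ValueError(f"group k-mers must be 19 nt, got {kmer!r}")


@dataclass
class GroupProfile:
    """Raw/normalized totals plus length and species tables per group."""

    raw_counts: dict[str, int]
    normalized_counts: dict[str, float]
    ambiguous_count: int
    length_histograms: dict[str, Counter]
    species_tables: dict[str, Counter]

    @property
    def total(self) -> int:
        return sum(self.raw_counts.values())

    def species_frame(self, group: str) -> pd.DataFrame:
        """Species table for one group, sorted by count descending."""
        items = self.species_tables[group].most_common()
        return pd.DataFrame(items, columns=["sequence", "count"])


def assign_group(read_sequence: str, defs: GroupDefinition | None = None
                 ) -> str:
    """Assign a read to group1/group2/group3 by 19-mer content.

    Group 1 (CAG-phase) takes precedence over group 2 (CCG-phase) when a
    read contains k-mers of both.
    """
    defs = defs or GroupDefinition()
    seq = normalize_sequence(read_sequence)
    g1 = tuple(normalize_sequence(k) for k in defs.group1_kmers)
    g2 = tuple(normalize_sequence(k) for k in defs.group2_kmers)
    if any(k in seq for k in g1):
        return "group1"
    if any(k in seq for k in g2):
        return "group2"
    return "group3"


def profile_library(
    reads: Iterable[ReadRecord],
    defs: GroupDefinition | None = None,
) -> GroupProfile:
    """Partition a library into the three repeat groups and summarize.

    Normalized counts are reads-per-million of the library total; raw group
    counts always sum exactly to the total input count.
    """
    defs = defs or GroupDefinition()
    g1 = tuple(normalize_sequence(k) for k in defs.group1_kmers)
    g2 = tuple(normalize_sequence(k) for k in defs.group2_kmers)
    raw = {"group1": 0, "group2": 0, "group3": 0}
    ambiguous = 0
    lengths = {g: Counter() for g in raw}
    species = {g: Counter() for g in raw}
    for read in reads:
        seq = normalize_sequence(read.sequence)
        in1 = any(k in seq for k in g1)
        in2 = any(k in seq for k in g2)
        group = "group1" if in1 else ("group2" if in2 else "group3")
        if in1 and in2:
            ambiguous += read.count
        raw[group] += read.count
        lengths[group][len(seq)] += read.count
        species[group][seq] += read.count
    total = sum(raw.values())
    if total == 0:
        raise ValueError("cannot profile an empty library "
                         "(per-million normalization undefined)")
    norm = {g: c * 1e6 / total for g, c in raw.items()}
    return GroupProfile(raw, norm, ambiguous, lengths, species)


def list_long_repeat_reads(
    reads: Iterable[ReadRecord],
    unit: str = "CAG",
    min_len: int = 8,
) -> pd.DataFrame:
    """Table of reads carrying a unit tract of at least ``min_len`` nt.

    Columns: read_id, sequence, tract_length_nt, count.  Tract detection is
    the same any-phase maximal-tract scan used for read classification.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    rows = []
    for read in reads:
        tract = longest_repeat_tract(read.sequence, unit)
        if tract and tract.length_nt >= min_len:
            rows.append((read.read_id, read.sequence, tract.length_nt,
                         read.count))
    return pd.DataFrame(
        rows, columns=["read_id", "sequence", "tract_length_nt", "count"]
    )


def profile_frame(profile: GroupProfile) -> pd.DataFrame:
    """Group summary as a tidy frame (group, raw_count, normalized_per_million)."""
    return pd.DataFrame(
        {
            "group": list(profile.raw_counts),
            "raw_count": list(profile.raw_counts.values()),
            "normalized_per_million": [
                profile.normalized_counts[g] for g in profile.raw_counts
            ],
        }
    )
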