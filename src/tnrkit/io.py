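"""Readers and writers for the small text formats the pipeline consumes.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO (gzip-transparent);
the collapsed-FASTA dialect (``>id_count`` headers), RNK ranked lists and
Broad-dialect GMT gene sets are simple tab formats handled here.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

from tnrkit.repeat_scan import ReadRecord

logger = logging.getLogger(__name__)

_COLLAPSED = re.compile(r"^(?P<stem>.*)_(?P<count>\d+)$")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_count(read_id: str) -> tuple[str, int]:
    m = _COLLAPSED.match(read_id)
    if m:
        return m.group("stem"), int(m.group("count"))
    return read_id, 1


def read_fasta(path: str | Path, collapsed: bool = True) -> Iterator[ReadRecord]:
    """Yield reads from a (optionally gzipped) FASTA file.

    When ``collapsed`` is true, trailing ``_<int>`` suffixes on record ids
    are interpreted as collapsed-read multiplicities.
    """
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rid, count = _parse_count(rec.id) if collapsed else (rec.id, 1)
            yield ReadRecord(rid, str(rec.seq), count)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield reads from a (optionally gzipped) FASTQ file; qualities ignored."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(rec.id, str(rec.seq), 1)


def read_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Dispatch on extension: .fa/.fasta -> FASTA, .fq/.fastq -> FASTQ."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    if name.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(reads: list[ReadRecord], path: str | Path,
                collapsed: bool = True) -> None:
    with open(path, "w") as out:
        for read in reads:
            rid = f"{read.read_id}_{read.count}" if collapsed else read.read_id
            out.write(f">{rid}\n{read.sequence}\n")


def read_region_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (gene_id, region_kind, sequence) triples.

    Accepts either a 3-column TSV or a FASTA whose headers are
    ``gene_id|region_kind``.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    if path.suffix in {".fa", ".fasta"} or str(path).endswith((".fa.gz", ".fasta.gz")):
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                gene, _, kind = rec.id.partition("|")
                rows.append((gene, kind, str(rec.seq)))
        return rows
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, kind, seq = line.split("\t")[:3]
            rows.append((gene, kind, seq))
    return rows


def write_region_table(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for gene, kind, seq in rows:
            out.write(f"{gene}\t{kind}\t{seq}\n")


def read_rnk(path: str | Path) -> dict[str, float]:
    """Read a 2-column RNK file into {gene: score}."""
    scores: dict[str, float] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, value = line.split("\t")[:2]
            if gene in scores:
                raise ValueError(f"duplicate gene id in RNK file: {gene}")
            scores[gene] = float(value)
    return scores


def write_rnk(scores: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as out:
        for gene, value in scores.items():
            out.write(f"{gene}\t{value:g}\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into {set_name: (description, members)}."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with _open_text(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = (fields[1], set(fields[2:]))
    return sets


def write_gmt(sets: dict[str, tuple[str, set[str]]], path: str | Path) -> None:
    with open(path, "w") as out:
        for name, (desc, members) in sets.items():
            if not members:
                logger.info("write_gmt: omitting empty set %s", name)
                continue
            out.write("\t".join([name, desc, *sorted(members)]) + "\n")
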