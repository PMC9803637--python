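"""Seeded generators for every input the analyses consume.

Each generator emulates the statistical structure of one data type —
repeat-tract read libraries, stitched transcript regions with planted
tracts, ranked gene lists with a planted negative shift, and RISC-bound
Dicer-product libraries with fixed 5' phase and controllable per-construct
abundance — and returns a truth table sufficient to check the downstream
module.  Plantings are verified with the production tract scanner before a
record is emitted, so the recorded truth is exact, not probabilistic:
random background abutting a planted tract can never lengthen it
unnoticed.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tnrkit.repeat_scan import ReadRecord, longest_repeat_tract
from tnrkit.risc_profile import GROUP1_KMERS, GROUP2_KMERS

_BASES = np.array(list("ACGT"))
_ALL_GROUP_KMERS = tuple(k.replace("U", "T")
                         for k in (*GROUP1_KMERS, *GROUP2_KMERS))


@dataclass
class SimulationSpec:
    """Shared knobs for the generators; defaults are the study conditions.

    ``dicer_lengths`` defaults to equal point masses at 21 and 22 nt (the
    dominant Dicer-product lengths); ``phase5`` fixes the 5' trinucleotide
    of CAG-phase products to AGC; ``abundance_ratio`` holds per-construct
    group-1 product weights (LOI:Ref = 4:1).
    """

    seed: int = 0
    n_genes: int = 100
    n_reads: int = 10_000
    read_len: int = 50
    tract_plan: dict[int, int] = field(default_factory=dict)
    effect_size: float = -2.0
    noise_sd: float = 1.0
    dicer_lengths: dict[int, float] = field(
        default_factory=lambda: {21: 0.5, 22: 0.5})
    phase5: str = "AGC"
    abundance_ratio: dict[str, float] = field(
        default_factory=lambda: {"LOI": 4.0, "Ref": 1.0})
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        total = sum(self.dicer_lengths.values())
        if total <= 0:
            raise ValueError("dicer_lengths must have positive mass")


#: backgrounds are kept free of tracts at or above this length, the lowest
#: threshold any catalog or read-classification stage uses
BACKGROUND_MAX_TRACT = 10


def _random_background(rng: np.random.Generator, length: int,
                       forbid_unit: str,
                       max_tract: int = BACKGROUND_MAX_TRACT) -> str:
    """Random sequence guaranteed to hold no forbid_unit tract >= max_tract."""
    while True:
        seq = "".join(rng.choice(_BASES, size=length))
        tract = longest_repeat_tract(seq, forbid_unit) if length >= 3 else None
        if tract is None or tract.length_nt < max_tract:
            return seq


def _plant_tract(rng: np.random.Generator, unit: str, tract_len: int,
                 total_len: int, offset: int | None = None) -> tuple[str, int]:
    """Embed an exact-length tract in background; verified with the scanner.

    Returns (sequence, start).  Retries until the planted tract is both
    present at the requested length and is the longest tract in the
    sequence (background can otherwise extend or rival it).
    """
    unit3 = unit.upper().replace("U", "T")
    if tract_len > total_len:
        raise ValueError("tract longer than the sequence")
    bg_max = min(tract_len, BACKGROUND_MAX_TRACT)
    for _ in range(1000):
        start = (int(rng.integers(0, total_len - tract_len + 1))
                 if offset is None else offset)
        phase = int(rng.integers(0, 3))
        tract = "".join(unit3[(phase + k) % 3] for k in range(tract_len))
        left = _random_background(rng, start, unit3, bg_max)
        right = _random_background(rng, total_len - start - tract_len,
                                   unit3, bg_max)
        seq = left + tract + right
        found = longest_repeat_tract(seq, unit3)
        if found and found.length_nt == tract_len and found.start == start:
            return seq, start
    raise RuntimeError("failed to plant a verified tract")  # pragma: no cover


def synth_transcriptome(
    spec: SimulationSpec,
    unit: str = "CTG",
    region_len: int = 120,
    junction_fraction: float = 0.25,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Region records with planted tracts, plus an exact truth table.

    Genes beyond the tract plan are pure background, guaranteed free of
    ``unit`` tracts of 10 nt or longer on the stitched mRNA.  A
    ``junction_fraction`` share of planted tracts is split across the
    ORF/3'UTR stitch so catalog matching on the concatenated mRNA is
    exercised.  Every gene's stitched mRNA is re-scanned before emission,
    so truth (gene_id, planted_tract_len) is exact, with 0 meaning
    "no tract at any catalog threshold".
    """
    rng = np.random.default_rng(spec.seed)
    unit3 = unit.upper().replace("U", "T")
    records: list[tuple[str, str, str]] = []
    truth_rows = []
    gene_idx = 0

    def emit_planted(gene: str, tract_len: int) -> list[tuple[str, str, str]]:
        for _ in range(1000):
            utr5 = _random_background(rng, region_len // 2, unit3)
            if rng.random() < junction_fraction and tract_len >= 6:
                # split the tract across the ORF/3'UTR stitch point
                cut = int(rng.integers(3, tract_len - 2))
                phase = int(rng.integers(0, 3))
                tract = "".join(unit3[(phase + k) % 3]
                                for k in range(tract_len))
                orf = _random_background(rng, region_len, unit3) + tract[:cut]
                utr3 = (tract[cut:]
                        + _random_background(rng, region_len // 2, unit3))
            else:
                orf, _ = _plant_tract(rng, unit3, tract_len, region_len)
                utr3 = _random_background(rng, region_len // 2, unit3)
            found = longest_repeat_tract(utr5 + orf + utr3, unit3)
            if found and found.length_nt == tract_len:
                return [(gene, "utr5", utr5), (gene, "orf", orf),
                        (gene, "utr3", utr3)]
        raise RuntimeError("failed to plant a verified gene")  # pragma: no cover

    for tract_len, n_genes in sorted(spec.tract_plan.items()):
        for _ in range(n_genes):
            gene = f"G{gene_idx:05d}"
            gene_idx += 1
            records += emit_planted(gene, tract_len)
            truth_rows.append((gene, tract_len))
    n_background = max(spec.n_genes - gene_idx, 0)
    for _ in range(n_background):
        gene = f"G{gene_idx:05d}"
        gene_idx += 1
        for _ in range(1000):
            parts = [
                (gene, "utr5", _random_background(rng, region_len // 2, unit3)),
                (gene, "orf", _random_background(rng, region_len, unit3)),
                (gene, "utr3", _random_background(rng, region_len // 2, unit3)),
            ]
            mrna = "".join(seq for _, _, seq in parts)
            found = longest_repeat_tract(mrna, unit3)
            if found is None or found.length_nt < BACKGROUND_MAX_TRACT:
                break
        records += parts
        truth_rows.append((gene, 0))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "planted_tract_len"])
    return records, truth


def synth_ranked_list(
    spec: SimulationSpec,
    target_set: set[str],
    gene_ids: list[str] | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Gene -> logFC table with a planted mean shift on the target set.

    Non-target scores ~ Normal(0, noise_sd); target scores ~
    Normal(effect_size, noise_sd).  Returns the score table and a truth
    frame (gene_id, is_target, true_mean).
    """
    rng = np.random.default_rng(spec.seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    unknown = target_set - set(gene_ids)
    if unknown:
        raise ValueError(f"target genes absent from the universe: "
                         f"{sorted(unknown)[:5]}")
    scores: dict[str, float] = {}
    rows = []
    for gene in gene_ids:
        mu = spec.effect_size if gene in target_set else 0.0
        scores[gene] = float(rng.normal(mu, spec.noise_sd))
        rows.append((gene, gene in target_set, mu))
    truth = pd.DataFrame(rows, columns=["gene_id", "is_target", "true_mean"])
    return scores, truth


def synth_read_library(
    spec: SimulationSpec,
    unit: str = "CAG",
    background_max_tract: int = BACKGROUND_MAX_TRACT,
) -> tuple[list[ReadRecord], dict[int, int]]:
    """Fixed-length reads with planted longest-tract lengths.

    ``spec.tract_plan`` maps tract length -> read count; remaining reads up
    to ``spec.n_reads`` are background guaranteed free of tracts of
    ``background_max_tract`` nt or longer (truth value 0).  Each planting
    is verified with the scanner
    before optional substitution noise is applied, and the returned truth
    histogram records pre-noise lengths.
    """
    rng = np.random.default_rng(spec.seed)
    unit3 = unit.upper().replace("U", "T")
    reads: list[ReadRecord] = []
    truth: dict[int, int] = {}
    idx = 0
    for tract_len, n in sorted(spec.tract_plan.items()):
        for _ in range(n):
            if tract_len >= spec.read_len:
                phase = int(rng.integers(0, 3))
                seq = "".join(unit3[(phase + k) % 3]
                              for k in range(spec.read_len))
                planted = spec.read_len
            else:
                seq, _ = _plant_tract(rng, unit3, tract_len, spec.read_len)
                planted = tract_len
            truth[planted] = truth.get(planted, 0) + 1
            seq = _apply_errors(rng, seq, spec.error_rate)
            reads.append(ReadRecord(f"R{idx:06d}", seq))
            idx += 1
    planted_total = sum(spec.tract_plan.values())
    for _ in range(max(spec.n_reads - planted_total, 0)):
        seq = _random_background(rng, spec.read_len, unit3,
                                 background_max_tract)
        truth[0] = truth.get(0, 0) + 1
        seq = _apply_errors(rng, seq, spec.error_rate)
        reads.append(ReadRecord(f"R{idx:06d}", seq))
        idx += 1
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str,
                  error_rate: float) -> str:
    """Substitution-only error model (no indels)."""
    if error_rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = rng.random(chars.size) < error_rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _dicer_product(rng: np.random.Generator, spec: SimulationSpec,
                   unit: str, phase5: str) -> str:
    """One Dicer-product read: fixed 5' trinucleotide, length from
    ``dicer_lengths``, body = the repeat phase continued."""
    lengths = sorted(spec.dicer_lengths)
    probs = np.array([spec.dicer_lengths[n] for n in lengths], dtype=float)
    probs /= probs.sum()
    length = int(rng.choice(lengths, p=probs))
    unit3 = unit.upper().replace("U", "T")
    start = (phase5.upper().replace("U", "T"))
    offset = unit3.index(start[0]) if start[0] in unit3 else 0
    return "".join(unit3[(offset + k) % 3] for k in range(length))


def synth_risc_library(
    spec: SimulationSpec,
    constructs: dict[str, float] | None = None,
    group1_base_fraction: float = 0.08,
    group2_fraction: float = 0.01,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Per-construct RISC-bound libraries with planted group compositions.

    For each construct (abundance weight w) a library of ``spec.n_reads``
    reads is drawn from a seeded multinomial with group-1 probability
    ``group1_base_fraction * w``, a fixed small group-2 (CCG-phase)
    fraction, and group-3 background filling the remainder.  Group-1
    products all begin with ``spec.phase5`` at Dicer-product lengths;
    group-2 products begin CCG.  Truth: construct, group, expected_fraction.
    """
    constructs = constructs or spec.abundance_ratio
    rng = np.random.default_rng(spec.seed)
    libraries: dict[str, list[ReadRecord]] = {}
    truth_rows = []
    for name, weight in constructs.items():
        p1 = group1_base_fraction * weight
        if p1 + group2_fraction >= 1.0:
            raise ValueError("group fractions exceed 1; lower the base "
                             "fraction or abundance weights")
        counts = rng.multinomial(
            spec.n_reads, [p1, group2_fraction, 1.0 - p1 - group2_fraction])
        reads: list[ReadRecord] = []
        idx = 0
        for _ in range(counts[0]):
            seq = _dicer_product(rng, spec, "CAG", spec.phase5)
            reads.append(ReadRecord(f"{name}_R{idx:06d}", seq)); idx += 1
        for _ in range(counts[1]):
            seq = _dicer_product(rng, spec, "CCG", "CCG")
            reads.append(ReadRecord(f"{name}_R{idx:06d}", seq)); idx += 1
        for _ in range(counts[2]):
            length = int(rng.choice(sorted(spec.dicer_lengths)))
            while True:
                seq = _random_background(rng, length, "CAG", 10)
                # verified group-3: free of both repeat 19-mer families
                if not any(k in seq for k in _ALL_GROUP_KMERS):
                    break
            reads.append(ReadRecord(f"{name}_R{idx:06d}", seq)); idx += 1
        libraries[name] = reads
        truth_rows += [(name, "group1", p1), (name, "group2", group2_fraction),
                       (name, "group3", 1.0 - p1 - group2_fraction)]
    truth = pd.DataFrame(truth_rows,
                         columns=["construct", "group", "expected_fraction"])
    return libraries, truth
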