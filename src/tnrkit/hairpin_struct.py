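"""MFE structure analysis of CAG-repeat hairpin RNAs.

CAG-repeat tracts self-pair into hairpin stems of C:G and G:C pairs with a
periodic A-A mismatch, which MFE folding renders as 1x1 interior loops.
This module builds HTT/AR repeat-variant sequences, folds them with a
Turner-1999 nearest-neighbor engine (ViennaRNA, via a narrow contract:
sequence + options in, dot-bracket + free energy out), segments the pair
table into stems that tolerate only 1x1 interior loops, and counts the CAG
units whose C and G are both paired inside one segment — the
"uninterrupted double-stranded CAG repeat" length that tracks hairpin
stability and Dicer-substrate quality across disease alleles.

The energy model itself is never re-implemented here: ``fold`` is a
contract to the engine, whose identity and settings are recorded in every
structure report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

try:
    import RNA as _vienna
except ImportError:  # pragma: no cover - engine presence is an env contract
    _vienna = None

_TURNER1999_LOADED = False


@dataclass(frozen=True)
class FoldSettings:
    """Folding options; SHAPE slope/intercept are recorded but unused
    (no reactivity data is ever supplied)."""

    parameter_set: str = "Turner-1999"
    no_isolated_pairs: bool = True
    dangles: int = 2  # both sides of a helix, in any case
    shape_slope: float = 1.9
    shape_intercept: float = 0.7

    def engine_name(self) -> str:
        if _vienna is None:
            return "unavailable"
        return f"ViennaRNA {_vienna.__version__}"


@dataclass(frozen=True)
class VariantSpec:
    """Repeat-variant construct: ordered (motif, repeat_count) segments
    plus optional literal flanks.

    ``segments=[("CAG", 40), ("CAACAG", 1), ("CCGCCA", 1), ("CCG", 7)]``
    expands to the HTT reference repeat region.
    """

    name: str
    segments: tuple[tuple[str, int], ...]
    flank5: str = ""
    flank3: str = ""

    @property
    def length(self) -> int:
        return (len(self.flank5) + len(self.flank3)
                + sum(len(m) * c for m, c in self.segments))


@dataclass
class HairpinStructure:
    sequence: str
    dot_bracket: str
    delta_g: float  # kcal/mol
    settings: FoldSettings
    engine: str

    @property
    def pair_table(self) -> list[tuple[int, int]]:
        """0-based (i, j) pairs, i < j, sorted by i."""
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for i, c in enumerate(self.dot_bracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                pairs.append((stack.pop(), i))
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return sorted(pairs)


@dataclass
class StemSegment:
    """Contiguous run of base pairs separated only by 1x1 interior loops."""

    pairs: list[tuple[int, int]]
    cag_units: int = 0

    @property
    def arm5_span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0]


def _to_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    return seq


def build_variant(spec: VariantSpec) -> str:
    """Deterministically expand a variant spec to its RNA sequence."""
    body = "".join(motif * count for motif, count in spec.segments)
    return _to_rna(spec.flank5 + body + spec.flank3)


def fold(sequence: str, settings: FoldSettings | None = None
         ) -> HairpinStructure:
    """MFE fold via the configured engine; returns structure, energy, settings.

    Raises ``RuntimeError`` with configuration guidance when no folding
    engine is importable.  Co-optimal MFE degeneracy resolves to the
    engine's canonical structure, which is recorded verbatim.
    """
    settings = settings or FoldSettings()
    seq = _to_rna(sequence)
    if len(seq) < 10:
        raise ValueError("sequence must be at least 10 nt to fold")
    if _vienna is None:
        raise RuntimeError(
            "no RNA folding engine available: install the ViennaRNA python "
            "bindings (module 'RNA') to use tnrkit.hairpin_struct.fold"
        )
    global _TURNER1999_LOADED
    if settings.parameter_set == "Turner-1999":
        if not _TURNER1999_LOADED:
            _vienna.params_load_RNA_Turner1999()
            _TURNER1999_LOADED = True
    else:
        raise ValueError(f"unsupported parameter set {settings.parameter_set!r}")
    md = _vienna.md()
    md.noLP = 1 if settings.no_isolated_pairs else 0
    md.dangles = settings.dangles
    fc = _vienna.fold_compound(seq, md)
    db, mfe = fc.mfe()
    return HairpinStructure(seq, db, float(mfe), settings,
                            settings.engine_name())


def stem_segments(structure: HairpinStructure) -> list[StemSegment]:
    """Partition the pair table into maximal runs tolerating 1x1 loops.

    Consecutive pairs (i, j), (i', j') stay in one segment iff i' - i <= 2
    and j - j' <= 2 with j' < j; bulges or loops larger than 1x1 start a
    new segment.  Every pair lands in exactly one segment.
    """
    pairs = structure.pair_table
    segments: list[StemSegment] = []
    current: list[tuple[int, int]] = []
    for pair in pairs:
        if (current
                and pair[0] - current[-1][0] <= 2
                and pair[1] < current[-1][1]
                and current[-1][1] - pair[1] <= 2):
            current.append(pair)
        else:
            if current:
                segments.append(StemSegment(current))
            current = [pair]
    if current:
        segments.append(StemSegment(current))
    for seg in segments:
        seg.cag_units = _count_cag_units(seg, structure.sequence)
    return segments


def _count_cag_units(segment: StemSegment, sequence: str) -> int:
    """CAG units on the 5' arm whose C and G are both paired in the segment.

    The 5' arm is scanned left to right; after a counted CAG the scan jumps
    past it, so units never overlap.  Half-paired triplets do not count.
    """
    paired5 = {i for i, _ in segment.pairs}
    lo, hi = min(paired5), max(paired5)
    count = 0
    c = lo
    while c <= hi - 2:
        if (sequence[c:c + 3] == "CAG" and c in paired5
                and c + 2 in paired5):
            count += 1
            c += 3
        else:
            c += 1
    return count


def longest_uninterrupted_cag_stem(structure: HairpinStructure) -> int:
    """Maximum double-stranded CAG-unit count over all stem segments."""
    segments = stem_segments(structure)
    if not segments:
        return 0
    return max(seg.cag_units for seg in segments)


def compare_variants(
    specs: list[VariantSpec],
    settings: FoldSettings | None = None,
):
    """Fold each variant and tabulate length, free energy and stem metrics.

    Returns a pandas DataFrame with one row per spec: name, length_nt,
    delta_g_kcal_mol, longest_cag_stem_units, n_segments, dot_bracket,
    engine.
    """
    import pandas as pd

    if len(specs) < 2:
        raise ValueError("compare_variants needs at least two specs")
    rows = []
    for spec in specs:
        seq = build_variant(spec)
        structure = fold(seq, settings)
        segs = stem_segments(structure)
        rows.append({
            "name": spec.name,
            "length_nt": len(seq),
            "delta_g_kcal_mol": structure.delta_g,
            "longest_cag_stem_units": longest_uninterrupted_cag_stem(structure),
            "n_segments": len(segs),
            "dot_bracket": structure.dot_bracket,
            "engine": structure.engine,
        })
    return pd.DataFrame(rows)


# --- printed construct sequences (decoded from the synthesized oligo list) ---

CTR_HP_CAG7 = "CAGCAGCAGCAGCAGCAGCAG"
CTR_HP_CAG12 = "CAG" * 12
# the synthesized (CAG)21 control carries a leading AG dinucleotide, as made
CTR_HP_CAG21 = "AG" + "CAG" * 21
CTR_HP_CAG29 = "CAG" * 29
CTR_HP_CAG40 = "CAG" * 40
AR_HP_3_9 = "UGC" * 4 + "AGC" * 9 + "AA"
AR_HP_3_17 = "UGC" * 4 + "AGC" * 17 + "AA"
REF_HP = "CAG" * 18 + "CAACAG" + "CCGCCA" + "CCG" * 7 + "CCU"
LOI_HP = "CAG" * 21 + "CCG" * 9 + "CCU"

CTR_HP_SERIES = {
    7: CTR_HP_CAG7,
    12: CTR_HP_CAG12,
    21: CTR_HP_CAG21,
    29: CTR_HP_CAG29,
    40: CTR_HP_CAG40,
}

#: HTT repeat-region formula constructs (no flanks): the reference allele
#: and the loss-of-inhibition (LOI) allele, which differ by two A->G
#: substitutions yet extend the uninterrupted CAG run from 40 to 42 units.
REF_FULL_SPEC = VariantSpec(
    "HTT-Ref",
    (("CAG", 40), ("CAACAG", 1), ("CCGCCA", 1), ("CCG", 7)),
)
LOI_FULL_SPEC = VariantSpec(
    "HTT-LOI",
    (("CAG", 40), ("CAGCAG", 1), ("CCGCCG", 1), ("CCG", 7)),
)

#: stem counts reported for the flanked (15 nt each side) full constructs
PRINTED_FULL_STEM_UNITS = {"HTT-Ref": 15, "HTT-LOI": 25}


def check_printed_stem_counts(
    flank5: str,
    flank3: str,
    settings: FoldSettings | None = None,
):
    """Fold the flanked full-length Ref/LOI constructs and compare their
    longest CAG stems with the reported counts (15 and 25 units).

    The 15-nt genomic flanks are not shipped and must be supplied by the
    caller.  Discrepancies are reported against the declared 1x1
    stem-counting convention, never silently reconciled.  Returns a frame
    with observed and expected counts and a ``matches`` column.
    """
    import pandas as pd

    rows = []
    for spec in (REF_FULL_SPEC, LOI_FULL_SPEC):
        flanked = VariantSpec(spec.name, spec.segments,
                              flank5=flank5, flank3=flank3)
        structure = fold(build_variant(flanked), settings)
        observed = longest_uninterrupted_cag_stem(structure)
        expected = PRINTED_FULL_STEM_UNITS[spec.name]
        rows.append({
            "name": spec.name,
            "delta_g_kcal_mol": structure.delta_g,
            "observed_stem_units": observed,
            "expected_stem_units": expected,
            "matches": observed == expected,
        })
    return pd.DataFrame(rows)


def write_vienna(structure: HairpinStructure, path, name: str = "seq") -> None:
    """Write sequence / dot-bracket / energy in Vienna format, with the
    engine and settings recorded in the header."""
    with open(path, "w") as out:
        out.write(f">{name} engine={structure.engine} "
                  f"params={structure.settings.parameter_set} "
                  f"noLP={int(structure.settings.no_isolated_pairs)} "
                  f"dangles={structure.settings.dangles}\n")
        out.write(structure.sequence + "\n")
        out.write(f"{structure.dot_bracket} ({structure.delta_g:.2f})\n")
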