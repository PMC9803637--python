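"""Nested catalogs of trinucleotide-repeat-containing genes.

Per gene, the longest deposited 5'UTR, ORF and 3'UTR are stitched into an
mRNA proxy, and the gene joins the set "contains a unit repeat of >= n nt"
when its stitched mRNA carries a perfect tract at least that long.  The
thresholds 10..19 nt produce a nested family of gene sets, the custom
collections used for repeat-length-stratified enrichment analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from tnrkit import io
from tnrkit.repeat_scan import longest_repeat_tract, normalize_sequence

logger = logging.getLogger(__name__)

REGION_KINDS = ("utr5", "orf", "utr3")


@dataclass
class GeneModel:
    """Stitched mRNA proxy: longest candidate of each region, concatenated."""

    gene_id: str
    utr5: str = ""
    orf: str = ""
    utr3: str = ""

    @property
    def mrna(self) -> str:
        return self.utr5 + self.orf + self.utr3


@dataclass
class GeneSetFamily:
    """Nested gene sets keyed by minimum tract length (nt)."""

    unit: str
    thresholds: list[int]
    sets: dict[int, set[str]] = field(default_factory=dict)

    def set_name(self, threshold: int) -> str:
        return f"{self.unit}_GE_{threshold}NT"

    def check_nested(self) -> bool:
        for lo, hi in zip(self.thresholds, self.thresholds[1:]):
            if not self.sets.get(hi, set()) <= self.sets.get(lo, set()):
                return False
        return True


def stitch_gene_models(
    region_records: list[tuple[str, str, str]],
) -> dict[str, GeneModel]:
    """Select per gene the longest candidate of each region kind and stitch.

    ``region_records`` are (gene_id, region_kind, sequence) triples; multiple
    candidates per kind are allowed (isoforms).  Ties on length are broken by
    lexicographically smallest sequence, logged.  Missing kinds are empty.
    """
    models: dict[str, GeneModel] = {}
    for gene_id, kind, seq in region_records:
        if kind not in REGION_KINDS:
            raise ValueError(
                f"unknown region kind {kind!r} for gene {gene_id} "
                f"(expected one of {REGION_KINDS})"
            )
        seq = normalize_sequence(seq)
        model = models.setdefault(gene_id, GeneModel(gene_id))
        current = getattr(model, kind)
        if len(seq) > len(current):
            setattr(model, kind, seq)
        elif current and len(seq) == len(current) and seq < current:
            logger.info("stitch_gene_models: %s/%s length tie, keeping "
                        "lexicographically first candidate", gene_id, kind)
            setattr(model, kind, seq)
    return models


def build_gene_set_family(
    models: dict[str, GeneModel],
    unit: str,
    thresholds: list[int] | range = range(10, 20),
) -> GeneSetFamily:
    """Catalog genes whose stitched mRNA holds a unit tract >= each threshold.

    Matching uses the same any-phase tract definition as read scanning, so a
    tract spanning a region junction counts on the stitched mRNA.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    family = GeneSetFamily(unit=normalize_sequence(unit), thresholds=thresholds)
    if not models:
        logger.warning("build_gene_set_family: empty model collection")
        family.sets = {t: set() for t in thresholds}
        return family
    lengths: dict[str, int] = {}
    for gene_id, model in models.items():
        tract = longest_repeat_tract(model.mrna, unit)
        lengths[gene_id] = tract.length_nt if tract else 0
    family.sets = {
        t: {g for g, n in lengths.items() if n >= t} for t in thresholds
    }
    return family


def write_gmt(family: GeneSetFamily, path: str | Path) -> None:
    """Write the family as Broad-dialect GMT, one line per nonempty threshold."""
    sets = {
        family.set_name(t): (
            f"genes with a {family.unit} repeat tract of >= {t} nt",
            family.sets.get(t, set()),
        )
        for t in family.thresholds
    }
    io.write_gmt(sets, path)


def read_gmt(path: str | Path, unit: str) -> GeneSetFamily:
    """Read a GMT written by :func:`write_gmt` back into a family."""
    raw = io.read_gmt(path)
    unit = normalize_sequence(unit)
    thresholds: list[int] = []
    sets: dict[int, set[str]] = {}
    for name, (_desc, members) in raw.items():
        prefix = f"{unit}_GE_"
        if not (name.startswith(prefix) and name.endswith("NT")):
            raise ValueError(f"set name {name!r} does not match unit {unit}")
        t = int(name[len(prefix):-2])
        thresholds.append(t)
        sets[t] = members
    thresholds.sort()
    return GeneSetFamily(unit=unit, thresholds=thresholds, sets=sets)
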