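"""Generators: exact truth tables, seeded reproducibility, planted signals."""

import numpy as np
import pytest

from tnrkit.repeat_scan import classify_reads, longest_repeat_tract
from tnrkit.risc_profile import assign_group
from tnrkit.synthetic_data import (
    SimulationSpec,
    synth_ranked_list,
    synth_read_library,
    synth_risc_library,
    synth_transcriptome,
)
from tnrkit.tnr_catalog import build_gene_set_family, stitch_gene_models


def test_read_library_truth_recovered_exactly():
    spec = SimulationSpec(seed=2, n_reads=300, tract_plan={10: 5, 13: 2, 50: 1})
    reads, truth = synth_read_library(spec)
    assert truth == {10: 5, 13: 2, 50: 1, 0: 292}
    table = classify_reads(reads, "CAG", min_len=10, max_len=50)
    assert table.class_counts == {10: 5, 13: 2, 50: 1}
    assert table.unclassified == 292


def test_full_length_plan_yields_pure_repeat_reads():
    spec = SimulationSpec(seed=4, n_reads=2, read_len=50, tract_plan={50: 2})
    reads, _ = synth_read_library(spec)
    for read in reads:
        assert longest_repeat_tract(read.sequence, "CAG").length_nt == 50


def test_substitution_noise_degrades_but_conserves_totals():
    plan = {15: 40}
    clean_spec = SimulationSpec(seed=6, n_reads=200, tract_plan=plan)
    noisy_spec = SimulationSpec(seed=6, n_reads=200, tract_plan=plan,
                                error_rate=0.05)
    clean, _ = synth_read_library(clean_spec)
    noisy, _ = synth_read_library(noisy_spec)
    t_clean = classify_reads(clean, "CAG")
    t_noisy = classify_reads(noisy, "CAG")
    assert t_noisy.total == t_clean.total == 200
    assert t_noisy.class_counts.get(15, 0) < t_clean.class_counts[15]


def test_generators_are_bit_reproducible():
    spec = SimulationSpec(seed=9, n_reads=50, n_genes=20,
                          tract_plan={12: 3})
    assert synth_read_library(spec)[0] == synth_read_library(spec)[0]
    r1, t1 = synth_transcriptome(spec, unit="CTG")
    r2, t2 = synth_transcriptome(spec, unit="CTG")
    assert r1 == r2 and t1.equals(t2)
    scores1, _ = synth_ranked_list(spec, {"G00001"})
    scores2, _ = synth_ranked_list(spec, {"G00001"})
    assert scores1 == scores2
    lib1, _ = synth_risc_library(SimulationSpec(seed=9, n_reads=500))
    lib2, _ = synth_risc_library(SimulationSpec(seed=9, n_reads=500))
    assert lib1 == lib2


def test_transcriptome_plan_drives_set_sizes():
    spec = SimulationSpec(seed=13, n_genes=30, tract_plan={15: 3})
    records, truth = synth_transcriptome(spec, unit="CTG")
    family = build_gene_set_family(stitch_gene_models(records), "CTG")
    assert len(family.sets[10]) == 3 and len(family.sets[15]) == 3
    assert len(family.sets[16]) == 0
    assert (truth.planted_tract_len == 0).sum() == 27


def test_empty_plan_gives_empty_sets():
    spec = SimulationSpec(seed=14, n_genes=10, tract_plan={})
    records, _ = synth_transcriptome(spec, unit="CTG")
    family = build_gene_set_family(stitch_gene_models(records), "CTG")
    assert all(not members for members in family.sets.values())


def test_background_genes_never_reach_the_catalog(rng):
    spec = SimulationSpec(seed=15, n_genes=200, tract_plan={})
    records, _ = synth_transcriptome(spec, unit="CTG")
    models = stitch_gene_models(records)
    for model in models.values():
        tract = longest_repeat_tract(model.mrna, "CTG")
        assert tract is None or tract.length_nt < 10


def test_ranked_list_planted_shift_statistics():
    spec = SimulationSpec(seed=16, n_genes=2000, effect_size=-2.0,
                          noise_sd=1.0)
    targets = {f"G{i:05d}" for i in range(100)}
    scores, truth = synth_ranked_list(spec, targets)
    target_scores = [scores[g] for g in targets]
    rest = [s for g, s in scores.items() if g not in targets]
    assert np.mean(target_scores) == pytest.approx(-2.0, abs=0.3)
    assert np.mean(rest) == pytest.approx(0.0, abs=0.1)


def test_ranked_list_rejects_unknown_targets():
    spec = SimulationSpec(seed=17, n_genes=10)
    with pytest.raises(ValueError, match="absent"):
        synth_ranked_list(spec, {"NOT_A_GENE"})


def test_risc_library_construction_properties():
    spec = SimulationSpec(seed=18, n_reads=3000)
    libraries, truth = synth_risc_library(spec)
    assert set(libraries) == {"LOI", "Ref"}
    for name, reads in libraries.items():
        groups = [assign_group(r.sequence) for r in reads]
        # group-1 reads all begin with the configured 5' phase
        for read, group in zip(reads, groups):
            assert len(read.sequence) in (21, 22)
            if group == "group1":
                assert read.sequence.startswith("AGC")
            elif group == "group2":
                assert read.sequence.startswith("CCG")
        planted = truth[truth.construct == name]
        for group in ("group1", "group2", "group3"):
            expected = float(
                planted[planted.group == group].expected_fraction.iloc[0])
            observed = groups.count(group) / len(reads)
            assert observed == pytest.approx(expected, abs=0.03)


def test_risc_rejects_overfull_group_fractions():
    spec = SimulationSpec(seed=19, n_reads=10,
                          abundance_ratio={"X": 20.0})
    with pytest.raises(ValueError, match="exceed"):
        synth_risc_library(spec)


def test_error_rate_validation():
    with pytest.raises(ValueError, match="probability"):
        SimulationSpec(error_rate=1.5)
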