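"""Variant construction, folding contract, and stem segmentation."""

import pytest

from tnrkit.hairpin_struct import (
    AR_HP_3_17,
    AR_HP_3_9,
    CTR_HP_CAG7,
    CTR_HP_SERIES,
    FoldSettings,
    HairpinStructure,
    LOI_FULL_SPEC,
    LOI_HP,
    REF_FULL_SPEC,
    REF_HP,
    VariantSpec,
    build_variant,
    check_printed_stem_counts,
    compare_variants,
    fold,
    longest_uninterrupted_cag_stem,
    stem_segments,
    write_vienna,
)


def _structure(seq: str, db: str) -> HairpinStructure:
    return HairpinStructure(seq, db, -1.0, FoldSettings(), "manual")


def test_formula_constructs_expand_to_153_nt():
    assert len(build_variant(REF_FULL_SPEC)) == 40 * 3 + 6 + 6 + 7 * 3 == 153
    assert len(build_variant(LOI_FULL_SPEC)) == 153


def test_loi_differs_from_ref_at_exactly_two_positions():
    ref, loi = build_variant(REF_FULL_SPEC), build_variant(LOI_FULL_SPEC)
    diffs = [i for i, (a, b) in enumerate(zip(ref, loi)) if a != b]
    assert len(diffs) == 2
    assert all(ref[i] == "A" and loi[i] == "G" for i in diffs)


def test_cag7_spec_reproduces_the_synthesized_oligo():
    assert build_variant(VariantSpec("cag7", (("CAG", 7),))) == CTR_HP_CAG7
    assert CTR_HP_CAG7 == "CAGCAGCAGCAGCAGCAGCAG"


def test_variant_spec_length_accounting():
    spec = VariantSpec("x", (("CAG", 4), ("CCG", 2)), flank5="GG",
                       flank3="UU")
    assert spec.length == 12 + 6 + 4 == len(build_variant(spec))


def test_fold_simple_stem_loop():
    s = fold("GGGGAAAACCCC")
    assert s.dot_bracket == "((((....))))"
    assert s.delta_g < 0
    assert s.engine.startswith("ViennaRNA")


def test_fold_unpairable_sequence_is_open():
    s = fold("AAAAAAAAAAAA")
    assert s.dot_bracket == "." * 12
    assert s.delta_g == 0.0


def test_fold_rejects_short_or_invalid_input():
    with pytest.raises(ValueError):
        fold("GGGCCC")
    with pytest.raises(ValueError):
        fold("GGGGAAAACCXC")


def test_fold_is_deterministic():
    a, b = fold(REF_HP), fold(REF_HP)
    assert (a.dot_bracket, a.delta_g) == (b.dot_bracket, b.delta_g)


def test_pair_table_validity_and_nesting():
    s = fold(LOI_HP)
    pairs = s.pair_table
    assert all(i < j for i, j in pairs)
    flat = [x for p in pairs for x in p]
    assert len(flat) == len(set(flat))  # each base in at most one pair
    for (i, j), (i2, j2) in zip(pairs, pairs[1:]):
        assert i2 > i
        assert not (i < i2 < j < j2)  # no pseudoknots


def test_perfect_helix_is_one_segment():
    segs = stem_segments(_structure("GGGGAAAACCCC", "((((....))))"))
    assert len(segs) == 1 and len(segs[0].pairs) == 4


def test_one_by_one_mismatch_does_not_split_a_stem():
    db = "(((.(((....))).)))"
    segs = stem_segments(_structure("CAG" * 6, db))
    assert len(segs) == 1 and len(segs[0].pairs) == 6


def test_bulge_splits_segments():
    # 3-nt bulge on the 5' arm between two helices
    db = "(((...(((....)))...)))"
    segs = stem_segments(_structure("G" * 22, db))
    assert [len(s.pairs) for s in segs] == [3, 3]


def test_segmentation_partitions_the_pair_set():
    for seq in (REF_HP, LOI_HP, AR_HP_3_9, AR_HP_3_17):
        structure = fold(seq)
        segs = stem_segments(structure)
        covered = [p for seg in segs for p in seg.pairs]
        assert sorted(covered) == structure.pair_table


def test_cag_units_bounded_by_arm_span():
    for seq in (REF_HP, LOI_HP):
        for seg in stem_segments(fold(seq)):
            lo, hi = seg.arm5_span
            assert seg.cag_units <= (hi - lo + 3) // 3


def test_open_structure_has_zero_cag_stem():
    s = _structure("CAG" * 4, "." * 12)
    assert longest_uninterrupted_cag_stem(s) == 0


def test_loi_orderings_vs_ref():
    """The LOI variant folds more stably, with a longer CAG stem."""
    ref, loi = fold(REF_HP), fold(LOI_HP)
    assert loi.delta_g < ref.delta_g
    assert (longest_uninterrupted_cag_stem(loi)
            > longest_uninterrupted_cag_stem(ref))


def test_ar_hairpin_stability_ordering():
    assert fold(AR_HP_3_17).delta_g < fold(AR_HP_3_9).delta_g


def test_ctr_series_stability_increases_with_repeat_count():
    energies = [fold(seq).delta_g for _, seq in sorted(CTR_HP_SERIES.items())]
    assert all(b <= a for a, b in zip(energies, energies[1:]))


def test_compare_variants_report():
    specs = [
        VariantSpec("Ref-HP", ((REF_HP, 1),)),
        VariantSpec("LOI-HP", ((LOI_HP, 1),)),
        VariantSpec("LOI-HP-copy", ((LOI_HP, 1),)),
    ]
    report = compare_variants(specs)
    assert list(report.name) == ["Ref-HP", "LOI-HP", "LOI-HP-copy"]
    loi_rows = report[report.name.str.startswith("LOI")]
    assert loi_rows.delta_g_kcal_mol.nunique() == 1
    assert loi_rows.longest_cag_stem_units.nunique() == 1


def test_printed_stem_count_check_reports_discrepancies():
    """With synthetic flanks the check must report, never reconcile."""
    report = check_printed_stem_counts("U" * 15, "A" * 15)  # synthetic flanks
    assert set(report.columns) >= {"observed_stem_units",
                                   "expected_stem_units", "matches"}
    assert list(report.expected_stem_units) == [15, 25]
    assert (report.matches == (report.observed_stem_units
                               == report.expected_stem_units)).all()


def test_vienna_output_records_engine_and_settings(tmp_path):
    path = tmp_path / "hp.vienna"
    write_vienna(fold(CTR_HP_CAG7), path, name="cag7")
    text = path.read_text()
    assert "ViennaRNA" in text and "Turner-1999" in text
    assert CTR_HP_CAG7 in text
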