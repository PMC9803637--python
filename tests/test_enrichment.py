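"""Ranking, the weighted KS running-sum statistic, and its permutation null."""

import numpy as np
import pytest

from tnrkit.enrichment import (
    brute_force_enrichment_score,
    enrichment_score,
    permutation_test,
    rank_by_logfc,
    run_family,
)
from tnrkit.synthetic_data import SimulationSpec, synth_ranked_list
from tnrkit.tnr_catalog import GeneSetFamily


def test_rank_descending_with_documented_tie_rule():
    ranked = rank_by_logfc({"A": 2.0, "B": -1.0, "C": 0.0})
    assert ranked.genes == ["A", "C", "B"]
    tied = rank_by_logfc({"B": 1.0, "A": 1.0})
    assert tied.genes == ["A", "B"]


def test_ranking_invariant_under_input_order(rng):
    table = {f"g{i}": float(s)
             for i, s in enumerate(rng.normal(size=200))}
    shuffled = dict(sorted(table.items(), key=lambda kv: kv[1]))
    assert rank_by_logfc(table).entries == rank_by_logfc(shuffled).entries


def test_rank_rejects_non_finite_scores():
    with pytest.raises(ValueError, match="non-finite"):
        rank_by_logfc({"A": float("nan")})


def test_single_member_at_top_gives_es_one():
    table = {f"g{i}": float(10 - i) for i in range(10)}
    ranked = rank_by_logfc(table)
    es, _ = enrichment_score(ranked, {"g0"})
    assert es == pytest.approx(1.0)


def test_single_member_at_bottom_matches_hand_evaluation():
    # 9 misses of -1/9 each precede the hit: ES = -1 by maximum deviation
    table = {f"g{i}": float(10 - i) for i in range(10)}
    ranked = rank_by_logfc(table)
    es, running = enrichment_score(ranked, {"g9"})
    assert es == pytest.approx(-1.0)
    assert running[-1] == pytest.approx(0.0, abs=1e-12)


def test_es_matches_brute_force_on_random_instances(rng):
    for _ in range(200):
        n = int(rng.integers(10, 60))
        scores = {f"g{i}": float(s) for i, s in enumerate(rng.normal(size=n))}
        ranked = rank_by_logfc(scores)
        k = int(rng.integers(1, max(2, n // 3)))
        members = set(rng.choice(list(scores), size=k, replace=False))
        es, _ = enrichment_score(ranked, members)
        assert abs(es - brute_force_enrichment_score(ranked, members)) < 1e-12
        assert -1.0 <= es <= 1.0


def test_reversing_a_tie_free_list_negates_es(rng):
    scores = np.sort(rng.normal(size=40))[::-1]
    table = {f"g{i}": float(s) for i, s in enumerate(scores)}
    ranked = rank_by_logfc(table)
    members = {f"g{i}" for i in (0, 3, 7, 11)}
    es_fwd, _ = enrichment_score(ranked, members)
    mirrored = {g: -s for g, s in table.items()}
    es_rev, _ = enrichment_score(rank_by_logfc(mirrored), members)
    assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


def test_no_member_in_list_is_rejected():
    ranked = rank_by_logfc({"A": 1.0, "B": 0.5})
    with pytest.raises(ValueError, match="no gene-set member"):
        enrichment_score(ranked, {"Z"})


def test_permutation_test_is_deterministic_under_seed():
    spec = SimulationSpec(seed=5, n_genes=300, effect_size=-1.0)
    targets = {f"G{i:05d}" for i in range(30)}
    scores, _ = synth_ranked_list(spec, targets)
    ranked = rank_by_logfc(scores)
    a = permutation_test(ranked, targets, n_perm=200, seed=42)
    b = permutation_test(ranked, targets, n_perm=200, seed=42)
    assert (a.es, a.nes, a.p_nominal) == (b.es, b.nes, b.p_nominal)
    c = permutation_test(ranked, targets, n_perm=200, seed=43)
    assert (a.nes, a.p_nominal) != (c.nes, c.p_nominal)


def test_p_value_never_zero_and_floored():
    spec = SimulationSpec(seed=8, n_genes=500, effect_size=-5.0,
                          noise_sd=0.5)
    targets = {f"G{i:05d}" for i in range(50)}
    scores, _ = synth_ranked_list(spec, targets)
    res = permutation_test(rank_by_logfc(scores), targets, n_perm=100, seed=1)
    assert res.p_nominal >= 1.0 / (100 + 1)
    assert res.es < 0 and res.nes < 0


def test_planted_negative_shift_is_detected():
    spec = SimulationSpec(seed=21, n_genes=1000, effect_size=-2.0)
    targets = {f"G{i:05d}" for i in range(60)}
    scores, _ = synth_ranked_list(spec, targets)
    res = permutation_test(rank_by_logfc(scores), targets,
                           n_perm=500, seed=9)
    assert res.es < 0
    assert res.p_nominal < 0.05


def test_run_family_identical_sets_give_identical_es():
    scores = {f"g{i}": float(50 - i) for i in range(50)}
    ranked = rank_by_logfc(scores)
    members = {"g1", "g4", "g7"}
    family = GeneSetFamily("CTG", [10, 11, 12],
                           {10: set(members), 11: set(members),
                            12: set(members)})
    results = run_family(ranked, family, n_perm=50, seed=0)
    assert len(results) == 3
    assert len({r.es for r in results}) == 1


def test_run_family_drops_empty_intersections():
    scores = {f"g{i}": float(5 - i) for i in range(5)}
    ranked = rank_by_logfc(scores)
    family = GeneSetFamily("CTG", [10, 11],
                           {10: {"g0", "g2", "absent"}, 11: {"absent"}})
    results = run_family(ranked, family, n_perm=20, seed=0)
    assert [r.set_name for r in results] == ["CTG_GE_10NT"]
    assert results[0].set_size == 2


def test_run_family_requires_nesting():
    ranked = rank_by_logfc({"a": 1.0, "b": 0.0})
    family = GeneSetFamily("CTG", [10, 11], {10: {"a"}, 11: {"b"}})
    with pytest.raises(ValueError, match="not nested"):
        run_family(ranked, family, n_perm=10, seed=0)
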