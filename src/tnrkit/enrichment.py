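"""Preranked gene-set enrichment with a gene-label permutation null.

Implements the weighted Kolmogorov-Smirnov running-sum statistic of
preranked GSEA: genes are ordered by log fold change, the running sum gains
``|score|^p / sum_members |score|^p`` at member positions and loses
``1/(N - n_members)`` elsewhere, and the enrichment score (ES) is the
signed maximum deviation.  The null distribution comes from random member
sets of the same size drawn without replacement; the normalized enrichment
score (NES) divides ES by the mean magnitude of same-sign null scores, and
the nominal permutation p-value carries the standard +1 correction so it is
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tnrkit.tnr_catalog import GeneSetFamily


@dataclass
class RankedList:
    """Genes sorted by descending score (ties broken by gene id)."""

    entries: list[tuple[str, float]]
    metric_name: str = "logFC"

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids in a ranked list must be unique")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    es: float
    nes: float
    p_nominal: float
    n_perm: int
    seed: int
    nes_defined: bool = True


def rank_by_logfc(table: dict[str, float],
                  metric_name: str = "logFC") -> RankedList:
    """Stable descending sort by score, ties broken by gene id."""
    for gene, score in table.items():
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for gene {gene}: {score}")
    entries = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList(entries=entries, metric_name=metric_name)


def _running_sum(scores: np.ndarray, member_mask: np.ndarray,
                 weight_p: float = 1.0) -> np.ndarray:
    n = scores.size
    k = int(member_mask.sum())
    if k == 0 or k == n:
        raise ValueError("member set must be a proper nonempty subset")
    w = np.abs(scores) ** weight_p
    hit = np.where(member_mask, w, 0.0)
    denom = hit.sum()
    if denom == 0:
        # all member scores are exactly zero: fall back to unweighted steps
        hit = member_mask.astype(float)
        denom = float(k)
    p_hit = np.cumsum(hit) / denom
    p_miss = np.cumsum(~member_mask) / (n - k)
    return p_hit - p_miss


#: two extremes of the running sum closer than this are a tie; the positive
#: extreme wins, so the statistic is stable against rounding order
_ES_TIE_TOL = 1e-12


def _es_from_running(running: np.ndarray) -> float:
    mx = float(running.max())
    mn = float(running.min())
    return mn if -mn > mx + _ES_TIE_TOL else mx


def enrichment_score(
    ranked: RankedList,
    members: set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    Members absent from the ranked list are ignored; raises if no member is
    present (the set is skipped by callers, matching how empty sets are
    dropped from enrichment reports).
    """
    genes = ranked.genes
    mask = np.fromiter((g in members for g in genes), dtype=bool,
                       count=len(genes))
    if not mask.any():
        raise ValueError("no gene-set member present in the ranked list")
    running = _running_sum(ranked.scores, mask, weight_p)
    return _es_from_running(running), running


def _null_es(scores: np.ndarray, k: int, n_perm: int,
             rng: np.random.Generator, weight_p: float = 1.0) -> np.ndarray:
    """Vectorized ES values for ``n_perm`` random member sets of size k."""
    n = scores.size
    w = np.abs(scores) ** weight_p
    # random size-k subsets per row, via argpartition of random keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    hit = np.where(masks, w, 0.0)
    denom = hit.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hit[zero] = masks[zero].astype(float)
        denom[zero] = float(k)
    p_hit = np.cumsum(hit, axis=1) / denom
    p_miss = np.cumsum(~masks, axis=1) / (n - k)
    running = p_hit - p_miss
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(-mn > mx + _ES_TIE_TOL, mn, mx)


def permutation_test(
    ranked: RankedList,
    members: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """Permutation null for one gene set: ES, NES, nominal p.

    Null ES come from ``n_perm`` random gene-label sets of the observed
    intersection size.  NES = ES / mean(|null ES| of the same sign as ES);
    p = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign).
    When no null shares the sign of ES, NES is undefined and p is reported
    at its 1/(n_perm+1) floor with ``nes_defined`` false.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    es, _ = enrichment_score(ranked, members, weight_p)
    genes = ranked.genes
    k = sum(g in members for g in genes)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.scores, k, n_perm, rng, weight_p)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, bool)
    n_same = int(same_sign.sum())
    if n_same == 0:
        return EnrichmentResult(set_name, k, es, float("nan"),
                                1.0 / (n_perm + 1), n_perm, seed,
                                nes_defined=False)
    null_same = null[same_sign]
    nes = es / float(np.mean(np.abs(null_same)))
    extreme = int(np.sum(np.abs(null_same) >= abs(es)))
    p = (1 + extreme) / (1 + n_same)
    return EnrichmentResult(set_name, k, es, nes, p, n_perm, seed)


def run_family(
    ranked: RankedList,
    family: GeneSetFamily,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[EnrichmentResult]:
    """One enrichment result per family threshold with a nonempty intersection.

    Thresholds whose set has no member in the ranked list are omitted.  Each
    threshold uses an independent, seed-derived permutation stream.
    """
    if not family.check_nested():
        raise ValueError("gene-set family is not nested")
    present = set(ranked.genes)
    results: list[EnrichmentResult] = []
    for offset, t in enumerate(family.thresholds):
        members = family.sets.get(t, set())
        if not members & present:
            continue
        results.append(
            permutation_test(ranked, members, n_perm=n_perm,
                             seed=seed + offset, weight_p=weight_p,
                             set_name=family.set_name(t))
        )
    return results


def brute_force_enrichment_score(
    ranked: RankedList, members: set[str], weight_p: float = 1.0
) -> float:
    """Independent loop evaluation of the running-sum definition (test oracle)."""
    genes = ranked.genes
    scores = [s for _, s in ranked.entries]
    in_set = [g in members for g in genes]
    n = len(genes)
    k = sum(in_set)
    denom = sum(abs(s) ** weight_p for s, m in zip(scores, in_set) if m)
    running = 0.0
    mx = mn = 0.0
    for s, m in zip(scores, in_set):
        if m:
            running += (abs(s) ** weight_p) / denom if denom else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        mx = max(mx, running)
        mn = min(mn, running)
    return mn if -mn > mx + _ES_TIE_TOL else mx
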