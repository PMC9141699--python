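"""One-tailed preranked gene-set enrichment on the survival ranking.

The ranking metric is ``-log10(p)`` from the gene-level Cox screen, so genes
with strong survival signal sit at the top of the list.  Only the top end is
scanned: the enrichment score is the *positive* maximum of the classic
weighted Kolmogorov-Smirnov running sum, and the permutation p-value is
one-tailed.  The null is built by drawing random same-size gene sets from the
ranked universe (gene-tag permutation): the upstream statistic is a single
fixed ranking, so phenotype permutation is not available at this stage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import GeneSet
from .survival import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_score", "gsea_pvalue", "select_candidates"]

DEFAULT_MIN_SIZE = 3
DEFAULT_MAX_SIZE = 500


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    n_overlap: int
    seed: int | None = None
    n_perm: int = 0


def _es_from_hits(metric: np.ndarray, hit_positions: np.ndarray, weight: float) -> float:
    """Positive maximum of the running sum for hits at the given 0-based ranks."""
    n = metric.shape[0]
    k = hit_positions.shape[0]
    hit_w = np.abs(metric[hit_positions]) ** weight
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics zero: fall back to unweighted increments
        hit_w = np.ones(k)
        denom = float(k)
    if n == k:  # degenerate: set covers the whole universe
        return 1.0
    miss_dec = 1.0 / (n - k)
    # running sum evaluated at each hit position (its local maximum candidates)
    order = np.argsort(hit_positions)
    pos = hit_positions[order]
    gains = np.cumsum(hit_w[order]) / denom
    misses_before = (pos + 1 - np.arange(1, k + 1)) * miss_dec
    peaks = gains - misses_before
    return float(max(peaks.max(), 0.0))


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    weight: float = 1.0,
    min_size: int = DEFAULT_MIN_SIZE,
) -> float:
    """One-tailed weighted KS enrichment score of a set on a ranked list.

    Hit increments are proportional to ``|metric|^weight``; each miss
    decrements ``1/(N - k)``.  The score is the maximum positive deviation of
    the running sum, 1.0 when the set occupies the top ranks.
    """
    positions = _hit_positions(ranked, gene_set)
    if positions is None or positions.size < min_size:
        raise ValueError(
            f"set {gene_set.name!r}: overlap with ranked list below min_size={min_size}"
        )
    return _es_from_hits(ranked.metric, positions, weight)


def _hit_positions(ranked: RankedGeneList, gene_set: GeneSet):
    index = {g: i for i, g in enumerate(ranked.gene_ids)}
    positions = np.array(sorted(index[g] for g in gene_set.genes if g in index), dtype=int)
    if positions.size == 0:
        return None
    return positions


def gsea_pvalue(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight: float = 1.0,
    min_size: int = DEFAULT_MIN_SIZE,
    method: str = "montecarlo",
) -> EnrichmentResult:
    """One-tailed enrichment p-value by gene-tag permutation.

    The null draws random same-size gene sets from the ranked universe;
    ``p = (#{es_null >= es_obs} + 1) / (n_perm + 1)`` (plus-one convention:
    this stage is a screen and a zero p would break -log reporting).
    ``method="exact"`` enumerates every placement instead (small universes).
    """
    positions = _hit_positions(ranked, gene_set)
    if positions is None:
        raise ValueError(f"set {gene_set.name!r} has no overlap with the ranked universe")
    k = positions.size
    if k < min_size:
        raise ValueError(f"set {gene_set.name!r}: overlap {k} below min_size={min_size}")
    es_obs = _es_from_hits(ranked.metric, positions, weight)
    n = len(ranked)
    if method == "exact":
        total = math.comb(n, k)
        if total > 500_000:
            raise ValueError("exact enumeration infeasible for this universe")
        count = sum(
            _es_from_hits(ranked.metric, np.array(combo), weight) >= es_obs
            for combo in combinations(range(n), k)
        )
        return EnrichmentResult(gene_set.name, es_obs, count / total, k, seed, total)
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        draw = rng.choice(n, size=k, replace=False)
        if _es_from_hits(ranked.metric, np.sort(draw), weight) >= es_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return EnrichmentResult(gene_set.name, es_obs, p, k, seed, n_perm)


def select_candidates(results, alpha: float = 0.05):
    """Names of sets with enrichment p below ``alpha`` (no multiplicity
    correction: the composite-score permutation test downstream is the
    confirmatory filter)."""
    if not results:
        raise ValueError("no enrichment results to select from")
    return [r.set_name for r in results if r.p_value < alpha]
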