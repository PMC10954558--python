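"""Preranked gene-set enrichment analysis (GSEA) on factor gene loadings.

Genes are ordered by a real-valued ranking metric (here, factor loadings).
For a gene set, the enrichment score (ES) is the maximal deviation from
zero of a running sum that increments at set members (weighted by
|metric|^p, normalized within the set) and decrements uniformly at
non-members.  Significance comes from gene-label permutations: null sets of
the same size drawn at random from the ranked universe.  NES and FDR use
the sign-stratified normalization of the original GSEA definition, and the
leading edge ("core genes") is the run of set members up to the running-sum
extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "preranked_gsea",
    "leading_edge",
]


@dataclass
class EnrichmentResult:
    gene_set: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge_genes: list[str] = field(default_factory=list)


def _order_by_metric(genes, metric):
    genes = np.asarray(genes)
    metric = np.asarray(metric, dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list has duplicate gene ids")
    if not np.all(np.isfinite(metric)):
        raise ValueError("ranking metric must be finite")
    # stable sort: metric ties broken by input order
    order = np.argsort(-metric, kind="stable")
    return genes[order], metric[order]


def _es_from_positions(
    positions: np.ndarray, abs_metric_sorted: np.ndarray, n: int, p: float
):
    """ES and extremum position given sorted hit positions (0-based).

    Returns (es, extremum_hit_index) where the index is into the sorted
    hit positions (for leading-edge extraction); the extremum for positive
    ES is *after* that hit, for negative ES *before* it.
    """
    m = positions.size
    if m == 0 or m == n:
        return 0.0, -1
    w = abs_metric_sorted[positions] ** p
    total = w.sum()
    if total <= 0:
        # all-zero metric over the set: fall back to unweighted steps
        w = np.ones(m)
        total = float(m)
    hit_cum = np.cumsum(w) / total
    miss_step = 1.0 / (n - m)
    # running sum just after each hit, and just before each hit
    misses_before = positions - np.arange(m)  # misses strictly before hit j
    after = hit_cum - (misses_before + 0) * miss_step
    before = np.concatenate([[0.0], hit_cum[:-1]]) - misses_before * miss_step
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = float(after[i_max])
    es_neg = float(before[i_min])
    if es_pos >= -es_neg:
        return es_pos, i_max
    return es_neg, i_min


def enrichment_score(ranked_genes, metric, gene_set, p: float = 1.0):
    """Weighted Kolmogorov-Smirnov-style enrichment score of one gene set.

    Returns (es, leading_edge_genes).
    """
    genes, met = _order_by_metric(ranked_genes, metric)
    index = {g: i for i, g in enumerate(genes)}
    positions = np.array(sorted(index[g] for g in gene_set if g in index))
    n = genes.size
    es, i_ext = _es_from_positions(positions, np.abs(met), n, p)
    if es > 0:
        le = [genes[j] for j in positions[: i_ext + 1]]
    elif es < 0:
        le = [genes[j] for j in positions[i_ext:]]
    else:
        le = []
    return es, le


def preranked_gsea(
    ranked_genes,
    metric,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 10000,
    min_size: int = 10,
    max_size: int = 500,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a GMT-style gene-set collection.

    Sets are intersected with the ranked universe; those outside
    [min_size, max_size] are skipped.  The null distribution per set size
    is built from ``n_perm`` random same-size gene samples; p-values and
    NES are computed within the sign stratum of the observed ES, and FDR q
    is the sign-stratified NES-ratio of the original GSEA definition.
    Deterministic given ``seed``.
    """
    genes, met = _order_by_metric(ranked_genes, metric)
    n = genes.size
    abs_met = np.abs(met)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        pos = np.array(sorted({index[g] for g in members if g in index}), dtype=int)
        if pos.size < min_size or pos.size > max_size or pos.size == n:
            continue
        kept.append((name, pos))

    # shared null draws per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for _, pos in kept:
        m = pos.size
        if m in null_by_size:
            continue
        null = np.empty(n_perm)
        for b in range(n_perm):
            sample = np.sort(rng.choice(n, size=m, replace=False))
            null[b], _ = _es_from_positions(sample, abs_met, n, weight)
        null_by_size[m] = null

    results = []
    obs_nes = []
    null_nes_pools: list[np.ndarray] = []
    for name, pos in kept:
        es, i_ext = _es_from_positions(pos, abs_met, n, weight)
        null = null_by_size[pos.size]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            p_val = (1 + int((same >= es).sum())) / (1 + max(1, same.size))
            denom = same.mean() if same.size else np.nan
        else:
            same = neg_null
            p_val = (1 + int((same <= es).sum())) / (1 + max(1, same.size))
            denom = -same.mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom != 0 else np.nan
        # normalized null (for FDR): each null ES scaled by its stratum mean
        with np.errstate(invalid="ignore", divide="ignore"):
            norm_null = np.concatenate([
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                neg_null / abs(neg_null.mean()) if neg_null.size else neg_null,
            ])
        null_nes_pools.append(norm_null)
        obs_nes.append(nes)
        if es > 0:
            le = [genes[j] for j in pos[: i_ext + 1]]
        elif es < 0:
            le = [genes[j] for j in pos[i_ext:]]
        else:
            le = []
        results.append(
            EnrichmentResult(
                gene_set=name, size=pos.size, es=float(es), nes=float(nes),
                p_value=float(min(1.0, p_val)), fdr=np.nan,
                leading_edge_genes=le,
            )
        )

    # sign-stratified FDR: ratio of null vs observed NES tail fractions
    all_null = np.concatenate(null_nes_pools) if null_nes_pools else np.array([])
    obs = np.array(obs_nes, dtype=float)
    for r, nes in zip(results, obs):
        if not np.isfinite(nes):
            r.fdr = np.nan
            continue
        if nes >= 0:
            null_frac = (all_null >= nes).mean() if all_null.size else np.nan
            null_base = (all_null >= 0).mean() if all_null.size else np.nan
            obs_frac = (obs[np.isfinite(obs)] >= nes).mean()
            obs_base = (obs[np.isfinite(obs)] >= 0).mean()
        else:
            null_frac = (all_null <= nes).mean() if all_null.size else np.nan
            null_base = (all_null < 0).mean() if all_null.size else np.nan
            obs_frac = (obs[np.isfinite(obs)] <= nes).mean()
            obs_base = (obs[np.isfinite(obs)] < 0).mean()
        if obs_frac and obs_base and null_base:
            r.fdr = float(min(1.0, (null_frac / null_base) / (obs_frac / obs_base)))
        else:
            r.fdr = 1.0
    return results


def leading_edge(result: EnrichmentResult, ranked_genes=None) -> list[str]:
    """Core genes of one enrichment: members at or before the running-sum
    maximum (positive ES) or at or after the minimum (negative ES)."""
    return list(result.leading_edge_genes)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_set": [r.gene_set for r in results],
            "size": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p_value for r in results],
            "FDR": [r.fdr for r in results],
            "leading_edge": ["|".join(r.leading_edge_genes) for r in results],
        }
    )
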