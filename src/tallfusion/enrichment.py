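"""Pre-ranked gene-set enrichment: weighted running-sum score with a
gene-set permutation null.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
statistic: walking down the ranked list, the running sum increments by
|score|^weight / sum(|score|^weight over hits) at set members and
decrements by 1/(N - |set|) at non-members; ES is the extremum of the
running sum by absolute value. The null distribution is built by resampling
gene sets of equal size (this module consumes pre-ranked lists only, so
phenotype permutation is not applicable); the permutation p-value is
(1 + #{|ES_null| >= |ES|}) / (n_perm + 1) and NES divides ES by the mean
|ES_null| among null scores of matching sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: tuple[str, ...]


def _validate_ranked(genes: list[str], scores: np.ndarray) -> None:
    if len(genes) != len(scores):
        raise ValueError("genes and scores must have equal length")
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("ranking scores must be sorted in descending order")


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Running enrichment sum over the ranked list for one hit mask."""
    n = len(scores)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    denom = w[hit_mask].sum()
    if denom == 0:
        logger.warning("all hit weights are zero; falling back to unweighted increments")
        w = np.ones(n)
        denom = float(n_hit)
    steps = np.where(hit_mask, w / denom, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray | list[float],
    gene_set: GeneSet | set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of a gene set against a ranked list.

    Returns (ES, running sum). ES is the running-sum value of largest
    absolute magnitude (earliest position on ties); |ES| <= 1.
    """
    scores = np.asarray(scores, dtype=float)
    _validate_ranked(ranked_genes, scores)
    members = set(gene_set.genes) if isinstance(gene_set, GeneSet) else set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    running = _running_sum(scores, hit_mask, weight)
    extremum = int(np.abs(running).argmax())  # argmax is earliest on ties
    return float(running[extremum]), running


def leading_edge_genes(
    ranked_genes: list[str], running: np.ndarray, hit_mask: np.ndarray
) -> tuple[str, ...]:
    """Hits up to (positive ES) or from (negative ES) the running-sum extremum."""
    extremum = int(np.abs(running).argmax())
    if running[extremum] >= 0:
        idx = np.flatnonzero(hit_mask[: extremum + 1])
    else:
        idx = extremum + np.flatnonzero(hit_mask[extremum:])
    return tuple(ranked_genes[i] for i in idx)


def _null_es(
    scores: np.ndarray, set_size: int, n_perm: int, weight: float,
    rng: np.random.Generator, chunk: int = 256,
) -> np.ndarray:
    """Null ES by resampling gene sets of equal size (vectorized in chunks)."""
    n = len(scores)
    w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    miss = -1.0 / (n - set_size)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        steps = np.full((m, n), miss)
        # m random subsets of positions, without replacement per row
        pos = np.argsort(rng.random((m, n)), axis=1)[:, :set_size]
        rows = np.repeat(np.arange(m), set_size)
        hit_w = w[pos.ravel()]
        denom = w[pos].sum(axis=1)
        denom = np.where(denom == 0, pos.shape[1], denom)  # degenerate all-zero sets
        steps[rows, pos.ravel()] = hit_w / np.repeat(denom, set_size)
        running = np.cumsum(steps, axis=1)
        idx = np.abs(running).argmax(axis=1)
        out[done : done + m] = running[np.arange(m), idx]
        done += m
    return out


def permutation_test(
    ranked_genes: list[str],
    scores: np.ndarray | list[float],
    gene_set: GeneSet | set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Gene-set permutation test for a pre-ranked enrichment score.

    p = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1); NES = ES / mean(|ES_null|
    restricted to null scores with the same sign as ES). Deterministic for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = np.asarray(scores, dtype=float)
    members = set(gene_set.genes) if isinstance(gene_set, GeneSet) else set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    es, running = enrichment_score(ranked_genes, scores, members, weight)
    set_size = int(hit_mask.sum())

    rng = np.random.default_rng(seed)
    null = _null_es(scores, set_size, n_perm, weight, rng)
    if np.all(null == 0):
        raise ValueError("degenerate permutation null (all zero)")
    p = (1 + int((np.abs(null) >= abs(es)).sum())) / (n_perm + 1)
    same_sign = null > 0 if es >= 0 else null < 0
    if same_sign.any():
        nes = es / np.abs(null[same_sign]).mean()
    else:
        nes = float("nan")
        logger.warning("no null scores share the observed ES sign; NES undefined")
    name = gene_set.name if isinstance(gene_set, GeneSet) else "gene_set"
    return EnrichmentResult(
        gene_set=name,
        es=es,
        nes=float(nes),
        p_value=p,
        n_permutations=n_perm,
        leading_edge=leading_edge_genes(ranked_genes, running, hit_mask),
    )


def enrichment_from_ranked_table(
    ranked: pd.DataFrame, gene_sets: list[GeneSet], n_perm: int = 1000,
    seed: int = 0, weight: float = 1.0,
) -> pd.DataFrame:
    """Run the permutation test for several gene sets against one ranked
    table (columns gene, score) and BH-adjust the p-values across sets."""
    from statsmodels.stats.multitest import multipletests

    genes = list(ranked["gene"])
    scores = ranked["score"].to_numpy(dtype=float)
    results = [
        permutation_test(genes, scores, gs, n_perm=n_perm, seed=seed + i, weight=weight)
        for i, gs in enumerate(gene_sets)
    ]
    table = pd.DataFrame(
        {
            "gene_set": [r.gene_set for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "n_leading_edge": [len(r.leading_edge) for r in results],
        }
    )
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
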