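"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the package itself: Fisher p-values by direct enumeration over
tables with fixed margins, Hamming scans by per-offset character loops,
enrichment scores by a literal running-sum loop, and BH adjustment by the
textbook step-up recursion.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed-margin tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    denom = comb(n, col1)

    def prob(x: int) -> float:
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


def hamming_scan_loop(window: str, barcode: str) -> tuple[int, int]:
    """Leftmost minimum-Hamming offset by per-offset comparison."""
    if len(window) < len(barcode):
        return -1, len(barcode) + 1
    best_pos, best_mm = 0, len(barcode) + 1
    for off in range(len(window) - len(barcode) + 1):
        mm = sum(x != y for x, y in zip(window[off : off + len(barcode)], barcode))
        if mm < best_mm:
            best_pos, best_mm = off, mm
    return best_pos, best_mm


def enrichment_score_loop(
    ranked_genes: list[str], scores, members: set[str], weight: float = 1.0
) -> float:
    """Literal weighted running-sum enrichment score."""
    scores = list(map(float, scores))
    n = len(ranked_genes)
    hits = [g in members for g in ranked_genes]
    n_hit = sum(hits)
    weights = [abs(s) ** weight if weight != 0 else 1.0 for s in scores]
    denom = sum(w for w, h in zip(weights, hits) if h)
    running, es, best = 0.0, 0.0, -1.0
    for i in range(n):
        if hits[i]:
            running += weights[i] / denom
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > best:
            best, es = abs(running), running
    return es


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def single_hit_loglik(f: float, doses, tested, responding) -> float:
    """Direct single-hit log-likelihood (independent of the fitted path)."""
    total = 0.0
    for d, n, r in zip(doses, tested, responding):
        p = 1.0 - np.exp(-d * f)
        total += r * np.log(p) + (n - r) * (-d * f)
    return total
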