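"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed, and returns the
simulated data together with a truth table so that downstream filters,
demultiplexers and scorers can be benchmarked without any external download.

The generators emulate the statistical structure the pipeline assumes:

* paired tumor/remission variant tables under binomial read sampling,
* barcoded long reads carrying either a fusion-junction or canonical exon
  structure, with substitution errors,
* two-group negative-binomial expression matrices with a planted up/down
  signature,
* single-hit limiting-dilution dose-response outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .core_io import CountsMatrix, LongRead

BASES = np.array(list("ACGT"))

# exon layout of the modelled transcripts: the 5' gene (TCF7) donates exons
# 1-4 to the fusion; its canonical transcript runs through exon 7; the 3'
# gene (SPI1) donates exons 3-5.
TCF7_EXONS = [f"TCF7_e{i}" for i in range(1, 8)]
SPI1_EXONS = [f"SPI1_e{i}" for i in range(3, 6)]
MARKER_LENGTH = 40


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset; one table per record kind."""

    records: pd.DataFrame
    params: dict = field(default_factory=dict)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    if hits.any():
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Paired tumor/remission variants


def simulate_paired_variants(
    n_somatic: int,
    n_germline: int,
    depth: int = 100,
    tumor_vaf_range: tuple[float, float] | float = (0.1, 0.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate candidate variants with tumor and remission read counts.

    Somatic records draw tumor alt counts ~ Binomial(depth, VAF) with a
    remission VAF of 0; germline records use VAF 0.5 in both samples.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_somatic + n_germline == 0:
        raise ValueError("empty configuration: no variants requested")
    if np.isscalar(tumor_vaf_range):
        lo = hi = float(tumor_vaf_range)
    else:
        lo, hi = map(float, tumor_vaf_range)
    if not (0 < lo <= hi <= 1):
        raise ValueError("tumor VAF range must lie in (0, 1]")

    rng = _rng(seed)
    n = n_somatic + n_germline
    is_somatic = np.zeros(n, dtype=bool)
    is_somatic[:n_somatic] = True
    true_vaf = np.where(is_somatic, rng.uniform(lo, hi, size=n), 0.5)

    tumor_alt = rng.binomial(depth, true_vaf)
    remission_vaf = np.where(is_somatic, 0.0, 0.5)
    remission_alt = rng.binomial(depth, remission_vaf)

    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 1000,
            "ref": "A",
            "alt": "T",
            "tumor_ref": depth - tumor_alt,
            "tumor_alt": tumor_alt,
            "remission_ref": depth - remission_alt,
            "remission_alt": remission_alt,
        }
    )
    truth = SimTruth(
        records=pd.DataFrame(
            {"pos": table["pos"], "is_somatic": is_somatic, "true_vaf": true_vaf}
        ),
        params={"depth": depth, "n_somatic": n_somatic, "n_germline": n_germline},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Barcoded long reads


def make_exon_markers(seed: int = 0) -> dict[str, str]:
    """Fixed random 40-nt marker per exon, plus the fusion junction marker.

    The junction marker spans the last 20 nt of the 5' gene's exon 4 and the
    first 20 nt of the 3' gene's exon 3, i.e. the breakpoint-crossing
    sequence a fusion read must contain.
    """
    # distinct stream key so markers never collide with other generators
    # (e.g. a whitelist) seeded with the same integer
    rng = np.random.default_rng([seed, 0x4D41524B])
    markers = {name: _random_dna(rng, MARKER_LENGTH) for name in TCF7_EXONS + SPI1_EXONS}
    markers["junction"] = markers["TCF7_e4"][-20:] + markers["SPI1_e3"][:20]
    return markers


def fusion_body(markers: dict[str, str]) -> str:
    """Transcript body of a fusion read: 5' exons 1-4 then 3' exons 3-5."""
    return "".join(markers[e] for e in TCF7_EXONS[:4]) + "".join(
        markers[e] for e in SPI1_EXONS
    )


def canonical_body(markers: dict[str, str]) -> str:
    """Transcript body of a canonical read: the intact 5' gene, exons 1-7."""
    return "".join(markers[e] for e in TCF7_EXONS)


def simulate_longreads(
    whitelist: list[str],
    n_cells: int,
    reads_per_cell: int,
    fusion_fraction: float = 0.3,
    sub_error_rate: float = 0.005,
    seed: int = 0,
    marker_seed: int | None = None,
) -> tuple[list[LongRead], SimTruth, dict[str, str]]:
    """Simulate barcoded long reads with fusion or canonical exon structure.

    Each read embeds its cell's 16-nt barcode near the 5' or 3' end (the
    orientation chosen at random; 3'-end barcodes are reverse-complemented),
    followed by a transcript body built from per-exon marker sequences.
    Substitution errors are applied uniformly at ``sub_error_rate``. All
    reads are longer than 250 nt.
    """
    if any(len(bc) != 16 for bc in whitelist):
        bad = [bc for bc in whitelist if len(bc) != 16][:3]
        raise ValueError(f"whitelist barcodes must be 16 nt, got {bad}")
    if not 0 <= fusion_fraction <= 1:
        raise ValueError("fusion_fraction must be in [0, 1]")
    if n_cells > len(whitelist):
        raise ValueError("more cells requested than whitelist barcodes")

    rng = _rng(seed)
    markers = make_exon_markers(marker_seed if marker_seed is not None else seed)
    bodies = {"fusion": fusion_body(markers), "canonical": canonical_body(markers)}

    reads: list[LongRead] = []
    truth_rows = []
    for ci in range(n_cells):
        barcode = whitelist[ci]
        for ri in range(reads_per_cell):
            is_fusion = rng.random() < fusion_fraction
            klass = "fusion" if is_fusion else "canonical"
            body = bodies[klass]
            pad5 = _random_dna(rng, int(rng.integers(0, 20)))
            pad3 = _random_dna(rng, int(rng.integers(0, 20)))
            forward = bool(rng.random() < 0.5)
            if forward:
                seq = pad5 + barcode + body + pad3
            else:
                seq = pad5 + body + reverse_complement(barcode) + pad3
            seq = _apply_substitutions(rng, seq, sub_error_rate)
            read_id = f"cell{ci:03d}_read{ri:04d}"
            reads.append(LongRead(read_id=read_id, sequence=seq))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "barcode": barcode,
                    "read_class": klass,
                    "orientation": "forward" if forward else "reverse_complement",
                }
            )
    truth = SimTruth(
        records=pd.DataFrame(truth_rows),
        params={
            "n_cells": n_cells,
            "reads_per_cell": reads_per_cell,
            "fusion_fraction": fusion_fraction,
            "sub_error_rate": sub_error_rate,
        },
    )
    return reads, truth, markers


def random_whitelist(n: int, seed: int = 0, length: int = 16, min_pairwise_dist: int = 4) -> list[str]:
    """Random barcode whitelist with a minimum pairwise Hamming distance.

    Real 10x whitelists are well separated; enforcing a minimum distance
    keeps one-substitution assignment unambiguous.
    """
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    while len(barcodes) < n:
        cand = _random_dna(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_pairwise_dist for bc in barcodes):
            barcodes.append(cand)
    return barcodes


# ---------------------------------------------------------------------------
# Two-group expression with a planted signature


def simulate_expression(
    n_groupA: int,
    n_groupB: int,
    n_genes: int = 2000,
    n_signature_up: int = 50,
    n_signature_down: int = 50,
    log2_effect: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    mean_log_mu: float = 3.0,
    mean_log_sigma: float = 1.0,
) -> tuple[CountsMatrix, SimTruth]:
    """Negative-binomial counts for two groups with planted signature genes.

    Gene-wise baseline means are drawn log-normally; planted genes are
    shifted by +/- ``log2_effect`` (log2 units) in group A. Gene lengths are
    drawn uniformly on 200-10000 bp so the matrix can feed TPM normalization.
    """
    if min(n_groupA, n_groupB) < 2:
        raise ValueError("each group needs >= 2 samples")
    if n_signature_up + n_signature_down > n_genes:
        raise ValueError("more signature genes than genes")
    if log2_effect < 0:
        raise ValueError("log2_effect must be >= 0")

    rng = _rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"A{i:02d}" for i in range(n_groupA)] + [f"B{i:02d}" for i in range(n_groupB)]
    base_mu = np.exp(rng.normal(mean_log_mu, mean_log_sigma, size=n_genes))

    direction = np.zeros(n_genes)
    planted = rng.choice(n_genes, size=n_signature_up + n_signature_down, replace=False)
    up_idx, down_idx = planted[:n_signature_up], planted[n_signature_up:]
    direction[up_idx] = 1.0
    direction[down_idx] = -1.0

    mu = np.empty((n_genes, len(samples)))
    mu[:, :n_groupA] = (base_mu * 2.0 ** (direction * log2_effect))[:, None]
    mu[:, n_groupA:] = base_mu[:, None]

    # NB parameterized by size r = 1/dispersion, p = r / (r + mu)
    r = 1.0 / max(dispersion, 1e-8)
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = CountsMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(rng.integers(200, 10001, size=n_genes), index=genes),
    )
    truth = SimTruth(
        records=pd.DataFrame(
            {
                "gene": genes,
                "direction": direction.astype(int),
                "is_signature": direction != 0,
            }
        ),
        params={
            "groupA": samples[:n_groupA],
            "groupB": samples[n_groupA:],
            "log2_effect": log2_effect,
            "dispersion": dispersion,
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Limiting dilution


def simulate_limiting_dilution(
    f_true: float,
    doses: list[float] = (2e6, 2e5, 2e4, 2e3),
    n_per_dose: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-hit dose-response outcomes: responders ~ Binom(n, 1-exp(-d*f))."""
    if not 0 < f_true < 1:
        raise ValueError("f_true must be in (0, 1)")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    rng = _rng(seed)
    p_respond = 1.0 - np.exp(-doses * f_true)
    responding = rng.binomial(n_per_dose, p_respond)
    return pd.DataFrame(
        {"dose": doses, "tested": n_per_dose, "responding": responding}
    )
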