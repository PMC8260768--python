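"""Expression normalization, QC, DE stand-in, and signature derivation/scoring.

The signature machinery mirrors the bulk and single-cell readouts used to
characterise ETP-ALL-like transcriptomes:

* TPM normalization from raw counts and gene lengths;
* per-cell QC on ribosomal / mitochondrial read fractions and expressed-gene
  counts;
* a deliberately simple two-group differential-expression stand-in (Welch t
  on log2(CPM+1) with Benjamini-Hochberg adjustment) so the pipeline can run
  end-to-end on synthetic data — externally produced DE tables (e.g. from a
  negative-binomial GLM fit) can be consumed directly in its place;
* signature derivation from a DE table (|fold change| > 2, adjusted p < 0.05);
* bulk signature scoring: z-score each signature gene across samples, take
  the per-sample mean, then z-score those means across samples;
* per-cell module scoring with expression-matched control genes drawn from
  average-expression bins;
* the pre-ranked statistic -sign(log2FC) * log10(adjusted p);
* Pearson correlation of every gene with an anchor gene (e.g. SPI1) with
  top-k / bottom-k selection.

All z-scores use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountsMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    max_ribo_fraction: float = 0.6  # dropped when strictly above
    max_mito_fraction: float = 0.1  # dropped when strictly above
    min_genes: int = 200  # dropped when strictly below

    def __post_init__(self) -> None:
        for name in ("max_ribo_fraction", "max_mito_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# Normalization


def tpm_normalize(matrix: CountsMatrix) -> CountsMatrix:
    """Transcripts-per-million: length-normalized rates rescaled to 1e6.

    Per sample: rate_g = count_g / length_kb_g; TPM_g = rate_g / sum(rate)
    * 1e6, so every column sums to 1e6. An all-zero sample cannot be
    normalized and stays all-zero (warned).
    """
    if matrix.gene_lengths is None:
        raise ValueError("TPM normalization requires gene lengths")
    lengths_kb = matrix.gene_lengths.to_numpy(dtype=float) / 1000.0
    rate = matrix.values.to_numpy(dtype=float) / lengths_kb[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("tpm_normalize: %d all-zero sample(s) left unnormalized", zero.sum())
        totals = np.where(zero, 1.0, totals)
    tpm = rate / totals * 1e6
    return CountsMatrix(
        values=pd.DataFrame(tpm, index=matrix.values.index, columns=matrix.values.columns),
        gene_lengths=matrix.gene_lengths,
    )


def cpm(values: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    totals = values.sum(axis=0).replace(0, 1.0)
    return values / totals * scale


def log_normalize_cp10k(values: pd.DataFrame) -> pd.DataFrame:
    """Counts per 10,000 then log1p — the normalization layer used for
    per-cell scores and correlation ranking."""
    return np.log1p(cpm(values, scale=1e4))


# ---------------------------------------------------------------------------
# Cell QC


def qc_filter_cells(
    matrix: CountsMatrix,
    mito_gene_ids: list[str],
    ribo_gene_ids: list[str],
    thresholds: QCThresholds | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop poor-quality cells; returns (kept cell ids, per-cell QC table).

    A cell is dropped iff ribosomal fraction > 0.6 OR mitochondrial
    fraction > 0.1 OR expressed genes < 200 (strict comparisons).
    """
    thresholds = thresholds or QCThresholds()
    values = matrix.values
    if values.empty:
        raise ValueError("empty matrix")
    for ids, label in ((mito_gene_ids, "mito"), (ribo_gene_ids, "ribo")):
        unknown = set(ids) - set(values.index)
        if unknown:
            raise ValueError(f"{label} gene ids not in matrix: {sorted(unknown)[:5]}")
    totals = values.sum(axis=0)
    safe_totals = totals.replace(0, 1.0)
    mito_frac = values.loc[mito_gene_ids].sum(axis=0) / safe_totals
    ribo_frac = values.loc[ribo_gene_ids].sum(axis=0) / safe_totals
    n_genes = (values > 0).sum(axis=0)
    dropped = (
        (ribo_frac > thresholds.max_ribo_fraction)
        | (mito_frac > thresholds.max_mito_fraction)
        | (n_genes < thresholds.min_genes)
    )
    qc = pd.DataFrame(
        {
            "cell_id": values.columns,
            "ribo_fraction": ribo_frac.to_numpy(),
            "mito_fraction": mito_frac.to_numpy(),
            "n_genes": n_genes.to_numpy(),
            "kept": ~dropped.to_numpy(),
        }
    )
    kept = [c for c, ok in zip(values.columns, ~dropped) if ok]
    logger.info("qc_filter_cells: n_in=%d kept=%d", values.shape[1], len(kept))
    return kept, qc


# ---------------------------------------------------------------------------
# Differential expression stand-in


def differential_expression(
    matrix: CountsMatrix | pd.DataFrame,
    group_a_ids: list[str],
    group_b_ids: list[str],
) -> pd.DataFrame:
    """Welch-t DE on log2(CPM+1), BH-adjusted across genes.

    Per gene: log2 fold change = mean(log2 CPM+1, group A) - mean(group B);
    two-sided Welch t p-value; Benjamini-Hochberg adjusted p. Genes with
    zero variance in both groups get p = 1.
    """
    values = matrix.values if isinstance(matrix, CountsMatrix) else matrix
    if min(len(group_a_ids), len(group_b_ids)) < 2:
        raise ValueError("each group needs >= 2 samples")
    logcpm = np.log2(cpm(values) + 1.0)
    a = logcpm[group_a_ids].to_numpy()
    b = logcpm[group_b_ids].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": values.index,
            "log2_fold_change": log2fc,
            "p_value": p,
            "adjusted_p": padj,
        }
    ).reset_index(drop=True)


def derive_signature(
    de_table: pd.DataFrame, fc_thresh: float = 2.0, padj_thresh: float = 0.05,
    name_prefix: str = "signature",
) -> tuple[GeneSet | None, GeneSet | None]:
    """Split a DE table into up/down gene sets at |FC| > fc_thresh (strict)
    and adjusted p < padj_thresh (strict). Returns None for an empty side."""
    log2_thresh = np.log2(fc_thresh)
    sig = de_table["adjusted_p"] < padj_thresh
    up = de_table.loc[sig & (de_table["log2_fold_change"] > log2_thresh), "gene"]
    down = de_table.loc[sig & (de_table["log2_fold_change"] < -log2_thresh), "gene"]
    up_set = GeneSet(f"{name_prefix}_up", "upregulated", tuple(up)) if len(up) else None
    down_set = GeneSet(f"{name_prefix}_down", "downregulated", tuple(down)) if len(down) else None
    return up_set, down_set


# ---------------------------------------------------------------------------
# Signature scoring


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    """Row-wise z-scores across columns with sample (n-1) SD."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mean) / sd


def _subset_signature(values: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    present = [g for g in gene_set.genes if g in values.index]
    absent = set(gene_set.genes) - set(present)
    if absent:
        logger.warning(
            "signature %s: %d gene(s) absent from matrix, dropped", gene_set.name, len(absent)
        )
    if not present:
        raise ValueError(f"signature {gene_set.name}: no genes present in matrix")
    return values.loc[present]


def score_signature_bulk(
    matrix: CountsMatrix | pd.DataFrame, gene_set: GeneSet
) -> pd.DataFrame:
    """Bulk signature score: per-gene z across samples -> per-sample mean
    -> z of means across samples.

    The per-gene z-scoring makes the score invariant to affine per-gene
    transformations of the input; constant genes (undefined z) are dropped
    with a warning. Requires >= 2 samples.
    """
    values = matrix.values if isinstance(matrix, CountsMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("bulk scoring needs >= 2 samples")
    sub = _subset_signature(values, gene_set).to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "signature %s: %d constant gene(s) dropped", gene_set.name, int(constant.sum())
        )
        sub = sub[~constant]
        if not len(sub):
            raise ValueError(f"signature {gene_set.name}: all genes constant")
    z = _zscore_columns(sub)
    raw_mean = z.mean(axis=0)
    rescaled = (raw_mean - raw_mean.mean()) / raw_mean.std(ddof=1)
    return pd.DataFrame(
        {"sample_id": values.columns, "raw_mean": raw_mean, "score": rescaled}
    )


def score_signature_cells(
    matrix: pd.DataFrame,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell module score with expression-matched control genes.

    The matrix must be log-normalized (see ``log_normalize_cp10k``). Genes
    are binned into ``n_bins`` groups by average expression across cells;
    for every signature gene, ``n_ctrl`` control genes are drawn from its
    bin (without replacement when the bin is large enough, otherwise with
    replacement, logged). The raw score is mean(signature genes) -
    mean(control genes); scores are then z-scored across cells.
    """
    if matrix.shape[0] < n_bins:
        raise ValueError(f"need >= {n_bins} genes to build expression bins")
    rng = np.random.default_rng(seed)
    sig_genes = [g for g in gene_set.genes if g in matrix.index]
    if not sig_genes:
        raise ValueError(f"signature {gene_set.name}: no genes present in matrix")

    avg = matrix.mean(axis=1)
    # equal-occupancy bins on the rank of the average expression
    bin_of = pd.Series(
        pd.qcut(avg.rank(method="first"), q=n_bins, labels=False), index=matrix.index
    )
    genes_by_bin = {b: idx.to_numpy() for b, idx in matrix.index.to_series().groupby(bin_of)}

    control_genes: list[str] = []
    for gene in sig_genes:
        pool = genes_by_bin[bin_of[gene]]
        replace = len(pool) < n_ctrl
        if replace:
            logger.warning(
                "score_signature_cells: bin of %s has %d genes < n_ctrl=%d; "
                "sampling with replacement", gene, len(pool), n_ctrl,
            )
        control_genes.extend(rng.choice(pool, size=n_ctrl, replace=replace))

    raw = matrix.loc[sig_genes].mean(axis=0) - matrix.loc[control_genes].mean(axis=0)
    score = (raw - raw.mean()) / raw.std(ddof=1)
    return pd.DataFrame(
        {"cell_id": matrix.columns, "raw_score": raw.to_numpy(), "score": score.to_numpy()}
    )


# ---------------------------------------------------------------------------
# Ranking and correlation


def rank_genes(de_table: pd.DataFrame) -> pd.DataFrame:
    """Pre-ranked list scored by -sign(log2FC) * log10(adjusted p).

    Adjusted p-values of zero are clipped to the smallest positive float
    (warned). Descending score order; ties broken by gene id.
    """
    padj = de_table["adjusted_p"].to_numpy(dtype=float)
    if (padj <= 0).any():
        logger.warning("rank_genes: %d adjusted p <= 0 clipped", int((padj <= 0).sum()))
        padj = np.clip(padj, np.finfo(float).tiny, None)
    score = -np.sign(de_table["log2_fold_change"].to_numpy()) * np.log10(padj)
    ranked = pd.DataFrame({"gene": de_table["gene"], "score": score})
    return ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def correlate_with_gene(
    matrix: pd.DataFrame, anchor_gene: str, k: int = 25
) -> tuple[pd.Series, list[str], list[str]]:
    """Pearson r of every gene against an anchor gene across cells/samples.

    The matrix should be log-normalized. Constant genes (undefined r) are
    excluded; the anchor itself is excluded from the top-k. Returns
    (per-gene r, top-k genes, bottom-k genes).
    """
    if anchor_gene not in matrix.index:
        raise ValueError(f"anchor gene {anchor_gene!r} not in matrix")
    x = matrix.loc[anchor_gene].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError("anchor gene is constant; correlation undefined")
    values = matrix.to_numpy(dtype=float)
    xc = x - x.mean()
    vc = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / denom
    r = pd.Series(r, index=matrix.index).drop(anchor_gene).dropna()
    ordered = r.sort_values(ascending=False)
    return r, list(ordered.index[:k]), list(ordered.index[-k:][::-1])
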