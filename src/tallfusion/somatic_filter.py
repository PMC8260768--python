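"""Tumor-vs-remission somatic variant decision rule.

A candidate variant is kept as somatic when all of the following hold:

* tumor VAF >= 5% (detectable even in minor subclones),
* the tumor/remission VAF difference is at least 20% (relative to the tumor
  VAF by default; an absolute-percentage-point mode is available because the
  wording of the rule admits both readings),
* the tumor/remission allele-count contrast is significant by a two-sided
  Fisher exact test (alpha 0.05 by default),
* remission VAF < 5%.

Thresholds are compared inclusively/exclusively exactly as stated ("at least
5%" inclusive, "<5%" exclusive). Records with zero read depth in either
sample have an undefined VAF and are rejected with rule ``no_coverage``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RULE_NO_COVERAGE = "no_coverage"
RULE_MIN_TUMOR_VAF = "min_tumor_vaf"
RULE_MIN_DIFF = "min_relative_diff"
RULE_FISHER = "fisher_significance"
RULE_MAX_REMISSION_VAF = "max_remission_vaf"


@dataclass(frozen=True)
class VariantRecord:
    """One candidate variant with paired tumor/remission read counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_ref: int
    tumor_alt: int
    remission_ref: int
    remission_alt: int

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def remission_depth(self) -> int:
        return self.remission_ref + self.remission_alt

    @property
    def vaf_tumor(self) -> float:
        """alt/(ref+alt); NaN when depth is zero (record auto-rejected)."""
        d = self.tumor_depth
        return self.tumor_alt / d if d > 0 else math.nan

    @property
    def vaf_remission(self) -> float:
        d = self.remission_depth
        return self.remission_alt / d if d > 0 else math.nan


@dataclass(frozen=True)
class FilterParams:
    min_tumor_vaf: float = 0.05
    min_relative_diff: float = 0.20
    max_remission_vaf: float = 0.05
    alpha: float = 0.05
    diff_mode: Literal["relative", "absolute"] = "relative"

    def __post_init__(self) -> None:
        for name in ("min_tumor_vaf", "min_relative_diff", "max_remission_vaf", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.diff_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown diff_mode {self.diff_mode!r}")


@dataclass(frozen=True)
class FilterDecision:
    record: VariantRecord
    kept: bool
    failed_rules: tuple[str, ...]
    fisher_p: float

    def __post_init__(self) -> None:
        assert self.kept == (len(self.failed_rules) == 0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than the observed table's (with
    the conventional (1 + 1e-7) relative tie tolerance). A table with an
    all-zero margin carries no information and returns p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        logger.debug("fisher_exact: degenerate margin, p = 1 by convention")
        return 1.0
    support_lo = max(0, row1 + col1 - n)
    support_hi = min(row1, col1)
    k = np.arange(support_lo, support_hi + 1)
    pmf = stats.hypergeom.pmf(k, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def _decide(record: VariantRecord, params: FilterParams) -> FilterDecision:
    failed: list[str] = []
    if record.tumor_depth == 0 or record.remission_depth == 0:
        return FilterDecision(record, kept=False, failed_rules=(RULE_NO_COVERAGE,), fisher_p=1.0)

    vt, vr = record.vaf_tumor, record.vaf_remission
    if not vt >= params.min_tumor_vaf:
        failed.append(RULE_MIN_TUMOR_VAF)
    if params.diff_mode == "relative":
        diff_ok = vt > 0 and (vt - vr) / vt >= params.min_relative_diff
    else:
        diff_ok = (vt - vr) >= params.min_relative_diff
    if not diff_ok:
        failed.append(RULE_MIN_DIFF)
    p = fisher_exact_two_sided(
        record.tumor_alt, record.tumor_ref, record.remission_alt, record.remission_ref
    )
    if not p < params.alpha:
        failed.append(RULE_FISHER)
    if not vr < params.max_remission_vaf:
        failed.append(RULE_MAX_REMISSION_VAF)
    return FilterDecision(record, kept=not failed, failed_rules=tuple(failed), fisher_p=p)


def filter_somatic(
    records: Iterable[VariantRecord], params: FilterParams | None = None
) -> list[FilterDecision]:
    """Apply the composite somatic decision rule to every record."""
    params = params or FilterParams()
    decisions = [_decide(r, params) for r in records]
    n_kept = sum(d.kept for d in decisions)
    logger.info(
        "filter_somatic: n_in=%d kept=%d dropped=%d params=%s",
        len(decisions), n_kept, len(decisions) - n_kept, params,
    )
    return decisions


def records_from_table(table: pd.DataFrame) -> list[VariantRecord]:
    """Build VariantRecords from a TSV-style table of count columns."""
    cols = [
        "chrom", "pos", "ref", "alt",
        "tumor_ref", "tumor_alt", "remission_ref", "remission_alt",
    ]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    return [
        VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            tumor_ref=int(row.tumor_ref), tumor_alt=int(row.tumor_alt),
            remission_ref=int(row.remission_ref), remission_alt=int(row.remission_alt),
        )
        for row in table.itertuples(index=False)
    ]


def decisions_to_table(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Flatten decisions into a table with derived VAFs and decision columns."""
    rows = []
    for d in decisions:
        r = d.record
        rows.append(
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "tumor_ref": r.tumor_ref, "tumor_alt": r.tumor_alt,
                "remission_ref": r.remission_ref, "remission_alt": r.remission_alt,
                "vaf_tumor": r.vaf_tumor, "vaf_remission": r.vaf_remission,
                "fisher_p": d.fisher_p, "kept": d.kept,
                "failed_rules": ";".join(d.failed_rules),
            }
        )
    return pd.DataFrame(rows)
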