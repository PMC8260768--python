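"""Cell-barcode demultiplexing of long reads and fusion-read classification.

Demultiplexing uses direct substitution-only sequence matching: the first
and last 200 nt of every read longer than 250 nt are scanned against each
whitelist barcode (16 nt) in forward and reverse-complement orientation, and
the best hit with at most one mismatch wins. Reads where two distinct
barcodes tie at the best distance are called ambiguous rather than assigned.

Read classification is marker-based: a read is a *fusion read* when it
contains the 5'-gene exon-4 marker, the breakpoint-junction marker and the
3'-gene exon-3 marker; a *canonical read* when it contains the 5' gene's
exon-4 and exon-7 markers. Marker search tolerates substitutions up to 10%
of the marker length.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import reverse_complement, seq_to_bytes, sliding_mismatches
from .core_io import LongRead, write_fastq

logger = logging.getLogger(__name__)

NO_MATCH = -1  # position sentinel when the window is shorter than the barcode

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNASSIGNED = "unassigned"
STATUS_TOO_SHORT = "too_short"

CLASS_FUSION = "fusion"
CLASS_CANONICAL = "canonical"
CLASS_OTHER = "other"


@dataclass(frozen=True)
class DemuxParams:
    barcode_length: int = 16
    window: int = 200  # scanned at each read end
    min_read_length: int = 250  # strict: only reads longer than this are scanned
    max_mismatches: int = 1  # "< 2 mismatches"
    marker_mismatch_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window < self.barcode_length:
            raise ValueError("window must be >= barcode length")
        if self.max_mismatches >= self.barcode_length:
            raise ValueError("max_mismatches must be < barcode length")


@dataclass(frozen=True)
class BarcodeAssignment:
    read_id: str
    status: str
    barcode: str | None = None
    orientation: str | None = None  # forward | reverse_complement
    position: int | None = None  # 0-based offset in the read
    mismatches: int | None = None
    read_class: str = CLASS_OTHER
    conflict: bool = False

    def __post_init__(self) -> None:
        assert (self.barcode is not None) == (self.status == STATUS_ASSIGNED)


def hamming_scan(window_seq: str, barcode: str) -> tuple[int, int]:
    """Best (leftmost) offset and Hamming distance of barcode in window_seq.

    Substitutions only; non-ACGT characters mismatch every base. When the
    window is shorter than the barcode returns the no-match sentinel
    ``(-1, len(barcode) + 1)``.
    """
    if len(window_seq) < len(barcode):
        return NO_MATCH, len(barcode) + 1
    mm = sliding_mismatches(seq_to_bytes(window_seq), seq_to_bytes(barcode))
    best = int(mm.argmin())  # argmin is leftmost on ties
    return best, int(mm[best])


class _WhitelistMatcher:
    """Vectorized scan of both orientations of every whitelist barcode."""

    def __init__(self, whitelist: Sequence[str], params: DemuxParams):
        if not whitelist:
            raise ValueError("empty whitelist")
        bad = [bc for bc in whitelist if len(bc) != params.barcode_length]
        if bad:
            raise ValueError(
                f"whitelist barcodes must be {params.barcode_length} nt, got {bad[:3]}"
            )
        self.params = params
        self.whitelist = list(whitelist)
        probes = [seq_to_bytes(bc) for bc in whitelist]
        probes += [seq_to_bytes(reverse_complement(bc)) for bc in whitelist]
        self.probes = np.stack(probes)  # (2*n_bc, L)
        self.orientations = ["forward"] * len(whitelist) + ["reverse_complement"] * len(whitelist)

    def scan(self, window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-probe (best_mismatches, best_position) over all offsets."""
        L = self.probes.shape[1]
        if len(window) < L:
            n = self.probes.shape[0]
            return np.full(n, L + 1), np.full(n, NO_MATCH)
        view = np.lib.stride_tricks.sliding_window_view(window, L)  # (n_off, L)
        mm = (view[None, :, :] != self.probes[:, None, :]).sum(axis=2)  # (n_probe, n_off)
        pos = mm.argmin(axis=1)
        return mm[np.arange(mm.shape[0]), pos], pos


def assign_barcode(
    read: LongRead,
    whitelist: Sequence[str],
    params: DemuxParams | None = None,
    _matcher: _WhitelistMatcher | None = None,
) -> BarcodeAssignment:
    """Demultiplex a single read against a barcode whitelist.

    Reads of length <= ``min_read_length`` are ``too_short``. Both 200-nt end
    windows (clipped to the read) are scanned against every barcode in both
    orientations; the hit with fewest mismatches wins if it has at most
    ``max_mismatches``. A tie between two distinct barcodes at the best
    distance yields ``ambiguous``; no qualifying hit yields ``unassigned``.
    """
    params = params or DemuxParams()
    matcher = _matcher or _WhitelistMatcher(whitelist, params)
    if len(read) <= params.min_read_length:
        return BarcodeAssignment(read.read_id, STATUS_TOO_SHORT)

    seq = seq_to_bytes(read.sequence)
    w = params.window
    windows = [(0, seq[:w]), (max(0, len(seq) - w), seq[max(0, len(seq) - w):])]

    best_mm = params.barcode_length + 1
    hits: list[tuple[int, int, int]] = []  # (probe_idx, absolute_pos, mm)
    for offset, window in windows:
        mm, pos = matcher.scan(window)
        for probe_idx in np.flatnonzero(mm <= params.max_mismatches):
            hits.append((int(probe_idx), offset + int(pos[probe_idx]), int(mm[probe_idx])))
    if not hits:
        return BarcodeAssignment(read.read_id, STATUS_UNASSIGNED)
    best_mm = min(h[2] for h in hits)
    best = [h for h in hits if h[2] == best_mm]
    n_bc = len(matcher.whitelist)
    barcodes = {matcher.whitelist[idx % n_bc] for idx, _, _ in best}
    if len(barcodes) > 1:
        return BarcodeAssignment(read.read_id, STATUS_AMBIGUOUS)
    idx, pos, mm = best[0]
    return BarcodeAssignment(
        read.read_id,
        STATUS_ASSIGNED,
        barcode=matcher.whitelist[idx % n_bc],
        orientation=matcher.orientations[idx],
        position=pos,
        mismatches=mm,
    )


def _contains_marker(seq: np.ndarray, marker: str, tol_fraction: float) -> bool:
    probe = seq_to_bytes(marker)
    mm = sliding_mismatches(seq, probe)
    if not len(mm):
        return False
    return bool(mm.min() <= int(tol_fraction * len(probe)))


def classify_read(
    read: LongRead,
    tcf7_e4_marker: str,
    spi1_e3_marker: str,
    tcf7_e7_marker: str,
    junction_marker: str,
    params: DemuxParams | None = None,
) -> tuple[str, bool]:
    """Classify a read as fusion / canonical / other by marker content.

    Fusion: contains the 5'-gene exon-4 marker AND the junction marker AND
    the 3'-gene exon-3 marker. Canonical: contains the 5'-gene exon-4 AND
    exon-7 markers. A read matching both rule sets is ``other`` with a
    conflict flag. Each marker search tolerates substitutions up to 10% of
    the marker length (both read orientations are searched).
    """
    params = params or DemuxParams()
    for name, marker in (
        ("tcf7_e4", tcf7_e4_marker), ("spi1_e3", spi1_e3_marker),
        ("tcf7_e7", tcf7_e7_marker), ("junction", junction_marker),
    ):
        if not marker:
            raise ValueError(f"missing marker sequence: {name}")
    tol = params.marker_mismatch_fraction

    for oriented in (read.sequence, reverse_complement(read.sequence)):
        seq = seq_to_bytes(oriented)
        has_e4 = _contains_marker(seq, tcf7_e4_marker, tol)
        if not has_e4:
            continue
        is_fusion = _contains_marker(seq, junction_marker, tol) and _contains_marker(
            seq, spi1_e3_marker, tol
        )
        is_canonical = _contains_marker(seq, tcf7_e7_marker, tol)
        if is_fusion and is_canonical:
            return CLASS_OTHER, True
        if is_fusion:
            return CLASS_FUSION, False
        if is_canonical:
            return CLASS_CANONICAL, False
    return CLASS_OTHER, False


def demux_run(
    reads: Iterable[LongRead],
    whitelist: Sequence[str],
    markers: dict[str, str],
    params: DemuxParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[BarcodeAssignment], pd.DataFrame, dict]:
    """Demultiplex and classify a read set; optionally write per-cell FASTQ.

    Returns (assignments, per-cell summary table, run report). The summary
    has one row per cell with n_assigned / n_fusion / n_canonical / n_other.
    Counts are conserved: assigned + ambiguous + unassigned + too_short
    equals the number of input reads.
    """
    params = params or DemuxParams()
    matcher = _WhitelistMatcher(whitelist, params)
    reads = list(reads)

    assignments: list[BarcodeAssignment] = []
    per_cell_reads: dict[str, list[LongRead]] = defaultdict(list)
    for read in reads:
        asg = assign_barcode(read, whitelist, params, _matcher=matcher)
        if asg.status == STATUS_ASSIGNED:
            klass, conflict = classify_read(
                read,
                tcf7_e4_marker=markers["TCF7_e4"],
                spi1_e3_marker=markers["SPI1_e3"],
                tcf7_e7_marker=markers["TCF7_e7"],
                junction_marker=markers["junction"],
                params=params,
            )
            asg = BarcodeAssignment(
                asg.read_id, asg.status, asg.barcode, asg.orientation,
                asg.position, asg.mismatches, read_class=klass, conflict=conflict,
            )
            per_cell_reads[asg.barcode].append(read)
        assignments.append(asg)

    status_counts = Counter(a.status for a in assignments)
    rows = []
    for barcode in whitelist:
        cell = [a for a in assignments if a.status == STATUS_ASSIGNED and a.barcode == barcode]
        rows.append(
            {
                "barcode": barcode,
                "n_assigned": len(cell),
                "n_fusion": sum(a.read_class == CLASS_FUSION for a in cell),
                "n_canonical": sum(a.read_class == CLASS_CANONICAL for a in cell),
                "n_other": sum(a.read_class == CLASS_OTHER for a in cell),
            }
        )
    summary = pd.DataFrame(rows)

    report = {
        "n_reads": len(reads),
        "n_assigned": status_counts.get(STATUS_ASSIGNED, 0),
        "n_ambiguous": status_counts.get(STATUS_AMBIGUOUS, 0),
        "n_unassigned": status_counts.get(STATUS_UNASSIGNED, 0),
        "n_too_short": status_counts.get(STATUS_TOO_SHORT, 0),
        "n_fusion": int(summary["n_fusion"].sum()),
        "n_canonical": int(summary["n_canonical"].sum()),
    }
    logger.info("demux_run: %s", report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for barcode, cell_reads in per_cell_reads.items():
            write_fastq(cell_reads, out_dir / f"cell_{barcode}.fastq")
        summary.to_csv(out_dir / "demux_summary.tsv", sep="\t", index=False)
    return assignments, summary, report
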