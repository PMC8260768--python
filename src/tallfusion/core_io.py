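"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based half-open internally; conversion to the
1-based inclusive convention used in reports happens only at I/O boundaries.
Count matrices are TSV with genes as rows and a leading ``gene_id`` column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_CHAR = "I"  # phred 40; used when a read carries no quality


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message names the record index."""


class GmtParseError(ValueError):
    """Raised for malformed GMT lines; message names the line number."""


@dataclass
class LongRead:
    """A single (long) sequencing read.

    quality, when present, is a phred string of the same length as the
    sequence; reads written without quality get a constant 'I' line.
    """

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r}: duplicate genes")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CountsMatrix:
    """Gene-by-sample matrix with optional per-gene lengths (bp).

    values is a pandas DataFrame indexed by gene id with sample ids as
    columns; entries are non-negative counts or normalized values.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in counts matrix")
        if self.gene_lengths is not None:
            missing = self.values.index.difference(self.gene_lengths.index)
            if len(missing):
                raise ValueError(f"gene lengths missing for {list(missing[:5])}")
            if (self.gene_lengths.loc[self.values.index] <= 0).any():
                raise ValueError("gene lengths must be positive")
            self.gene_lengths = self.gene_lengths.loc[self.values.index]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> list[LongRead]:
    """Parse a 4-line FASTQ file into LongReads, preserving file order.

    Raises FastqParseError naming the 0-based index of the offending record
    for truncated files or sequence/quality length mismatches.
    """
    reads: list[LongRead] = []
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record {index}: {exc}") from exc
            if not seq:
                raise FastqParseError(f"malformed FASTQ record {index}: empty sequence")
            reads.append(LongRead(read_id=title.split()[0], sequence=seq, quality=qual))
            index += 1
    return reads


def write_fastq(reads: Iterable[LongRead], path: str | Path) -> Path:
    """Write reads as 4-line FASTQ; reads without quality get 'I' per base."""
    path = Path(path)
    with open(path, "w") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else DEFAULT_QUALITY_CHAR * len(read)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
    return path


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name TAB description TAB gene...), one set per line.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a line with fewer than three fields is a parse error.
    """
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"line {lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} field(s)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("GMT %s line %d: duplicate gene %s dropped", name, lineno, g)
                else:
                    seen[g] = None
            if not seen:
                raise GmtParseError(f"line {lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, genes=tuple(seen)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Tabular formats


def read_counts_tsv(path: str | Path, lengths_path: str | Path | None = None) -> CountsMatrix:
    """Read a gene-by-sample TSV (first column ``gene_id``).

    An optional side table (columns ``gene_id``, ``length``) supplies gene
    lengths in base pairs. Duplicate gene or sample identifiers are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", dtype={"gene_id": str})
        if lt["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in lengths table")
        lengths = lt.set_index("gene_id")["length"]
    return CountsMatrix(values=df, gene_lengths=lengths)


def write_counts_tsv(matrix: CountsMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")
    return path


def read_barcode_whitelist(path: str | Path) -> list[str]:
    """Read one cell barcode per line; blank lines ignored."""
    barcodes: list[str] = []
    with open(path) as handle:
        for raw in handle:
            bc = raw.strip()
            if bc:
                barcodes.append(bc.upper())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in whitelist")
    return barcodes


def read_dose_response_tsv(path: str | Path) -> pd.DataFrame:
    """Read a limiting-dilution table with columns dose, tested, responding."""
    df = pd.read_csv(path, sep="\t")
    required = {"dose", "tested", "responding"}
    if not required.issubset(df.columns):
        raise ValueError(f"dose-response table needs columns {sorted(required)}")
    return df


def write_json_summary(summary: dict, path: str | Path) -> Path:
    """Write a machine-readable JSON summary of a pipeline stage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")
    return path


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def log_stage(stage: str, n_in: int, n_kept: int, **params) -> None:
    """Structured per-stage audit log: input size, parameters, kept/dropped."""
    logger.info(
        "%s: n_in=%d kept=%d dropped=%d params=%s",
        stage,
        n_in,
        n_kept,
        n_in - n_kept,
        params,
    )
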