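"""Fusion transcript and fusion protein modelling.

Given two gene models and intronic genomic breakpoints, build the fusion
transcript exon list (5' gene exons up to the breakpoint intron, then 3'
gene exons after it) and the fusion protein coordinate map: an N-terminal
segment of protein A joined to an internal/terminal segment of protein B,
with domain retention decided by full containment in the retained segment.

The motivating case is the t(5;11) TCF7-SPI1 chimera: exons 1-4 of TCF7
(TCF1 residues 1-182, including the N-terminal beta-catenin binding region)
joined to exons 3-5 of SPI1 (PU.1 residues 52-271, retaining the ETS DNA
binding domain), a 402-residue protein.

Protein coordinates are 1-based inclusive; genomic intervals are 0-based
half-open internally. The fusion's reading frame is assumed preserved; frame
consistency is a validation warning, not a hard error, since only exon-level
structure is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._seq import seq_to_bytes, sliding_mismatches

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinDomain:
    """Named protein domain with 1-based inclusive residue coordinates."""

    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError(f"domain {self.name}: bad interval {self.start_aa}..{self.end_aa}")


@dataclass
class GeneModel:
    """Minimal gene model: ordered exons, protein length, named domains.

    Exons are genomic (start, end) intervals, 0-based half-open, listed in
    transcription (5'->3') order; for '-' strand genes the genomic
    coordinates therefore decrease along the list.
    """

    name: str
    strand: str
    exons: list[tuple[int, int]]
    protein_length: int
    domains: list[ProteinDomain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.name}: empty exon interval {start}..{end}")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
            if e0 > s1:
                raise ValueError(f"{self.name}: exons overlap or are out of order")
        for dom in self.domains:
            if dom.end_aa > self.protein_length:
                raise ValueError(
                    f"{self.name}: domain {dom.name} exceeds protein length "
                    f"{self.protein_length}"
                )

    def n_exons(self) -> int:
        return len(self.exons)

    def intron_index_of(self, position: int) -> int:
        """Index i of the intron between exons i and i+1 containing position.

        Returns ``n_exons - 1`` for a position downstream of the last exon
        (the "intron after the last exon" boundary case) and ``-1`` for a
        position upstream of the first exon. A position inside an exon is an
        error: exonic breakpoints are unsupported.
        """
        for i, (start, end) in enumerate(self.exons):
            inside = start <= position < end
            if inside:
                raise ValueError(
                    f"{self.name}: exonic breakpoint unsupported (position {position} "
                    f"inside exon {i + 1})"
                )
        # walk transcription order and find the first exon 3' of the position
        for i, (start, end) in enumerate(self.exons):
            before_exon = position < start if self.strand == "+" else position >= end
            if before_exon:
                return i - 1
        return len(self.exons) - 1


@dataclass(frozen=True)
class FusionExon:
    gene: str
    exon_number: int  # 1-based within its gene
    interval: tuple[int, int]


@dataclass(frozen=True)
class FusionProtein:
    """Coordinate map of a two-segment fusion protein (1-based inclusive)."""

    a_end: int
    b_start: int
    b_end: int
    retained_domains: tuple[ProteinDomain, ...]

    @property
    def total_length(self) -> int:
        return self.a_end + (self.b_end - self.b_start + 1)

    @property
    def segment_a(self) -> tuple[int, int]:
        return (1, self.a_end)

    @property
    def segment_b(self) -> tuple[int, int]:
        return (self.a_end + 1, self.total_length)


def build_fusion_transcript(
    gene_a: GeneModel,
    gene_b: GeneModel,
    break_a: int,
    break_b: int,
) -> list[FusionExon]:
    """Exon list of the fusion transcript for intronic genomic breakpoints.

    Any breakpoint coordinate within the same intron yields the same
    transcript: exons of the 5' gene up to the breakpoint intron, then exons
    of the 3' gene after its breakpoint intron.
    """
    ia = gene_a.intron_index_of(break_a)
    ib = gene_b.intron_index_of(break_b)
    if ia < 0:
        raise ValueError(f"{gene_a.name}: breakpoint upstream of the first exon retains nothing")
    if ib == gene_b.n_exons() - 1:
        raise ValueError(f"{gene_b.name}: breakpoint downstream of the last exon retains nothing")
    exons = [
        FusionExon(gene_a.name, i + 1, gene_a.exons[i]) for i in range(ia + 1)
    ] + [
        FusionExon(gene_b.name, j + 1, gene_b.exons[j])
        for j in range(ib + 1, gene_b.n_exons())
    ]
    return exons


def fusion_protein(
    a_end: int,
    b_start: int,
    b_end: int,
    domains_a: Sequence[ProteinDomain] = (),
    domains_b: Sequence[ProteinDomain] = (),
) -> FusionProtein:
    """Join residues 1..a_end of protein A to residues b_start..b_end of B.

    A domain is retained iff it lies fully inside its retained segment;
    B-domain coordinates are shifted by ``a_end - b_start + 1`` into fusion
    coordinates. Total length = a_end + (b_end - b_start + 1).
    """
    if a_end < 1:
        raise ValueError("a_end must be >= 1")
    if not 1 <= b_start <= b_end:
        raise ValueError(f"invalid B segment {b_start}..{b_end}")
    retained: list[ProteinDomain] = []
    for dom in domains_a:
        if dom.end_aa <= a_end:
            retained.append(dom)
    shift = a_end - b_start + 1
    for dom in domains_b:
        if b_start <= dom.start_aa and dom.end_aa <= b_end:
            retained.append(
                ProteinDomain(dom.name, dom.start_aa + shift, dom.end_aa + shift)
            )
    return FusionProtein(a_end=a_end, b_start=b_start, b_end=b_end,
                         retained_domains=tuple(retained))


def truncate_n_terminus(protein: FusionProtein, n_removed: int) -> FusionProtein:
    """Remove the first ``n_removed`` residues of the fusion (e.g. the
    beta-catenin binding region) and return the shortened protein map."""
    if not 0 < n_removed < protein.total_length:
        raise ValueError("n_removed must be inside the protein")
    if n_removed >= protein.a_end:
        raise ValueError("truncation removes the whole A segment")
    new_a_end = protein.a_end - n_removed
    kept = tuple(
        ProteinDomain(d.name, d.start_aa - n_removed, d.end_aa - n_removed)
        for d in protein.retained_domains
        if d.start_aa > n_removed
    )
    return FusionProtein(a_end=new_a_end, b_start=protein.b_start, b_end=protein.b_end,
                         retained_domains=kept)


def classify_breakpoint_read(
    read_sequence: str,
    junction_window: str,
    m: int = 20,
    max_mismatches_per_side: int = 2,
) -> bool:
    """Does a read support the fusion junction?

    ``junction_window`` is a 2k-nt sequence centred on the junction. A read
    supports the fusion iff it contains, at adjacent positions, at least
    ``m`` nt matching each side of the junction with at most
    ``max_mismatches_per_side`` substitutions per side.
    """
    if len(junction_window) < 2 * m:
        raise ValueError(f"junction window shorter than 2*m = {2 * m}")
    if len(junction_window) % 2 != 0:
        raise ValueError("junction window must have even length (centred on the junction)")
    half = len(junction_window) // 2
    left_flank = seq_to_bytes(junction_window[half - m : half])
    right_flank = seq_to_bytes(junction_window[half : half + m])
    read = seq_to_bytes(read_sequence)
    if len(read) < 2 * m:
        return False
    left_mm = sliding_mismatches(read, left_flank)
    right_mm = sliding_mismatches(read, right_flank)
    # left flank at offset o must be followed by the right flank at o + m
    n_off = len(left_mm) - m
    if n_off <= 0:
        return False
    ok = (left_mm[:n_off] <= max_mismatches_per_side) & (
        right_mm[m : m + n_off] <= max_mismatches_per_side
    )
    return bool(ok.any())


# ---------------------------------------------------------------------------
# I/O: gene models as exon-row TSV plus a protein-domain TSV


def read_gene_models(exon_path: str | Path, domain_path: str | Path | None = None,
                     protein_lengths: dict[str, int] | None = None) -> dict[str, GeneModel]:
    """Read gene models from a minimal exon-row TSV.

    Columns: gene, strand, start, end (1-based inclusive in the file,
    converted to 0-based half-open on read), rows in transcription order.
    The optional domain TSV has columns gene, domain, start_aa, end_aa.
    """
    exons = pd.read_csv(exon_path, sep="\t")
    domains = pd.read_csv(domain_path, sep="\t") if domain_path is not None else None
    models: dict[str, GeneModel] = {}
    for gene, sub in exons.groupby("gene", sort=False):
        strand = sub["strand"].iloc[0]
        ivals = [(int(s) - 1, int(e)) for s, e in zip(sub["start"], sub["end"])]
        doms: list[ProteinDomain] = []
        if domains is not None:
            for row in domains[domains["gene"] == gene].itertuples(index=False):
                doms.append(ProteinDomain(row.domain, int(row.start_aa), int(row.end_aa)))
        plen = (protein_lengths or {}).get(
            gene, max((d.end_aa for d in doms), default=1)
        )
        models[gene] = GeneModel(name=gene, strand=strand, exons=ivals,
                                 protein_length=plen, domains=doms)
    return models


def fusion_report(
    transcript: list[FusionExon], protein: FusionProtein
) -> dict:
    """JSON-ready fusion report: exon list, protein segments, length, domains."""
    return {
        "exons": [
            {
                "gene": e.gene,
                "exon_number": e.exon_number,
                "start_1based": e.interval[0] + 1,
                "end_1based": e.interval[1],
            }
            for e in transcript
        ],
        "protein": {
            "segment_a": list(protein.segment_a),
            "segment_b": list(protein.segment_b),
            "source_b_residues": [protein.b_start, protein.b_end],
            "total_length_aa": protein.total_length,
            "retained_domains": [
                {"name": d.name, "start_aa": d.start_aa, "end_aa": d.end_aa}
                for d in protein.retained_domains
            ],
        },
    }
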