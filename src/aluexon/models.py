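"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open on the forward genome strand;
conversion from 1-based formats (GTF, RepeatMasker .out, editing-site tables)
happens at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class RegionClass(enum.Enum):
    """Location of an exon relative to a transcript's annotated CDS."""

    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"


class PtcClass(enum.Enum):
    """NMD fate of an exon-inclusion transcript under the 50-nt rule."""

    NON_PTC = "NON_PTC"
    PTC = "PTC"


class JunctionRole(enum.Enum):
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    SKIPPING = "SKIPPING"


class PeptideLocation(enum.Enum):
    EXON_BODY = "EXON_BODY"
    UPSTREAM_JUNCTION = "UPSTREAM_JUNCTION"
    DOWNSTREAM_JUNCTION = "DOWNSTREAM_JUNCTION"


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat copy (e.g. an Alu element) on the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str       # subfamily, e.g. AluSx, AluY, AluJb
    family: str     # e.g. SINE/Alu

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"repeat {self.name}: start {self.start} >= end {self.end}")
        if not self.family:
            raise ValueError("repeat family must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus the annotated CDS span.

    ``exons`` are stored in ascending genomic order; for minus-strand
    transcripts the 5'->3' order is the reverse (see :meth:`exons_in_sense`).
    ``cds_start``/``cds_end`` delimit the genomic CDS span (half-open),
    including the stop codon; ``None`` for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons {(s1, e1)} {(s2, e2)}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: CDS boundaries must both be set or both None")
        if self.cds_start is not None:
            span = (self.exons[0][0], self.exons[-1][1])
            if not (span[0] <= self.cds_start < self.cds_end <= span[1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def exons_in_sense(self) -> list[tuple[int, int]]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def internal_exons(self) -> list[tuple[int, int]]:
        """Exons that are neither first nor last (in either orientation)."""
        return self.exons[1:-1]


@dataclass
class AluExonRecord:
    """An internal exon predominantly derived from a single Alu copy.

    Existence of a record implies the two overlap thresholds hold:
    at least 25 bp of the exon covered by the Alu, and the covered
    fraction strictly exceeding one half of the exon length.
    """

    chrom: str
    start: int
    end: int
    transcript_id: str
    gene_id: str
    strand: str
    overlap_bp: int
    overlap_fraction: float
    subfamily: str
    divisible_by_3: bool = False
    region: Optional[RegionClass] = None
    ptc: Optional[PtcClass] = None
    straddles_cds_boundary: bool = False
    stop_lost: bool = False

    MIN_OVERLAP_BP = 25
    MIN_OVERLAP_FRACTION = 0.5

    def __post_init__(self) -> None:
        if self.overlap_bp < self.MIN_OVERLAP_BP:
            raise ValueError(f"Alu overlap {self.overlap_bp} bp < {self.MIN_OVERLAP_BP}")
        if self.overlap_fraction <= self.MIN_OVERLAP_FRACTION:
            raise ValueError(f"Alu overlap fraction {self.overlap_fraction} not > {self.MIN_OVERLAP_FRACTION}")
        self.divisible_by_3 = (self.end - self.start) % 3 == 0

    @property
    def exon(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfResult:
    """Outcome of translating an exon-inclusion mRNA from the annotated start."""

    mrna: str
    orf_nt: str
    protein: str
    start_mrna: int                # mRNA coordinate of the A of the start codon
    stop_mrna: Optional[int]       # coordinate just past the stop codon; None if stop lost
    stop_lost: bool = False

    # amino-acid span of the cassette exon in the protein, half-open; the
    # amino acid encoded by a codon straddling an exon boundary is assigned
    # to the exon span (inclusive rule)
    exon_aa_span: Optional[tuple[int, int]] = None
    # protein coordinates of the upstream/downstream exon junctions
    junction_aa: Optional[tuple[int, int]] = None


@dataclass
class TranslationEvidence:
    """Joint Ribo-seq / RNA-seq inclusion-level evidence for one exon."""

    exon_id: str
    psi_ribo: Optional[float]
    psi_rna: Optional[float]
    covered_in_both: bool
    nonzero_ribo: bool = False
    strong_ribo: bool = False
    higher_in_ribo: bool = False

    STRONG_THRESHOLD = 0.15

    def __post_init__(self) -> None:
        if not self.covered_in_both:
            self.nonzero_ribo = self.strong_ribo = self.higher_in_ribo = False
            return
        self.nonzero_ribo = self.psi_ribo is not None and self.psi_ribo > 0
        self.strong_ribo = self.psi_ribo is not None and self.psi_ribo >= self.STRONG_THRESHOLD
        self.higher_in_ribo = (
            self.psi_ribo is not None and self.psi_rna is not None and self.psi_ribo > self.psi_rna
        )


@dataclass(frozen=True)
class PeptideHit:
    """A peptide uniquely mapped into an exon-inclusion ORF."""

    peptide: str
    exon_id: str
    location: PeptideLocation
    protein_id: str
    match_start: int  # protein coordinates, half-open
    match_end: int
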