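"""Identification and classification of Alu-derived internal exons.

An exon is called Alu-derived when a single repeat copy covers at least
25 bp of it and more than half of its length. Candidate exons are then
placed relative to the host transcript's CDS, spliced into the mature
mRNA, translated from the annotated start codon, and classified for
nonsense-mediated-decay (NMD) fate under the 50-nt rule: a stop codon
more than 50 nt upstream of the last exon-exon junction is a premature
termination codon (PTC).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import GenomeSequence
from .models import (
    AluExonRecord,
    OrfResult,
    PtcClass,
    RegionClass,
    RepeatAnnotation,
    TranscriptModel,
)

PTC_DISTANCE_NT = 50
STOP_CODONS = {"TAA", "TAG", "TGA"}


class NonCodingTranscriptError(ValueError):
    """Raised when a CDS-dependent operation meets a transcript without CDS."""


def _check_chromosome_consistency(
    transcripts: Sequence[TranscriptModel], repeats: Sequence[RepeatAnnotation]
) -> None:
    t_chroms = {t.chrom for t in transcripts}
    r_chroms = {r.chrom for r in repeats}
    if t_chroms and r_chroms and not (t_chroms & r_chroms):
        raise ValueError(
            "inconsistent chromosome names between gene models and repeats: "
            f"transcripts use {sorted(t_chroms)[:5]}..., repeats use {sorted(r_chroms)[:5]}..."
        )


def find_alu_exons(
    transcripts: Sequence[TranscriptModel],
    repeats: Sequence[RepeatAnnotation],
) -> list[AluExonRecord]:
    """Scan internal exons for predominant overlap with a single Alu copy.

    Returns one record per (exon, transcript) pair whose best-overlapping
    repeat covers >=25 bp of the exon and >50% of its length. When several
    repeats overlap an exon, only the one with the largest intersection is
    considered. First and last exons are never candidates.
    """
    transcripts = list(transcripts)
    repeats = list(repeats)
    _check_chromosome_consistency(transcripts, repeats)

    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep)

    records: list[AluExonRecord] = []
    for tx in transcripts:
        tree = trees.get(tx.chrom)
        if tree is None:
            continue
        for (s, e) in tx.internal_exons():
            best: Optional[RepeatAnnotation] = None
            best_bp = 0
            for iv in sorted(tree.overlap(s, e)):
                bp = min(e, iv.end) - max(s, iv.begin)
                if bp > best_bp:
                    best, best_bp = iv.data, bp
            if best is None:
                continue
            frac = best_bp / (e - s)
            if best_bp >= AluExonRecord.MIN_OVERLAP_BP and frac > AluExonRecord.MIN_OVERLAP_FRACTION:
                records.append(
                    AluExonRecord(
                        chrom=tx.chrom,
                        start=s,
                        end=e,
                        transcript_id=tx.transcript_id,
                        gene_id=tx.gene_id,
                        strand=tx.strand,
                        overlap_bp=best_bp,
                        overlap_fraction=frac,
                        subfamily=best.name,
                    )
                )
    return records


def classify_exon_region(exon: tuple[int, int], transcript: TranscriptModel) -> RegionClass:
    """Place an exon relative to the transcript's CDS.

    Any overlap with the CDS span (>=1 bp) classifies the exon as CDS;
    exons entirely outside fall in the 5' or 3' UTR according to strand.
    """
    if not transcript.has_cds:
        raise NonCodingTranscriptError(
            f"{transcript.transcript_id}: no CDS annotation; exon excluded from coding analysis"
        )
    s, e = exon
    if e > transcript.cds_start and s < transcript.cds_end:
        return RegionClass.CDS
    upstream = e <= transcript.cds_start
    if transcript.strand == "+":
        return RegionClass.FIVE_UTR if upstream else RegionClass.THREE_UTR
    return RegionClass.THREE_UTR if upstream else RegionClass.FIVE_UTR


def exon_straddles_cds_boundary(exon: tuple[int, int], transcript: TranscriptModel) -> bool:
    s, e = exon
    if not transcript.has_cds:
        return False
    overlaps = e > transcript.cds_start and s < transcript.cds_end
    inside = s >= transcript.cds_start and e <= transcript.cds_end
    return overlaps and not inside


def splice_in_exon(transcript: TranscriptModel, exon: tuple[int, int]) -> TranscriptModel:
    """Transcript model with ``exon`` included (no-op if already annotated)."""
    if exon in transcript.exons:
        return transcript
    s, e = exon
    for (a1, b1), (a2, b2) in zip(transcript.exons, transcript.exons[1:]):
        if b1 <= s and e <= a2:
            return TranscriptModel(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                chrom=transcript.chrom,
                strand=transcript.strand,
                exons=sorted(transcript.exons + [exon]),
                cds_start=transcript.cds_start,
                cds_end=transcript.cds_end,
                biotype=transcript.biotype,
            )
    raise ValueError(f"exon {exon} does not fit in an intron of {transcript.transcript_id}")


def _genomic_to_mrna(transcript: TranscriptModel, pos: int) -> int:
    """Map a genomic base position to its mature-mRNA coordinate (sense)."""
    offset = 0
    for (s, e) in transcript.exons_in_sense():
        if s <= pos < e:
            return offset + (pos - s if transcript.strand == "+" else e - 1 - pos)
        offset += e - s
    raise ValueError(f"position {pos} not exonic in {transcript.transcript_id}")


def mrna_sequence(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    return "".join(
        genome.fetch(transcript.chrom, s, e, transcript.strand)
        for (s, e) in transcript.exons_in_sense()
    )


def build_inclusion_orf(
    transcript: TranscriptModel,
    alu_exon: tuple[int, int],
    genome: GenomeSequence,
) -> OrfResult:
    """Splice the exon into the mature mRNA and translate from the
    annotated start codon to the first in-frame stop.

    An exon whose length is not a multiple of 3 shifts the reading frame
    of everything downstream. If no stop codon is reached before the mRNA
    end the result is flagged ``stop_lost``. The returned record also
    carries the exon's amino-acid span and the two junction positions in
    protein coordinates (amino acids from codons straddling an exon
    boundary are assigned to the exon span).
    """
    if not transcript.has_cds:
        raise NonCodingTranscriptError(f"{transcript.transcript_id}: no annotated start codon")
    tx = splice_in_exon(transcript, alu_exon)
    mrna = mrna_sequence(tx, genome)

    start_genomic = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    start = _genomic_to_mrna(tx, start_genomic)

    coding = mrna[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein_full = str(Seq(coding).translate())
    stop_idx = protein_full.find("*")
    if stop_idx == -1:
        stop_lost, protein = True, protein_full
        stop_mrna: Optional[int] = None
        orf_nt = coding
    else:
        stop_lost, protein = False, protein_full[:stop_idx]
        orf_nt = coding[: 3 * (stop_idx + 1)]
        stop_mrna = start + 3 * (stop_idx + 1)

    # exon span in mRNA coordinates
    es, ee = alu_exon
    first = _genomic_to_mrna(tx, es if tx.strand == "+" else ee - 1)
    x0, x1 = first, first + (ee - es)

    exon_aa_span = junction_aa = None
    n0, n1 = x0 - start, x1 - start
    if n1 > 0 and n0 < len(orf_nt):
        a = max(0, n0) // 3
        b = -(-min(n1, len(orf_nt)) // 3)  # ceil division
        exon_aa_span = (a, b)
        junction_aa = (a, b)

    return OrfResult(
        mrna=mrna,
        orf_nt=orf_nt,
        protein=protein,
        start_mrna=start,
        stop_mrna=stop_mrna,
        stop_lost=stop_lost,
        exon_aa_span=exon_aa_span,
        junction_aa=junction_aa,
    )


def translate_annotated(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Protein translated from the annotated start codon of the transcript
    as annotated (no exon spliced in), up to the first in-frame stop."""
    if not transcript.has_cds:
        raise NonCodingTranscriptError(f"{transcript.transcript_id}: no annotated start codon")
    mrna = mrna_sequence(transcript, genome)
    start_genomic = transcript.cds_start if transcript.strand == "+" else transcript.cds_end - 1
    start = _genomic_to_mrna(transcript, start_genomic)
    coding = mrna[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    stop = protein.find("*")
    return protein if stop == -1 else protein[:stop]


def last_junction_mrna_position(transcript: TranscriptModel) -> int:
    """Mature-mRNA coordinate of the last exon-exon junction (sense)."""
    exons = transcript.exons_in_sense()
    if len(exons) < 2:
        raise ValueError(f"{transcript.transcript_id}: single-exon transcript has no junction")
    total = sum(e - s for (s, e) in exons)
    last_len = exons[-1][1] - exons[-1][0]
    return total - last_len


def classify_ptc(orf: OrfResult, transcript_with_exon: TranscriptModel) -> PtcClass:
    """Apply the 50-nt NMD rule to a translated inclusion isoform.

    The stop position is taken just past the stop codon's last base; the
    transcript is PTC when the last junction lies more than 50 nt further
    downstream. Stop-lost inputs are classified NON_PTC with a warning.
    """
    if orf.stop_lost or orf.stop_mrna is None:
        warnings.warn("stop-lost transcript classified NON_PTC", stacklevel=2)
        return PtcClass.NON_PTC
    last_junction = last_junction_mrna_position(transcript_with_exon)
    return PtcClass.PTC if last_junction - orf.stop_mrna > PTC_DISTANCE_NT else PtcClass.NON_PTC


def annotate_alu_exons(
    transcripts: Sequence[TranscriptModel],
    repeats: Sequence[RepeatAnnotation],
    genome: Optional[GenomeSequence] = None,
) -> list[AluExonRecord]:
    """Full annotation stage: find Alu exons, then classify region and,
    when a genome is supplied, NMD fate of the inclusion isoform.

    Exons of non-coding transcripts keep ``region=None``/``ptc=None``.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    records = find_alu_exons(transcripts, repeats)
    for rec in records:
        tx = by_id[rec.transcript_id]
        if not tx.has_cds:
            continue
        rec.region = classify_exon_region(rec.exon, tx)
        rec.straddles_cds_boundary = exon_straddles_cds_boundary(rec.exon, tx)
        if genome is not None:
            orf = build_inclusion_orf(tx, rec.exon, genome)
            rec.stop_lost = orf.stop_lost
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec.ptc = classify_ptc(orf, splice_in_exon(tx, rec.exon))
    return records


def frame_divisibility_test(
    coding_records: Iterable[AluExonRecord], nmd_records: Iterable[AluExonRecord]
) -> tuple[dict[str, int], dict[str, float], float]:
    """Compare divisibility-by-3 of exon length between candidate
    protein-coding and NMD-inducing exon sets (two-sided Fisher).
    """
    from .stats import fisher_exact_2x2

    coding = list(coding_records)
    nmd = list(nmd_records)
    if not coding or not nmd:
        raise ValueError("both exon sets must be non-empty")
    cd = sum(r.divisible_by_3 for r in coding)
    nd = sum(r.divisible_by_3 for r in nmd)
    counts = {
        "coding_divisible": cd,
        "coding_total": len(coding),
        "nmd_divisible": nd,
        "nmd_total": len(nmd),
    }
    fractions = {"coding": cd / len(coding), "nmd": nd / len(nmd)}
    _, p = fisher_exact_2x2([[cd, len(coding) - cd], [nd, len(nmd) - nd]])
    return counts, fractions, p


def subfamily_fraction(records: Sequence[AluExonRecord], subfamily: str) -> tuple[int, float]:
    """Count and fraction of records from a given Alu subfamily (e.g. AluY)."""
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    n = sum(r.subfamily == subfamily for r in records)
    return n, n / len(records)
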