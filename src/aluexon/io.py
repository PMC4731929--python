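"""Format readers and writers.

Internal coordinates are 0-based half-open everywhere; GTF (1-based
closed) and RepeatMasker .out (1-based inclusive) are converted at this
boundary. Stage hand-offs use headered UTF-8 TSV files with '.' for
missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .models import RepeatAnnotation, TranscriptModel

logger = logging.getLogger(__name__)


# --- GTF ---------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read Ensembl-dialect GTF into transcript models.

    Exon and CDS features are grouped by their transcript_id attribute;
    CDS boundaries are the min/max over CDS features. A feature line
    without transcript_id raises with its line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError:
                raise ValueError(f"{path}:{lineno}: feature lacks transcript_id attribute")
            gene_id = (feat.attributes.get("gene_id") or [tx_id])[0]
            biotype = (feat.attributes.get("gene_biotype")
                       or feat.attributes.get("transcript_biotype")
                       or ["protein_coding"])[0]
            meta.setdefault(tx_id, (gene_id, feat.seqid, feat.strand, biotype))
            interval = (feat.start - 1, feat.end)  # 1-based closed -> half-open
            (exons if feat.featuretype == "exon" else cds).setdefault(tx_id, []).append(interval)

    transcripts = []
    for tx_id, ex in exons.items():
        gene_id, chrom, strand, biotype = meta[tx_id]
        cds_ivs = cds.get(tx_id)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
                exons=sorted(ex),
                cds_start=min(s for s, _ in cds_ivs) if cds_ivs else None,
                cds_end=max(e for _, e in cds_ivs) if cds_ivs else None,
                biotype=biotype,
            )
        )
    return transcripts


def write_gtf(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; gene_biotype "{tx.biotype}";'
            for s, e in tx.exons:
                fh.write(f"{tx.chrom}\taluexon\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n")
                if tx.has_cds:
                    cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                    if cs < ce:
                        fh.write(f"{tx.chrom}\taluexon\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t.\t{attrs}\n")


# --- repeats -----------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Read a RepeatMasker .out file (3 header lines, whitespace-delimited,
    1-based inclusive coordinates, strand 'C' meaning minus)."""
    repeats = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].lstrip("-").isdigit():
                continue  # header or blank
            if len(fields) < 11:
                skipped += 1
                continue
            chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
            strand = "-" if fields[8] in ("C", "-") else "+"
            repeats.append(
                RepeatAnnotation(chrom=chrom, start=begin - 1, end=end,
                                 strand=strand, name=fields[9], family=fields[10])
            )
    if skipped:
        logger.info("read_repeatmasker_out: skipped %d short lines", skipped)
    return repeats


def write_repeatmasker_out(path: str | Path, repeats: Sequence[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            strand = "C" if r.strand == "-" else "+"
            fh.write(
                f" 1000 10.0  0.0  0.0  {r.chrom} {r.start + 1} {r.end} (0) "
                f"{strand} {r.name} {r.family} 1 {r.length} (0) {i}\n"
            )


def read_bed6(path: str | Path, family: str = "SINE/Alu") -> list[RepeatAnnotation]:
    """Read repeats from BED6 (0-based half-open; name = subfamily)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [
        RepeatAnnotation(chrom=row.chrom, start=int(row.start), end=int(row.end),
                         strand=row.strand, name=row.name, family=family)
        for row in df.itertuples(index=False)
    ]


def write_bed6(path: str | Path, repeats: Sequence[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def write_exon_bed6(path: str | Path, records) -> None:
    """BED6 of Alu-exon intervals (one line per exon-transcript pair)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\t0\t{r.strand}\n")


# --- FASTA / peptides --------------------------------------------------------

def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def read_peptides(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_peptides(path: str | Path, peptides: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.writelines(p + "\n" for p in peptides)


# --- TSV stage hand-offs -----------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "exon_id": r.exon_id, "chrom": r.chrom, "start": r.start, "end": r.end,
            "strand": r.strand, "transcript_id": r.transcript_id, "gene_id": r.gene_id,
            "overlap_bp": r.overlap_bp, "overlap_fraction": round(r.overlap_fraction, 4),
            "subfamily": r.subfamily, "divisible_by_3": r.divisible_by_3,
            "region": r.region.value if r.region else ".",
            "ptc": r.ptc.value if r.ptc else ".",
            "straddles_cds_boundary": r.straddles_cds_boundary,
            "stop_lost": r.stop_lost,
        })
    return pd.DataFrame(rows)


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"exon_id", "sample", "UJC", "DJC", "SJC"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_editing_tsv(path: str | Path, manifest_path: str | Path | None = None):
    """Read a per-site editing count TSV (1-based positions) and an optional
    library manifest TSV (library, group, replicate)."""
    from .editing import DEFAULT_MANIFEST, EditingCounts

    df = pd.read_csv(path, sep="\t")
    if "site_pos" in df.columns:
        df = df.rename(columns={"site_chrom": "chrom", "site_pos": "pos"})
    manifest = None
    if manifest_path is not None:
        m = pd.read_csv(manifest_path, sep="\t")
        manifest = {row.library: (row.group, int(row.replicate))
                    for row in m.itertuples(index=False)}
    return EditingCounts(df, manifest or DEFAULT_MANIFEST)
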