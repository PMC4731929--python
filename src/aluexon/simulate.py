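"""Synthetic genomes with planted Alu exonization events and ground truth.

The generator builds toy protein-coding genes (5'UTR exon, several coding
exons, a terminal exon with the stop codon and 3'UTR), inserts copies of a
bundled synthetic Alu-like consensus into introns, and exonizes a subset
of the insertions with fully recorded truth: exon coordinates, subfamily
label, mRNA region, reading frame, NMD fate of the inclusion isoform, and
a true inclusion level (PSI) per tissue. Downstream stages get matching
simulators: binomially sampled junction read counts (RNA-seq and
Ribo-seq), peptide libraries with planted unique / junction-spanning /
multi-mapping / background peptides, and 3x3-replicate editing count
tables with condition-specific effects and null sites.

Every output is fully determined by the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .editing import DEFAULT_MANIFEST, EditingCounts
from .genome import GenomeSequence
from .models import RepeatAnnotation, TranscriptModel
from .peptides import ProteinSpace

# Bundled synthetic ~300-nt Alu-like consensus. This is an invented
# sequence with Alu-like length and GC content, not a real subfamily
# consensus; subfamily labels attached to simulated copies are metadata.
ALU_CONSENSUS = (
    "AACCCGCCTTCCGGGTAGGTAATGCTGTGACGGTACCACGTGGCGTTGGGACACAGGGGC"
    "CTCGAAGACGGGACGCTTCGAGGCACTACCGAGGATGGCGCCGCTCGCTACAATCACAAA"
    "GGAAAACGTACGACACATTCAGAGTAAATGACGGGCAAGGCTGGAGCGTTAGACCTGCAA"
    "AGGACATAAGAGGGGGATTTGGCCCGGCGGGCGTCTGGTGACCCTGGCGCAAGTTTTGTT"
    "CCCGAACGTTCGGTAGGGCCGCGCTCGCTCTGAACCCATCGGATGAGCGTAAAGGAACGA"
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; the seed fixes every output."""

    seed: int = 0
    n_genes: int = 30
    # gene architecture (lengths in nt)
    n_coding_exons: tuple[int, int] = (2, 4)
    coding_exon_len: tuple[int, int] = (90, 180)
    intron_len: tuple[int, int] = (200, 400)
    utr5_len: int = 120
    utr3_len: int = 150
    utr3_intron_offset: int = 30  # stop-to-junction distance when the 3'UTR is split
    # Alu insertion / exonization
    alu_insertion_prob: float = 0.85
    exonization_prob: float = 0.7
    mutation_rate: float = 0.02
    region_weights: dict = field(
        default_factory=lambda: {"FIVE_UTR": 0.2, "CDS": 0.65, "THREE_UTR": 0.15}
    )
    cds_event_weights: dict = field(
        default_factory=lambda: {"coding": 0.35, "ptc_stop": 0.4, "frameshift": 0.25}
    )
    subfamily_weights: dict = field(
        default_factory=lambda: {"AluSx": 0.60, "AluY": 0.15, "AluJb": 0.25}
    )
    n_decoy_pairs: int = 1       # event pairs sharing an identical exon slice
    n_subthreshold: int = 2      # planted exons failing the 25 bp / 50% rule
    # inclusion levels and junction reads
    tissues: tuple[str, ...] = ("cerebellum", "heart", "testes")
    psi_beta: tuple[float, float] = (2.0, 2.0)
    depth_mean: float = 200.0
    rna_read_length: int = 50
    ribo_read_length: int = 30
    translation_factor_coding: float = 1.0
    translation_factor_ptc: float = 0.3
    # peptide planting
    peptide_length: int = 9
    n_background_peptides: int = 5
    n_short_peptides: int = 2
    # editing simulation
    n_null_sites: int = 150
    n_common_sites: int = 30
    n_short_only_sites: int = 10
    n_long_only_sites: int = 10
    editing_baseline_beta: tuple[float, float] = (2.0, 6.0)
    editing_delta: float = 1.5
    editing_coverage_mean: float = 100.0
    editing_coverage_dispersion: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.alu_insertion_prob, self.exonization_prob, self.mutation_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_genes and 2 * self.n_decoy_pairs + self.n_subthreshold > self.n_genes:
            raise ValueError("decoy/subthreshold plans exceed n_genes")


@dataclass
class PlantedExon:
    """Ground truth for one planted exonization event."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    subfamily: str
    region: str                      # FIVE_UTR / CDS / THREE_UTR
    event_type: str                  # coding / ptc_stop / frameshift / subthreshold
    frame: int
    expect_found: bool               # passes the 25 bp / >50% overlap thresholds
    divisible_by_3: bool
    ptc: str                         # NON_PTC / PTC (inclusion isoform)
    stop_lost: bool
    psi: dict[str, float]            # tissue -> true inclusion level
    translation_factor: float
    # sense-strand junction sequences and translation flags for read simulation
    junctions: dict[str, str] = field(repr=False, default_factory=dict)
    junction_boundaries: dict[str, int] = field(repr=False, default_factory=dict)
    ribo_translated: dict[str, bool] = field(default_factory=dict)

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass
class SimulatedGenome:
    """Bundle of the emitted genome, annotations, repeats and truth."""

    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    repeats: list[RepeatAnnotation]
    truth: list[PlantedExon]
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = asdict(t)
            row.pop("junctions")
            row.pop("junction_boundaries")
            row["exon_id"] = t.exon_id
            row["ribo_translated"] = ",".join(k for k, v in t.ribo_translated.items() if v)
            for tissue, p in row.pop("psi").items():
                row[f"psi_{tissue}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        from . import io as aio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aio.write_fasta(outdir / "genome.fa", {c: self.genome.fetch(c, 0, self.genome.length(c))
                                               for c in self.genome.chromosomes()})
        aio.write_gtf(outdir / "annotation.gtf", self.transcripts)
        aio.write_repeatmasker_out(outdir / "repeats.out", self.repeats)
        aio.write_bed6(outdir / "repeats.bed", self.repeats)
        self.truth_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        alt = [c for c in "ACGT" if c != chars[i]]
        chars[i] = alt[rng.integers(3)]
    return "".join(chars)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _repair_stops(seq: str) -> str:
    """Replace in-frame (frame 0) stop codons by a sense codon."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    codons = [("TCA" if c in STOP_CODONS else c) for c in codons]
    return "".join(codons) + seq[len(codons) * 3 :]


def _weighted_choice(rng: np.random.Generator, weights: dict) -> str:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Emit a toy genome with planted exonization events and ground truth.

    One gene per chromosome. A subset of introns carries Alu-consensus
    insertions; a subset of those insertions is exonized with recorded
    splice boundaries, reading frame, NMD fate, and true per-tissue PSI.
    The repeat track covers exactly the inserted copies.
    """
    rng = np.random.default_rng([config.seed, 11])
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatAnnotation] = []
    truth: list[PlantedExon] = []

    # deterministic gene plans; special roles assigned to the first genes
    plans = []
    for g in range(config.n_genes):
        plan = {
            "strand": "+" if rng.random() < 0.5 else "-",
            "insert": rng.random() < config.alu_insertion_prob,
            "subfamily": _weighted_choice(rng, config.subfamily_weights),
        }
        plan["exonize"] = plan["insert"] and rng.random() < config.exonization_prob
        plan["region"] = _weighted_choice(rng, config.region_weights)
        plan["event"] = (
            _weighted_choice(rng, config.cds_event_weights)
            if plan["region"] == "CDS" else "utr"
        )
        plans.append(plan)
    decoy_slice: Optional[str] = None
    for d in range(2 * config.n_decoy_pairs):
        plans[d].update(insert=True, exonize=True, region="CDS", event="coding", decoy=True)
    for s in range(config.n_subthreshold):
        g = 2 * config.n_decoy_pairs + s
        plans[g].update(insert=True, exonize=True, region="CDS", event="subthreshold")

    lo_e, hi_e = config.coding_exon_len
    for g, plan in enumerate(plans):
        gene_id, tx_id = f"GENE{g + 1:03d}", f"TX{g + 1:03d}"
        chrom = f"chr{g + 1}"
        exonized = plan["exonize"]
        region = plan["region"] if exonized else None
        event = plan["event"] if exonized else None
        is_decoy = plan.get("decoy", False)

        n_chunks = max(2, int(rng.integers(config.n_coding_exons[0], config.n_coding_exons[1] + 1)))
        chunk_lens = [int(rng.integers(lo_e, hi_e + 1)) for _ in range(n_chunks)]
        total = sum(chunk_lens)
        chunk_lens[-1] += (3 - (total + 3) % 3) % 3  # CDS = chunks + TAA, multiple of 3

        # codon-align the insertion boundary for CDS events
        insert_after = int(rng.integers(1, n_chunks))
        if region == "CDS":
            offset = sum(chunk_lens[:insert_after])
            shift = offset % 3
            if shift and chunk_lens[insert_after - 1] > shift + 30:
                chunk_lens[insert_after - 1] -= shift
                chunk_lens[insert_after] += shift

        cds_codons = (sum(chunk_lens) - 3) // 3  # ATG + codons fill the chunks
        cds_seq = "ATG" + _random_codons(rng, cds_codons - 1) + "TAA"
        cuts = np.cumsum(chunk_lens)
        chunks = [cds_seq[(0 if i == 0 else cuts[i - 1]) : cuts[i]] for i in range(n_chunks)]

        utr5 = _random_seq(rng, config.utr5_len)
        utr3 = _random_seq(rng, config.utr3_len)
        split_utr3 = exonized and region == "THREE_UTR"

        # exon sequence of the planted event
        alu_copy = None
        exon_seq = None
        alu_pre = alu_post = ""
        extra_exon_tail = ""
        if exonized:
            if event == "subthreshold":
                # 24 bp of the Alu's tail plus 36 bp of intron: fails both thresholds
                alu_copy = _mutate(ALU_CONSENSUS, config.mutation_rate, rng)
                exon_seq = alu_copy[-24:] + _random_seq(rng, 36)
                alu_pre, alu_post = alu_copy[:-24], ""
                extra_exon_tail = exon_seq[24:]
            else:
                if event == "coding":
                    length = int(rng.integers(20, 44)) * 3  # 60..129, multiple of 3
                elif event == "ptc_stop":
                    length = int(rng.integers(20, 44)) * 3
                elif event == "frameshift":
                    length = int(rng.integers(60, 130))
                    if length % 3 == 0:
                        length += 1
                else:  # UTR event
                    length = int(rng.integers(60, 130))
                off = int(rng.integers(0, len(ALU_CONSENSUS) - length + 1))
                if is_decoy:
                    off, length = 40, 93  # shared codon-aligned slice
                    if decoy_slice is None:
                        decoy_slice = _repair_stops(ALU_CONSENSUS[off : off + length])
                    exon_seq = decoy_slice
                else:
                    exon_seq = _mutate(ALU_CONSENSUS[off : off + length], config.mutation_rate, rng)
                    if event in ("coding", "frameshift"):
                        exon_seq = _repair_stops(exon_seq)
                    elif event == "ptc_stop":
                        exon_seq = _repair_stops(exon_seq)
                        mid = (len(exon_seq) // 2) // 3 * 3
                        exon_seq = exon_seq[:mid] + "TAA" + exon_seq[mid + 3 :]
                alu_pre = ALU_CONSENSUS[:off]
                alu_post = ALU_CONSENSUS[off + len(exon_seq) :] if not is_decoy else ALU_CONSENSUS[off + length :]
                alu_copy = alu_pre + exon_seq + alu_post

        # assemble sense-strand pieces: list of (kind, seq, tag)
        pieces: list[tuple[str, str, str]] = [("exon", utr5, "utr5")]

        def add_intron(alu_here: bool, exon_here: bool) -> None:
            ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            left = _random_seq(rng, ilen // 2)
            right = _random_seq(rng, ilen - ilen // 2)
            if not alu_here:
                pieces.append(("intron", left + right, ""))
                return
            if not exon_here:
                pieces.append(("intron", left, ""))
                pieces.append(("repeat", alu_copy_full, ""))
                pieces.append(("intron", right, ""))
                return
            pieces.append(("intron", left, ""))
            if alu_pre:
                pieces.append(("repeat", alu_pre, "pre"))
            pieces.append(("exon", exon_seq, "alu"))
            if alu_post:
                pieces.append(("repeat", alu_post, "post"))
            pieces.append(("intron", right, ""))

        # choose the intron carrying the insertion
        target_intron: Optional[int] = None
        n_introns = n_chunks  # introns: utr5|chunk1, between chunks, (+ utr3 intron)
        if plan["insert"]:
            if not exonized:
                target_intron = int(rng.integers(0, n_introns))
                alu_copy_full = _mutate(ALU_CONSENSUS, config.mutation_rate, rng)
            elif region == "FIVE_UTR":
                target_intron = 0
            elif region == "CDS":
                target_intron = insert_after  # between chunks insert_after-1 and insert_after
            # THREE_UTR events go into the split 3'UTR intron, handled below
        if exonized and event == "subthreshold":
            alu_copy_full = alu_copy

        add_intron(plan["insert"] and target_intron == 0, exonized and region == "FIVE_UTR")
        for j in range(n_chunks):
            is_last = j == n_chunks - 1
            if is_last and not split_utr3:
                pieces.append(("exon", chunks[j] + utr3, "last"))
            elif is_last:
                pieces.append(("exon", chunks[j] + utr3[: config.utr3_intron_offset], "last_cds"))
            else:
                pieces.append(("exon", chunks[j], f"cds{j}"))
            if not is_last:
                here = target_intron == j + 1 and plan["insert"]
                add_intron(here, here and exonized and region == "CDS")
        if split_utr3:
            add_intron(True, True)
            pieces.append(("exon", utr3[config.utr3_intron_offset :], "utr3b"))

        # lay out on the chromosome
        strand = plan["strand"]
        spacer = 500
        sense_offset = 0
        sense_intervals: list[tuple[str, int, int, str]] = []  # kind, s, e, tag
        for kind, seq, tag in pieces:
            sense_intervals.append((kind, sense_offset, sense_offset + len(seq), tag))
            sense_offset += len(seq)
        gene_sense = "".join(seq for _, seq, _ in pieces)
        glen = len(gene_sense)
        chrom_seq = (
            _random_seq(rng, spacer)
            + (gene_sense if strand == "+" else reverse_complement(gene_sense))
            + _random_seq(rng, spacer)
        )
        genome[chrom] = chrom_seq

        def to_genomic(s: int, e: int) -> tuple[int, int]:
            if strand == "+":
                return spacer + s, spacer + e
            return spacer + glen - e, spacer + glen - s

        exon_ivs, repeat_ivs = [], []
        alu_exon_sense: Optional[tuple[int, int]] = None
        for kind, s, e, tag in sense_intervals:
            if kind == "exon":
                exon_ivs.append((s, e, tag))
                if tag == "alu":
                    alu_exon_sense = (s, e)
            elif kind == "repeat":
                repeat_ivs.append((s, e))
        # merge repeat pieces with an embedded exon into one copy
        if exonized and alu_exon_sense is not None and event != "subthreshold":
            s0 = min([s for s, _ in repeat_ivs] + [alu_exon_sense[0]])
            e0 = max([e for _, e in repeat_ivs] + [alu_exon_sense[1]])
            repeat_ivs = [(s0, e0)]
        elif exonized and event == "subthreshold":
            # repeat covers pre-piece plus the first 24 bp of the exon
            s0 = min(s for s, _ in repeat_ivs)
            repeat_ivs = [(s0, alu_exon_sense[0] + 24)]

        genomic_exons = sorted(to_genomic(s, e) for s, e, _ in exon_ivs)
        # CDS span: start of first coding chunk .. end of TAA
        cds_sense_s = None
        for kind, s, e, tag in sense_intervals:
            if tag.startswith("cds") or tag in ("last", "last_cds"):
                cds_sense_s = s
                break
        # locate end of CDS (TAA) inside the terminal coding exon
        for kind, s, e, tag in sense_intervals:
            if tag in ("last", "last_cds"):
                cds_sense_e = s + len(chunks[-1])
        gs, ge = to_genomic(cds_sense_s, cds_sense_e)
        cds_start, cds_end = min(gs, ge), max(gs, ge)

        transcripts.append(
            TranscriptModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
                exons=genomic_exons, cds_start=cds_start, cds_end=cds_end,
            )
        )
        for s, e in repeat_ivs:
            g0, g1 = to_genomic(s, e)
            repeats.append(
                RepeatAnnotation(chrom=chrom, start=min(g0, g1), end=max(g0, g1),
                                 strand=strand, name=plan["subfamily"], family="SINE/Alu")
            )

        if not exonized:
            continue

        # --- ground truth for the planted event ------------------------------
        exon_list = [(s, e, tag) for kind, s, e, tag in sense_intervals if kind == "exon"]
        exon_seqs = {tag: gene_sense[s:e] for s, e, tag in exon_list}
        order = [tag for _, _, tag in exon_list]
        mrna = "".join(exon_seqs[t] for t in order)
        idx = order.index("alu")
        up_tag, down_tag = order[idx - 1], order[idx + 1]
        x0 = sum(len(exon_seqs[t]) for t in order[:idx])
        x1 = x0 + len(exon_seqs["alu"])

        # independent translation of the inclusion isoform
        atg = sum(len(exon_seqs[t]) for t in order[: order.index(
            next(t for t in order if t.startswith("cds") or t in ("last", "last_cds")))])
        stop_end = None
        for i in range(atg, len(mrna) - 2, 3):
            if mrna[i : i + 3] in STOP_CODONS:
                stop_end = i + 3
                break
        stop_lost = stop_end is None
        last_junction = len(mrna) - len(exon_seqs[order[-1]])
        ptc = "PTC" if (not stop_lost and last_junction - stop_end > 50) else "NON_PTC"

        # ribo translatability of each junction (inclusion isoform for
        # UPSTREAM/DOWNSTREAM, skipping isoform for SKIPPING)
        skip_mrna = "".join(exon_seqs[t] for t in order if t != "alu")
        skip_atg = sum(len(exon_seqs[t]) for t in order[: order.index(
            next(t for t in order if t.startswith("cds") or t in ("last", "last_cds")))]
            if t != "alu")
        skip_stop = None
        for i in range(skip_atg, len(skip_mrna) - 2, 3):
            if skip_mrna[i : i + 3] in STOP_CODONS:
                skip_stop = i + 3
                break
        skip_junction = x0  # boundary between up flank and down flank in skip mRNA
        ribo_translated = {
            "UPSTREAM": stop_lost or stop_end > x0,
            "DOWNSTREAM": stop_lost or stop_end > x1,
            "SKIPPING": skip_stop is None or skip_stop > skip_junction,
        }

        flank = 27
        up_seq, down_seq, mid_seq = exon_seqs[up_tag], exon_seqs[down_tag], exon_seqs["alu"]
        junctions = {
            "UPSTREAM": up_seq[-flank:] + mid_seq[:flank],
            "DOWNSTREAM": mid_seq[-flank:] + down_seq[:flank],
            "SKIPPING": up_seq[-flank:] + down_seq[:flank],
        }
        boundaries = {
            "UPSTREAM": min(flank, len(up_seq)),
            "DOWNSTREAM": min(flank, len(mid_seq)),
            "SKIPPING": min(flank, len(up_seq)),
        }

        alu_s, alu_e = alu_exon_sense
        g0, g1 = to_genomic(alu_s, alu_e)
        psi = {t: float(np.round(rng.beta(*config.psi_beta), 6)) for t in config.tissues}
        tfactor = (config.translation_factor_coding
                   if ptc == "NON_PTC" else config.translation_factor_ptc)
        truth.append(
            PlantedExon(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
                start=min(g0, g1), end=max(g0, g1),
                subfamily=plan["subfamily"],
                region=region, event_type=event, frame=0,
                expect_found=event != "subthreshold",
                divisible_by_3=len(mid_seq) % 3 == 0,
                ptc=ptc, stop_lost=stop_lost,
                psi=psi, translation_factor=tfactor,
                junctions=junctions, junction_boundaries=boundaries,
                ribo_translated=ribo_translated,
            )
        )

    return SimulatedGenome(
        genome=GenomeSequence(genome),
        transcripts=transcripts,
        repeats=repeats,
        truth=truth,
        config=config,
    )


def simulate_junction_counts(
    truth: Sequence[PlantedExon],
    config: SimulationConfig,
    assay: str = "rna",
    seed: Optional[int] = None,
    samples: Optional[Sequence[str]] = None,
    depth: Optional[float] = None,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Binomially sampled junction counts for the planted exons.

    Each junction is sampled independently in proportion to the abundance
    of the isoform carrying it: with ``depth`` read opportunities per
    junction, UJC and DJC are each Binomial(depth, psi * t) and SJC is
    Binomial(depth, 1 - psi), with t the event's translation factor for
    ``assay='ribo'`` and 1 for RNA. All three junctions having equal
    mappable length by construction, the averaged-junction estimator
    PSI = ((UJC+DJC)/2) / ((UJC+DJC)/2 + SJC) is consistent for psi. In
    the Ribo-seq assay no footprints are generated on junctions 3' of the
    relevant isoform's stop codon. ``noiseless=True`` replaces sampling
    by exact (float-valued) expectations, so the estimated PSI equals the
    planted value to machine precision - the noiseless limit used for
    exact-recovery checks.
    """
    if assay not in ("rna", "ribo"):
        raise ValueError("assay must be 'rna' or 'ribo'")
    depth_mean = config.depth_mean if depth is None else depth
    if depth_mean <= 0:
        raise ValueError("depth must be positive")
    if samples is None:
        samples = list(config.tissues) if assay == "rna" else ["hela_ribo"]
    rng = np.random.default_rng([config.seed if seed is None else seed,
                                 22 if assay == "rna" else 23])
    rows = []
    for ev in truth:
        for si, sample in enumerate(samples):
            tissue = config.tissues[si % len(config.tissues)]
            psi = ev.psi[tissue]
            t = ev.translation_factor if assay == "ribo" else 1.0
            p_incl = min(1.0, psi * t)
            p_skip = 1.0 - psi
            if noiseless:
                # exact expectations (float-valued counts): PSI_hat == psi
                ujc = djc = depth_mean * p_incl
                sjc = depth_mean * p_skip
            else:
                n = int(rng.poisson(depth_mean))
                ujc = int(rng.binomial(n, p_incl)) if n else 0
                djc = int(rng.binomial(n, p_incl)) if n else 0
                sjc = int(rng.binomial(n, p_skip)) if n else 0
            if assay == "ribo":
                if not ev.ribo_translated.get("UPSTREAM", True):
                    ujc = 0
                if not ev.ribo_translated.get("DOWNSTREAM", True):
                    djc = 0
                if not ev.ribo_translated.get("SKIPPING", True):
                    sjc = 0
            rows.append({"exon_id": ev.exon_id, "sample": sample,
                         "UJC": ujc, "DJC": djc, "SJC": sjc})
    return pd.DataFrame(rows, columns=["exon_id", "sample", "UJC", "DJC", "SJC"])


def simulate_junction_reads(
    counts: pd.DataFrame,
    truth: Sequence[PlantedExon],
    read_length: int,
    seed: int = 0,
) -> list[str]:
    """Materialise a count table as read sequences drawn from the planted
    junction sequences, each read covering the splice boundary."""
    rng = np.random.default_rng([seed, 24])
    by_exon = {ev.exon_id: ev for ev in truth}
    role_col = {"UPSTREAM": "UJC", "DOWNSTREAM": "DJC", "SKIPPING": "SJC"}
    reads = []
    for _, row in counts.iterrows():
        ev = by_exon[row["exon_id"]]
        for role, col in role_col.items():
            seq = ev.junctions[role]
            b = ev.junction_boundaries[role]
            lo = max(0, b + 1 - read_length)
            hi = min(len(seq) - read_length, b - 1)
            if hi < lo:
                continue
            for _ in range(int(row[col])):
                off = int(rng.integers(lo, hi + 1))
                reads.append(seq[off : off + read_length])
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_peptides(
    truth: Sequence[PlantedExon],
    space: ProteinSpace,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Plant a peptide library with known intended classifications.

    Emits unique exon-body peptides, junction-spanning peptides (>=1 aa
    on each side of a junction), multi-mapping decoys (from event pairs
    sharing an identical exon slice), sub-length peptides, and unique
    background-only peptides. Returns columns peptide / label / exon_id.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 31])
    L = config.peptide_length
    by_exon = {iso.exon_id: iso for iso in space.isoforms}
    rows = []
    seen: set[str] = set()

    def plant(pep: str, label: str, exon_id: str) -> None:
        if pep and pep not in seen:
            seen.add(pep)
            rows.append({"peptide": pep, "label": label, "exon_id": exon_id})

    n_short_planted = 0
    for ev in truth:
        iso = by_exon.get(ev.exon_id)
        if iso is None or ev.event_type not in ("coding",):
            continue
        a, b = iso.exon_aa_span
        ja, jb = iso.junction_aa
        prot = iso.protein
        # is this event part of a decoy pair? (identical body elsewhere)
        body_window = prot[a : a + L] if b - a >= L else ""
        n_occ = len(space.occurrences(body_window)) if body_window else 0
        if n_occ > 1:
            plant(body_window, "DECOY_MULTI", ev.exon_id)
        elif body_window:
            # slide to find a unique body window
            for start in range(a, b - L + 1):
                pep = prot[start : start + L]
                if len(space.occurrences(pep)) == 1:
                    plant(pep, "UNIQUE_BODY", ev.exon_id)
                    break
        # junction-spanning peptides: window centred on each junction
        for jpos, label in ((ja, "UNIQUE_JUNCTION_UP"), (jb, "UNIQUE_JUNCTION_DOWN")):
            start = jpos - L // 2
            if start < 0 or start + L > len(prot):
                continue
            pep = prot[start : start + L]
            if len(space.occurrences(pep)) == 1:
                plant(pep, label, ev.exon_id)
        # sub-length peptides (must be rejected)
        if b - a >= 5 and n_short_planted < config.n_short_peptides:
            plant(prot[a : a + 5], "TOO_SHORT", ev.exon_id)
            n_short_planted += 1

    background_names = sorted(space.background)
    for _ in range(config.n_background_peptides):
        for _try in range(20):
            name = background_names[int(rng.integers(len(background_names)))]
            prot = space.background[name]
            if len(prot) < L + 2:
                continue
            start = int(rng.integers(0, len(prot) - L))
            pep = prot[start : start + L]
            if len(space.occurrences(pep)) == 1:
                plant(pep, "BACKGROUND", "")
                break
    return pd.DataFrame(rows, columns=["peptide", "label", "exon_id"])


def protein_space_from_simulation(sim: SimulatedGenome) -> ProteinSpace:
    """Protein space for the simulated study: inclusion-isoform ORFs for
    every planted (found) event, plus the annotated translations of all
    non-host genes as the background proteome."""
    from .annotation import build_inclusion_orf, translate_annotated
    from .peptides import build_protein_space

    by_tx = {t.transcript_id: t for t in sim.transcripts}
    hosts = {ev.transcript_id for ev in sim.truth}
    orfs = {}
    for ev in sim.truth:
        if not ev.expect_found:
            continue
        tx = by_tx[ev.transcript_id]
        orfs[ev.exon_id] = build_inclusion_orf(tx, (ev.start, ev.end), sim.genome)
    background = {
        tx.transcript_id: translate_annotated(tx, sim.genome)
        for tx in sim.transcripts
        if tx.transcript_id not in hosts and tx.has_cds
    }
    return build_protein_space(background, orfs)


def simulate_editing_counts(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[EditingCounts, pd.DataFrame]:
    """3x3-replicate editing count tables with planted effects.

    Per site a baseline level is drawn from a Beta distribution; each
    condition shifts it on the logit scale (EV always 0; SHORT/LONG by
    the configured delta according to the site's label). Replicate
    coverage is negative-binomial; edited counts are binomial at the
    group's level. Returns the count table plus per-site ground truth.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 41])
    labels = (
        ["null"] * config.n_null_sites
        + ["common"] * config.n_common_sites
        + ["short_only"] * config.n_short_only_sites
        + ["long_only"] * config.n_long_only_sites
    )
    n = len(labels)
    a, b = config.editing_baseline_beta
    baseline = rng.beta(a, b, n)
    delta = config.editing_delta
    deltas = {
        "EV": np.zeros(n),
        "SHORT": np.where(np.isin(labels, ["common", "short_only"]), delta, 0.0),
        "LONG": np.where(np.isin(labels, ["common", "long_only"]), delta, 0.0),
    }
    logit = np.log(baseline / (1 - baseline))
    levels = {g: 1 / (1 + np.exp(-(logit + d))) for g, d in deltas.items()}

    m = config.editing_coverage_mean
    r = config.editing_coverage_dispersion
    p_nb = r / (r + m)
    data = {
        "chrom": ["chrE"] * n,
        "pos": np.arange(1, n + 1) * 100,
        "strand": ["+"] * n,
    }
    for lib, (group, _) in DEFAULT_MANIFEST.items():
        cov = rng.negative_binomial(r, p_nb, n)
        e = rng.binomial(cov, levels[group])
        data[f"e_{lib}"] = e
        data[f"u_{lib}"] = cov - e
    table = pd.DataFrame(data)
    counts = EditingCounts(table)
    truth = pd.DataFrame({
        "site_id": counts.table["site_id"],
        "label": labels,
        "level_EV": levels["EV"],
        "level_SHORT": levels["SHORT"],
        "level_LONG": levels["LONG"],
    })
    return counts, truth
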