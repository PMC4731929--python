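"""Splice-junction libraries, read matching, and exon inclusion levels (PSI).

For each cassette exon three junction sequences are built, each 54 nt by
default: the last 27 nt of the 5' sequence joined to the first 27 nt of
the 3' sequence, for the upstream-inclusion, downstream-inclusion and
skipping junctions. Reads are matched ungapped with a mismatch cap and a
uniqueness requirement, yielding per-sample counts (UJC, DJC, SJC) from
which the percent-spliced-in is estimated as

    PSI = I / (I + S),   I = (UJC + DJC) / 2,   S = SJC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .models import JunctionRole, TranscriptModel
from .stats import bh_fdr, fisher_exact_2x2

FLANK_NT = 27
COVERAGE_MIN_READS = 10

COUNT_COLUMNS = ["exon_id", "sample", "UJC", "DJC", "SJC"]
_ROLE_COLUMN = {
    JunctionRole.UPSTREAM: "UJC",
    JunctionRole.DOWNSTREAM: "DJC",
    JunctionRole.SKIPPING: "SJC",
}


@dataclass
class JunctionLibrary:
    """The three junction sequences of one cassette exon.

    ``boundary[role]`` is the position of the splice boundary within the
    junction sequence (= length of the 5' segment). ``truncated`` marks
    junctions whose segments were shortened by a short exon.
    """

    exon_id: str
    sequences: dict[JunctionRole, str]
    boundary: dict[JunctionRole, int]
    truncated: bool = False


def build_junction_library(
    transcript: TranscriptModel,
    alu_exon: tuple[int, int],
    genome: GenomeSequence,
    flank: int = FLANK_NT,
) -> JunctionLibrary:
    """Build upstream/downstream/skipping junction sequences on the
    transcript (sense) strand. Segments are truncated (and the library
    flagged) when the cassette or a flanking exon is shorter than ``flank``.
    """
    from .annotation import splice_in_exon

    tx = splice_in_exon(transcript, alu_exon)
    sense = tx.exons_in_sense()
    idx = sense.index(tuple(alu_exon))
    if idx == 0 or idx == len(sense) - 1:
        raise ValueError(f"exon {alu_exon} is not internal in {transcript.transcript_id}")
    up, mid, down = sense[idx - 1], sense[idx], sense[idx + 1]

    def tail(exon: tuple[int, int]) -> str:  # last `flank` nt in sense
        seq = genome.fetch(tx.chrom, exon[0], exon[1], tx.strand)
        return seq[-flank:]

    def head(exon: tuple[int, int]) -> str:  # first `flank` nt in sense
        seq = genome.fetch(tx.chrom, exon[0], exon[1], tx.strand)
        return seq[:flank]

    pieces = {
        JunctionRole.UPSTREAM: (tail(up), head(mid)),
        JunctionRole.DOWNSTREAM: (tail(mid), head(down)),
        JunctionRole.SKIPPING: (tail(up), head(down)),
    }
    sequences = {role: a + b for role, (a, b) in pieces.items()}
    boundary = {role: len(a) for role, (a, _) in pieces.items()}
    truncated = any(len(s) < 2 * flank for s in sequences.values())
    exon_id = f"{tx.chrom}:{mid[0]}-{mid[1]}:{tx.strand}"
    return JunctionLibrary(exon_id=exon_id, sequences=sequences, boundary=boundary, truncated=truncated)


def _best_offset_mismatches(read: str, junction: str, boundary: int) -> int | None:
    """Fewest mismatches over ungapped offsets where the read covers the
    splice boundary with >=1 nt on each side; None if no valid offset."""
    n, m = len(read), len(junction)
    if n > m:
        return None
    lo = max(0, boundary + 1 - n)
    hi = min(m - n, boundary - 1)
    best: int | None = None
    for off in range(lo, hi + 1):
        mm = sum(a != b for a, b in zip(read, junction[off : off + n]))
        if best is None or mm < best:
            best = mm
            if best == 0:
                break
    return best


def match_reads(
    reads: Iterable[str],
    libraries: Sequence[JunctionLibrary],
    read_prefix_length: int,
    max_mismatches: int = 2,
    sample: str = "sample1",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match reads against a junction library collection.

    Each read is trimmed to its first ``read_prefix_length`` nt (shorter
    reads are skipped and tallied). A read counts toward a junction iff it
    aligns ungapped with at most ``max_mismatches`` mismatches while
    overlapping the splice boundary, and exactly one junction in the whole
    collection attains the minimal mismatch count (ties are discarded as
    multi-mapped). Returns the count table and a tally log.
    """
    counts: dict[tuple[str, JunctionRole], int] = {
        (lib.exon_id, role): 0 for lib in libraries for role in lib.sequences
    }
    log = {"reads_in": 0, "too_short": 0, "unmapped": 0, "multi_mapped": 0, "counted": 0}
    for read in reads:
        log["reads_in"] += 1
        if len(read) < read_prefix_length:
            log["too_short"] += 1
            continue
        read = read[:read_prefix_length].upper()
        best_mm: int | None = None
        best_keys: list[tuple[str, JunctionRole]] = []
        for lib in libraries:
            for role, seq in lib.sequences.items():
                mm = _best_offset_mismatches(read, seq, lib.boundary[role])
                if mm is None or mm > max_mismatches:
                    continue
                if best_mm is None or mm < best_mm:
                    best_mm, best_keys = mm, [(lib.exon_id, role)]
                elif mm == best_mm:
                    best_keys.append((lib.exon_id, role))
        if best_mm is None:
            log["unmapped"] += 1
        elif len(best_keys) > 1:
            log["multi_mapped"] += 1
        else:
            counts[best_keys[0]] += 1
            log["counted"] += 1

    rows = []
    for lib in libraries:
        row = {"exon_id": lib.exon_id, "sample": sample}
        for role, col in _ROLE_COLUMN.items():
            row[col] = counts.get((lib.exon_id, role), 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=COUNT_COLUMNS), log


def compute_psi(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent-spliced-in per (exon, sample) from junction counts.

    Adds ``psi`` (NaN when inclusion + skipping support is zero),
    ``max_jc`` and the coverage flag ``covered`` (max junction count >= 10).
    """
    df = counts.copy()
    for col in ("UJC", "DJC", "SJC"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    inclusion = (df["UJC"] + df["DJC"]) / 2.0
    denom = inclusion + df["SJC"]
    df["psi"] = np.where(denom > 0, inclusion / denom.replace(0, np.nan), np.nan)
    df["max_jc"] = df[["UJC", "DJC", "SJC"]].max(axis=1)
    df["covered"] = df["max_jc"] >= COVERAGE_MIN_READS
    return df


def select_high_inclusion(
    psis: pd.DataFrame, threshold: float = 0.33, min_max_junction: int = COVERAGE_MIN_READS
) -> list[str]:
    """Exons with PSI >= threshold in at least one covered sample."""
    ok = psis[(psis["max_jc"] >= min_max_junction) & (psis["psi"] >= threshold)]
    return sorted(ok["exon_id"].unique())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def differential_splicing_standin(
    counts: pd.DataFrame,
    sample_pairs: Sequence[tuple[str, str]],
    delta_threshold: float = 0.10,
    fdr_threshold: float = 0.10,
    min_max_junction: int = COVERAGE_MIN_READS,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise differential-splicing screen (declared stand-in).

    For each exon and sample pair where both samples pass the coverage
    gate, a two-sided Fisher exact test is run on the 2x2 table of rounded
    inclusion support I = round((UJC+DJC)/2) versus skipping counts, with
    BH correction over all (exon, pair) hypotheses jointly. An exon is
    called when some pair shows |dPSI| >= ``delta_threshold`` at
    q < ``fdr_threshold``. This is a simple substitute for a full
    likelihood-based differential-splicing model and is not claimed
    equivalent to one.
    """
    samples = counts["sample"].unique()
    if len(samples) < 2:
        raise ValueError("differential splicing needs at least 2 samples")
    psis = compute_psi(counts)
    indexed = psis.set_index(["exon_id", "sample"])

    rows = []
    for exon in psis["exon_id"].unique():
        for a, b in sample_pairs:
            try:
                ra, rb = indexed.loc[(exon, a)], indexed.loc[(exon, b)]
            except KeyError:
                continue
            if not (ra["covered"] and rb["covered"]):
                continue
            ia = _round_half_up((ra["UJC"] + ra["DJC"]) / 2.0)
            ib = _round_half_up((rb["UJC"] + rb["DJC"]) / 2.0)
            sa, sb = int(ra["SJC"]), int(rb["SJC"])
            table = [[ia, sa], [ib, sb]]
            if ia + ib == 0 or sa + sb == 0 or ia + sa == 0 or ib + sb == 0:
                p = 1.0  # empty margin: no evidence of a difference
            else:
                _, p = fisher_exact_2x2(table)
            dpsi = (np.nan if np.isnan(ra["psi"]) or np.isnan(rb["psi"])
                    else ra["psi"] - rb["psi"])
            rows.append({"exon_id": exon, "sample_a": a, "sample_b": b,
                         "delta_psi": dpsi, "p": p})
    result = pd.DataFrame(rows, columns=["exon_id", "sample_a", "sample_b", "delta_psi", "p"])
    if result.empty:
        return result.assign(q=pd.Series(dtype=float)), []
    result["q"] = bh_fdr(result["p"].to_numpy())
    called_mask = (result["delta_psi"].abs() >= delta_threshold) & (result["q"] < fdr_threshold)
    called = sorted(result.loc[called_mask, "exon_id"].unique())
    return result, called


def combine_lists(high_inclusion: Iterable[str], differential: Iterable[str]) -> list[str]:
    """Deduplicated union of the two exon lists, sorted by key."""
    return sorted(set(high_inclusion) | set(differential))
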