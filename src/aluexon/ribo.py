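"""Translational evidence from ribosome-profiling junction reads.

Ribo-seq footprints mapped to the same junction library as the RNA-seq
reads yield a footprint-based inclusion level; comparing it with the
matched RNA-seq PSI distinguishes exons whose inclusion isoform is
actively translated from those whose inclusion reads are transcript-only.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .models import TranslationEvidence
from .junctions import compute_psi
from .stats import fisher_exact_2x2

RIBO_READ_PREFIX = 30


def trim_to_prefix(reads: Iterable[str], n: int = RIBO_READ_PREFIX) -> tuple[list[str], int]:
    """Truncate each read to its first ``n`` nt; drop and tally shorter reads."""
    if n <= 0:
        raise ValueError(f"prefix length must be positive, got {n}")
    kept, dropped = [], 0
    for r in reads:
        if len(r) < n:
            dropped += 1
        else:
            kept.append(r[:n])
    return kept, dropped


def compare_ribo_rna(
    ribo_counts: pd.DataFrame, rna_counts: pd.DataFrame
) -> list[TranslationEvidence]:
    """Joint inclusion-level evidence per exon from both assays.

    Both count tables must cover the same exon universe. Flags are only
    set for exons passing the dual coverage gate (>=10 reads on one of the
    three junctions in each assay).
    """
    ribo_exons = set(ribo_counts["exon_id"])
    rna_exons = set(rna_counts["exon_id"])
    if ribo_exons != rna_exons:
        diff = sorted(ribo_exons ^ rna_exons)
        raise ValueError(f"mismatched exon universes between assays: {diff[:10]}")

    ribo = compute_psi(ribo_counts).groupby("exon_id").agg(
        psi=("psi", "first"), covered=("covered", "any")
    )
    rna = compute_psi(rna_counts).groupby("exon_id").agg(
        psi=("psi", "first"), covered=("covered", "any")
    )
    evidence = []
    for exon in sorted(ribo_exons):
        r, m = ribo.loc[exon], rna.loc[exon]
        covered = bool(r["covered"] and m["covered"])
        evidence.append(
            TranslationEvidence(
                exon_id=exon,
                psi_ribo=None if pd.isna(r["psi"]) else float(r["psi"]),
                psi_rna=None if pd.isna(m["psi"]) else float(m["psi"]),
                covered_in_both=covered,
            )
        )
    return evidence


def ribo_enrichment_test(
    strong_coding: tuple[int, int], strong_control: tuple[int, int]
) -> float:
    """One-sided (greater) Fisher exact p for enrichment of strongly
    translated exons in the candidate coding set over the control set.

    Arguments are (hits, total) pairs.
    """
    (hc, nc), (hk, nk) = strong_coding, strong_control
    for h, n in ((hc, nc), (hk, nk)):
        if h < 0 or n < 0 or h > n:
            raise ValueError(f"invalid (hits, total) pair ({h}, {n})")
    _, p = fisher_exact_2x2([[hc, nc - hc], [hk, nk - hk]], alternative="greater")
    return p


def evidence_table(evidence: Sequence[TranslationEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "exon_id": [e.exon_id for e in evidence],
            "psi_ribo": [e.psi_ribo for e in evidence],
            "psi_rna": [e.psi_rna for e in evidence],
            "covered_in_both": [e.covered_in_both for e in evidence],
            "nonzero_ribo": [e.nonzero_ribo for e in evidence],
            "strong_ribo": [e.strong_ribo for e in evidence],
            "higher_in_ribo": [e.higher_in_ribo for e in evidence],
        }
    )
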