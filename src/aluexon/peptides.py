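"""Proteogenomic peptide mapping onto exon-inclusion ORFs.

Peptides (plain amino-acid strings) are searched against a protein space
consisting of a background proteome plus the translated exon-inclusion
isoforms. Only peptides of at least six residues that occur at exactly one
location in the whole space are retained; matches intersecting a cassette
exon's amino-acid span become hits, classified as exon-body or
junction-spanning. NMD-inducing exons provide a negative control from
which an upper-bound false-discovery rate for the hit list is estimated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .models import OrfResult, PeptideHit, PeptideLocation
from .stats import fisher_exact_2x2

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LENGTH = 6
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class InclusionIsoform:
    """One exon-inclusion ORF translation with its exon span annotated."""

    exon_id: str
    protein: str
    exon_aa_span: tuple[int, int]      # half-open, straddling codons included
    junction_aa: tuple[int, int]       # upstream/downstream junction positions


@dataclass
class ProteinSpace:
    """Searchable space of background proteins and inclusion isoforms."""

    background: dict[str, str]
    isoforms: list[InclusionIsoform]

    def proteins(self) -> dict[str, str]:
        out = dict(self.background)
        for iso in self.isoforms:
            out[f"inclusion|{iso.exon_id}"] = iso.protein
        return out

    def occurrences(self, peptide: str) -> list[tuple[str, int]]:
        """All (protein id, offset) occurrences of ``peptide`` in the space."""
        hits = []
        for name, seq in self.proteins().items():
            start = seq.find(peptide)
            while start != -1:
                hits.append((name, start))
                start = seq.find(peptide, start + 1)
        return hits


def build_protein_space(
    background: Mapping[str, str],
    alu_exon_orfs: Mapping[str, OrfResult],
) -> ProteinSpace:
    """Assemble the protein space from background translations plus
    per-exon inclusion-isoform ORF results.

    ORFs whose exon lies outside the translated region (no amino-acid
    span) or that could not be translated are skipped with a log entry.
    """
    isoforms = []
    for exon_id, orf in alu_exon_orfs.items():
        if not orf.protein or orf.exon_aa_span is None:
            logger.info("skipping untranslatable/extra-ORF isoform for exon %s", exon_id)
            continue
        isoforms.append(
            InclusionIsoform(
                exon_id=exon_id,
                protein=orf.protein,
                exon_aa_span=orf.exon_aa_span,
                junction_aa=orf.junction_aa or orf.exon_aa_span,
            )
        )
    return ProteinSpace(background=dict(background), isoforms=isoforms)


def _classify_location(
    match: tuple[int, int], iso: InclusionIsoform
) -> Optional[PeptideLocation]:
    m0, m1 = match
    a, b = iso.junction_aa
    if m0 < a < m1:
        return PeptideLocation.UPSTREAM_JUNCTION
    if m0 < b < m1:
        return PeptideLocation.DOWNSTREAM_JUNCTION
    s, e = iso.exon_aa_span
    if m0 >= s and m1 <= e:
        return PeptideLocation.EXON_BODY
    return None


def map_peptides(
    peptides: Iterable[str],
    space: ProteinSpace,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> tuple[list[PeptideHit], dict[str, int]]:
    """Map peptides to the protein space under the uniqueness rule.

    Peptides shorter than ``min_length`` or containing non-amino-acid
    characters are rejected; peptides occurring at more than one location
    anywhere in the space are dropped. A unique match intersecting an
    inclusion isoform's exon span or one of its junctions becomes a hit.
    Returns the hits plus a tally of rejections.
    """
    by_protein = {f"inclusion|{iso.exon_id}": iso for iso in space.isoforms}
    hits: list[PeptideHit] = []
    log = {"peptides_in": 0, "too_short": 0, "bad_characters": 0,
           "multi_mapped": 0, "no_match": 0, "outside_exons": 0, "hits": 0}
    for pep in dict.fromkeys(peptides):  # dedupe, keep order
        log["peptides_in"] += 1
        if len(pep) < min_length:
            log["too_short"] += 1
            continue
        if not set(pep) <= AA_ALPHABET:
            log["bad_characters"] += 1
            continue
        occ = space.occurrences(pep)
        if len(occ) == 0:
            log["no_match"] += 1
            continue
        if len(occ) > 1:
            log["multi_mapped"] += 1
            continue
        protein, start = occ[0]
        iso = by_protein.get(protein)
        loc = None if iso is None else _classify_location((start, start + len(pep)), iso)
        if loc is None:
            log["outside_exons"] += 1
            continue
        hits.append(
            PeptideHit(
                peptide=pep, exon_id=iso.exon_id, location=loc,
                protein_id=protein, match_start=start, match_end=start + len(pep),
            )
        )
        log["hits"] += 1
    return hits, log


def classify_hits(hits: Sequence[PeptideHit]) -> dict[str, dict[str, bool]]:
    """Per-exon summary: any hit, and any junction-spanning hit.

    A hit is junction-spanning when its match covers at least one amino
    acid strictly on each side of a junction position.
    """
    summary: dict[str, dict[str, bool]] = {}
    for h in hits:
        rec = summary.setdefault(h.exon_id, {"has_hit": False, "has_junction_spanning_hit": False})
        rec["has_hit"] = True
        if h.location in (PeptideLocation.UPSTREAM_JUNCTION, PeptideLocation.DOWNSTREAM_JUNCTION):
            rec["has_junction_spanning_hit"] = True
    return summary


def negative_control_fdr(
    n_candidates: int, candidate_hits: int, n_control: int, control_hits: int
) -> tuple[float, int, float]:
    """FDR upper bound for the candidate hit list from a negative control.

    The control hit rate is projected onto the candidate set to give the
    expected number of false-positive hits (rounded half-up); dividing by
    the observed candidate hits yields the upper-bound FDR. Returns
    ``(background_rate, expected_false_positives, fdr_upper_bound)``.
    """
    for name, v in (("n_candidates", n_candidates), ("candidate_hits", candidate_hits),
                    ("n_control", n_control), ("control_hits", control_hits)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if candidate_hits > n_candidates or control_hits > n_control:
        raise ValueError("hits cannot exceed totals")
    if n_control == 0:
        raise ValueError("control set is empty")
    if candidate_hits == 0:
        raise ValueError("candidate_hits = 0: FDR undefined")
    rate = control_hits / n_control
    expected_fp = int(math.floor(n_candidates * rate + 0.5))
    return rate, expected_fp, expected_fp / candidate_hits


def hit_rate_enrichment(
    candidate: tuple[int, int], control: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p comparing hit rates between candidate and
    control exon sets; arguments are (hits, total) pairs."""
    (hc, nc), (hk, nk) = candidate, control
    _, p = fisher_exact_2x2([[hc, nc - hc], [hk, nk - hk]])
    return p
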