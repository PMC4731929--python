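"""Shared fixtures: toy gene models and a session-wide simulated study."""

from __future__ import annotations

import math

import pytest

from aluexon import GenomeSequence, SimulationConfig, TranscriptModel, simulate_genome


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic synthetic study reused across tests."""
    cfg = SimulationConfig(seed=777)
    return cfg, simulate_genome(cfg)


@pytest.fixture
def toy_gene():
    """Three-exon plus-strand toy gene: ATGGCA | GCAGCA | GCATAA.

    The middle exon is the cassette; the annotated transcript holds only
    the flanks, with the CDS spanning ATG..TAA. Returns
    (genome, transcript, cassette_exon_interval).
    """
    seq = "ATGGCA" + "GTAG" + "GCAGCA" + "GTAG" + "GCATAA" + "ACGT"
    genome = GenomeSequence({"c": seq})
    tx = TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="c", strand="+",
        exons=[(0, 6), (20, 26)], cds_start=0, cds_end=26,
    )
    return genome, tx, (10, 16)


@pytest.fixture
def toy_gene_minus():
    """The same toy gene laid out on the minus strand."""
    from Bio.Seq import reverse_complement

    sense = "ATGGCA" + "GTAG" + "GCAGCA" + "GTAG" + "GCATAA" + "ACGT"
    seq = reverse_complement(sense)
    L = len(sense)

    def flip(iv):
        return (L - iv[1], L - iv[0])

    genome = GenomeSequence({"c": seq})
    tx = TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="c", strand="-",
        exons=sorted([flip((0, 6)), flip((20, 26))]),
        cds_start=flip((0, 26))[0], cds_end=flip((0, 26))[1],
    )
    return genome, tx, flip((10, 16))


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementations they check

def hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins (r1, r2 rows; c1 first column)."""
    n = r1 + r2
    return math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)


def fisher_oracle(table, alternative="two_sided") -> float:
    """Fisher exact p by explicit enumeration of all tables at fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom_pmf(x, r1, r2, c1)
        if alternative == "two_sided":
            if p <= p_obs * (1 + 1e-7):
                total += p
        elif alternative == "greater":
            if x >= a:
                total += p
        elif alternative == "less":
            if x <= a:
                total += p
    return min(1.0, total)


def wilcoxon_signflip_oracle(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied magnitudes.
    """
    import itertools

    import numpy as np

    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, dtype=float)
    m = len(ws)
    p_low = (ws <= w_obs).sum() / m
    p_high = (ws >= w_obs).sum() / m
    return min(1.0, 2 * min(p_low, p_high))
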