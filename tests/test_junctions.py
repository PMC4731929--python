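"""Junction libraries, read matching and PSI estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aluexon import (
    GenomeSequence,
    JunctionRole,
    TranscriptModel,
    build_junction_library,
    combine_lists,
    compute_psi,
    differential_splicing_standin,
    match_reads,
    select_high_inclusion,
)
from aluexon.junctions import JunctionLibrary

from .conftest import fisher_oracle


def _counts(rows):
    return pd.DataFrame(rows, columns=["exon_id", "sample", "UJC", "DJC", "SJC"])


@pytest.fixture
def three_exon_library():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    e1, e2, e3 = ("".join(bases[rng.integers(0, 4, n)]) for n in (60, 40, 60))
    i1 = "".join(bases[rng.integers(0, 4, 100)])
    i2 = "".join(bases[rng.integers(0, 4, 100)])
    seq = e1 + i1 + e2 + i2 + e3
    genome = GenomeSequence({"c": seq})
    tx = TranscriptModel(gene_id="G", transcript_id="T", chrom="c", strand="+",
                         exons=[(0, 60), (300, 360)], cds_start=0, cds_end=360)
    cassette = (160, 200)
    return genome, tx, cassette, (e1, e2, e3)


class TestBuildJunctionLibrary:
    def test_constructive_definition(self, three_exon_library):
        genome, tx, cassette, (e1, e2, e3) = three_exon_library
        lib = build_junction_library(tx, cassette, genome)
        assert lib.sequences[JunctionRole.UPSTREAM] == e1[-27:] + e2[:27]
        assert lib.sequences[JunctionRole.DOWNSTREAM] == e2[-27:] + e3[:27]
        assert lib.sequences[JunctionRole.SKIPPING] == e1[-27:] + e3[:27]
        assert all(len(s) == 54 for s in lib.sequences.values())
        assert not lib.truncated

    def test_short_cassette_truncates_and_flags(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        e1, e2, e3 = ("".join(bases[rng.integers(0, 4, n)]) for n in (60, 20, 60))
        seq = e1 + "G" * 50 + e2 + "G" * 50 + e3
        genome = GenomeSequence({"c": seq})
        tx = TranscriptModel(gene_id="G", transcript_id="T", chrom="c", strand="+",
                             exons=[(0, 60), (180, 240)], cds_start=0, cds_end=240)
        lib = build_junction_library(tx, (110, 130), genome)
        assert lib.truncated
        assert lib.sequences[JunctionRole.UPSTREAM] == e1[-27:] + e2  # 27 + 20
        assert lib.boundary[JunctionRole.DOWNSTREAM] == 20

    def test_minus_strand_junctions_on_sense(self, three_exon_library):
        from Bio.Seq import reverse_complement

        genome, tx, cassette, (e1, e2, e3) = three_exon_library
        plus = build_junction_library(tx, cassette, genome)
        L = genome.length("c")
        seq = genome.fetch("c", 0, L)
        flip = lambda iv: (L - iv[1], L - iv[0])
        genome_m = GenomeSequence({"c": reverse_complement(seq)})
        tx_m = TranscriptModel(gene_id="G", transcript_id="T", chrom="c", strand="-",
                               exons=sorted([flip((0, 60)), flip((300, 360))]),
                               cds_start=0, cds_end=L)
        lib_m = build_junction_library(tx_m, flip(cassette), genome_m)
        assert lib_m.sequences == plus.sequences

    def test_non_internal_exon_rejected(self, three_exon_library):
        genome, tx, cassette, _ = three_exon_library
        with pytest.raises(ValueError, match="intron|internal"):
            build_junction_library(tx, (500, 560), genome)


class TestMatchReads:
    def _libs(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        libs = []
        for i in range(3):
            seqs = {role: "".join(bases[rng.integers(0, 4, 54)])
                    for role in JunctionRole}
            libs.append(JunctionLibrary(exon_id=f"E{i}", sequences=seqs,
                                        boundary={r: 27 for r in JunctionRole}))
        return libs

    def test_exact_read_counted_once(self):
        libs = self._libs()
        read = libs[0].sequences[JunctionRole.UPSTREAM][0:30]
        counts, log = match_reads([read], libs, read_prefix_length=30)
        assert log["counted"] == 1
        assert counts.set_index("exon_id").loc["E0", "UJC"] == 1

    def test_mismatch_cap(self):
        libs = self._libs()
        seq = libs[1].sequences[JunctionRole.SKIPPING]
        read = list(seq[10:40])
        for pos in (0, 5, 9):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        counts, log = match_reads(["".join(read)], libs, read_prefix_length=30)
        assert log["unmapped"] == 1
        two_mm = list(seq[10:40])
        for pos in (0, 5):
            two_mm[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[two_mm[pos]]
        counts, log = match_reads(["".join(two_mm)], libs, read_prefix_length=30)
        assert log["counted"] == 1
        assert counts.set_index("exon_id").loc["E1", "SJC"] == 1

    def test_ambiguous_read_discarded(self):
        libs = self._libs()
        shared = libs[0].sequences[JunctionRole.UPSTREAM]
        libs[2].sequences[JunctionRole.DOWNSTREAM] = shared
        read = shared[5:35]
        counts, log = match_reads([read], libs, read_prefix_length=30)
        assert log["multi_mapped"] == 1
        assert counts[["UJC", "DJC", "SJC"]].to_numpy().sum() == 0

    def test_short_reads_tallied(self):
        libs = self._libs()
        _, log = match_reads(["ACGT"], libs, read_prefix_length=30)
        assert log["too_short"] == 1

    def test_zero_mismatch_mode_equals_substring_search(self):
        libs = self._libs()
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        reads = []
        for _ in range(40):
            lib = libs[rng.integers(0, 3)]
            role = list(JunctionRole)[rng.integers(0, 3)]
            off = int(rng.integers(0, 25))
            reads.append(lib.sequences[role][off : off + 30])
        for _ in range(10):
            reads.append("".join(bases[rng.integers(0, 4, 30)]))
        counts, log = match_reads(reads, libs, read_prefix_length=30, max_mismatches=0)
        # oracle: substring membership with midpoint coverage and uniqueness
        expect = {(lib.exon_id, role): 0 for lib in libs for role in JunctionRole}
        n_counted = 0
        for read in reads:
            locs = []
            for lib in libs:
                for role, seq in lib.sequences.items():
                    off = seq.find(read)
                    while off != -1:
                        if off < 27 < off + len(read):
                            locs.append((lib.exon_id, role))
                        off = seq.find(read, off + 1)
            if len(locs) == 1:
                expect[locs[0]] += 1
                n_counted += 1
        got = counts.set_index("exon_id")
        col = {JunctionRole.UPSTREAM: "UJC", JunctionRole.DOWNSTREAM: "DJC",
               JunctionRole.SKIPPING: "SJC"}
        for (exon, role), n in expect.items():
            assert got.loc[exon, col[role]] == n
        assert log["counted"] == n_counted


class TestComputePsi:
    @pytest.mark.parametrize("ujc,djc,sjc,expected", [
        (10, 10, 10, 0.5),
        (20, 0, 0, 1.0),
        (7, 9, 4, 8 / 12),
        (0, 0, 20, 0.0),
    ])
    def test_formula(self, ujc, djc, sjc, expected):
        df = compute_psi(_counts([{"exon_id": "E", "sample": "s",
                                   "UJC": ujc, "DJC": djc, "SJC": sjc}]))
        assert df["psi"].iloc[0] == pytest.approx(expected)

    def test_undefined_when_no_support(self):
        df = compute_psi(_counts([{"exon_id": "E", "sample": "s",
                                   "UJC": 0, "DJC": 0, "SJC": 0}]))
        assert np.isnan(df["psi"].iloc[0]) and not df["covered"].iloc[0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(_counts([{"exon_id": "E", "sample": "s",
                                  "UJC": -1, "DJC": 0, "SJC": 0}]))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 9))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance_and_range(self, u, d, s, k):
        base = compute_psi(_counts([{"exon_id": "E", "sample": "s",
                                     "UJC": u, "DJC": d, "SJC": s}]))["psi"].iloc[0]
        scaled = compute_psi(_counts([{"exon_id": "E", "sample": "s",
                                       "UJC": k * u, "DJC": k * d, "SJC": k * s}]))["psi"].iloc[0]
        if np.isnan(base):
            assert np.isnan(scaled)
        else:
            assert 0.0 <= base <= 1.0
            assert scaled == pytest.approx(base)


class TestSelection:
    def test_threshold_and_coverage_gate(self):
        counts = _counts([
            {"exon_id": "A", "sample": "t1", "UJC": 10, "DJC": 10, "SJC": 20},  # psi ~0.33
            {"exon_id": "B", "sample": "t1", "UJC": 9, "DJC": 9, "SJC": 1},     # psi 0.9, max 9
            {"exon_id": "C", "sample": "t1", "UJC": 0, "DJC": 0, "SJC": 0},
        ])
        psis = compute_psi(counts)
        assert select_high_inclusion(psis, threshold=1 / 3) == ["A"]

    def test_one_sample_suffices(self):
        counts = _counts([
            {"exon_id": "A", "sample": "t1", "UJC": 1, "DJC": 1, "SJC": 40},
            {"exon_id": "A", "sample": "t2", "UJC": 30, "DJC": 30, "SJC": 10},
        ])
        assert select_high_inclusion(compute_psi(counts)) == ["A"]


class TestDifferentialStandin:
    def test_identical_counts_not_called(self):
        counts = _counts([
            {"exon_id": "A", "sample": "t1", "UJC": 30, "DJC": 30, "SJC": 30},
            {"exon_id": "A", "sample": "t2", "UJC": 30, "DJC": 30, "SJC": 30},
        ])
        result, called = differential_splicing_standin(counts, [("t1", "t2")])
        assert called == []
        assert result["delta_psi"].iloc[0] == 0

    def test_strong_shift_called_with_oracle_p(self):
        counts = _counts([
            {"exon_id": "A", "sample": "t1", "UJC": 90, "DJC": 90, "SJC": 10},
            {"exon_id": "A", "sample": "t2", "UJC": 40, "DJC": 40, "SJC": 60},
        ])
        result, called = differential_splicing_standin(counts, [("t1", "t2")])
        assert called == ["A"]
        assert result["delta_psi"].iloc[0] == pytest.approx(0.5)
        assert result["p"].iloc[0] == pytest.approx(
            fisher_oracle([[90, 10], [40, 60]]), rel=1e-9)

    def test_effect_size_gate_blocks_tiny_delta(self):
        counts = _counts([
            {"exon_id": "A", "sample": "t1", "UJC": 5000, "DJC": 5000, "SJC": 5000},
            {"exon_id": "A", "sample": "t2", "UJC": 5000, "DJC": 5000, "SJC": 5800},
        ])
        result, called = differential_splicing_standin(counts, [("t1", "t2")])
        assert abs(result["delta_psi"].iloc[0]) < 0.10
        assert result["q"].iloc[0] < 0.10  # highly significant yet not called
        assert called == []

    def test_requires_two_samples(self):
        counts = _counts([{"exon_id": "A", "sample": "t1", "UJC": 1, "DJC": 1, "SJC": 1}])
        with pytest.raises(ValueError):
            differential_splicing_standin(counts, [("t1", "t2")])


class TestCombineLists:
    def test_union_semantics(self):
        a = [f"x{i}" for i in range(48)]
        b = a[:23] + [f"y{i}" for i in range(4)]
        assert len(combine_lists(a, b)) == 52

    def test_disjoint_and_idempotent(self):
        assert len(combine_lists(["a", "b", "c"], ["d", "e", "f", "g"])) == 7
        assert combine_lists(["a", "b"], ["a", "b"]) == ["a", "b"]

    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    @settings(max_examples=50, deadline=None)
    def test_inclusion_exclusion(self, a, b):
        sa = {str(x) for x in a}
        sb = {str(x) for x in b}
        assert len(combine_lists(sa, sb)) == len(sa) + len(sb) - len(sa & sb)
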