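"""Alu-exon identification, region placement, ORF construction, NMD fate."""

import numpy as np
import pytest

from aluexon import (
    GenomeSequence,
    PtcClass,
    RegionClass,
    RepeatAnnotation,
    TranscriptModel,
    classify_exon_region,
    classify_ptc,
    build_inclusion_orf,
    find_alu_exons,
    frame_divisibility_test,
    subfamily_fraction,
)
from aluexon.annotation import NonCodingTranscriptError, last_junction_mrna_position
from aluexon.models import AluExonRecord, OrfResult


def _tx(exons, strand="+", cds=None, chrom="c1", tid="T"):
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(gene_id="G", transcript_id=tid, chrom=chrom,
                           strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end)


def _rep(start, end, chrom="c1", name="AluSx"):
    return RepeatAnnotation(chrom=chrom, start=start, end=end, strand="+",
                            name=name, family="SINE/Alu")


class TestFindAluExons:
    def test_overlap_thresholds(self):
        # internal exon length 100 at [200, 300)
        tx = _tx([(0, 100), (200, 300), (400, 500)])
        assert len(find_alu_exons([tx], [_rep(200, 260)])) == 1   # 60 bp, 60%
        assert len(find_alu_exons([tx], [_rep(200, 250)])) == 0   # 50 bp = 50%, not >50%
        assert len(find_alu_exons([tx], [_rep(150, 276)])) == 1   # 76 bp of the exon

    def test_bp_floor_applies_even_with_high_fraction(self):
        tx = _tx([(0, 100), (200, 240), (400, 500)])  # internal exon 40 bp
        assert len(find_alu_exons([tx], [_rep(200, 224)])) == 0   # 24 bp, fraction 0.6

    def test_terminal_exons_excluded(self):
        tx = _tx([(0, 100), (200, 300), (400, 500)])
        assert len(find_alu_exons([tx], [_rep(0, 100)])) == 0
        assert len(find_alu_exons([tx], [_rep(400, 500)])) == 0

    def test_largest_single_repeat_governs(self):
        # two repeats over one 100-bp exon: 30 bp and 45 bp; neither >50%
        tx = _tx([(0, 100), (200, 300), (400, 500)])
        reps = [_rep(200, 230, name="AluY"), _rep(255, 300, name="AluJb")]
        assert find_alu_exons([tx], reps) == []
        # the larger one alone crossing 51%: record carries its subfamily
        reps = [_rep(200, 230, name="AluY"), _rep(245, 300, name="AluJb")]
        recs = find_alu_exons([tx], reps)
        assert len(recs) == 1 and recs[0].subfamily == "AluJb" and recs[0].overlap_bp == 55

    def test_disjoint_chromosome_names_rejected(self):
        tx = _tx([(0, 100), (200, 300), (400, 500)], chrom="chr1")
        with pytest.raises(ValueError, match="chromosome"):
            find_alu_exons([tx], [_rep(200, 260, chrom="1")])

    def test_matches_bruteforce_oracle_on_random_layouts(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n_exons = rng.integers(3, 7)
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), n_exons, replace=False))
            exons = [(int(s), int(s + rng.integers(30, 200))) for s in starts]
            exons = [(s, e) for (s, e) in exons]
            # enforce non-overlap
            fixed = []
            last = -1
            for s, e in exons:
                s = max(s, last + 1)
                e = max(e, s + 30)
                fixed.append((s, e))
                last = e
            tx = _tx(fixed, tid=f"T{trial}")
            reps = [_rep(int(s), int(s + rng.integers(25, 350)))
                    for s in rng.choice(np.arange(0, 5200, 7), rng.integers(1, 6), replace=False)]
            got = {(r.start, r.end) for r in find_alu_exons([tx], reps)}
            expect = set()
            for (s, e) in fixed[1:-1]:
                best = max((min(e, r.end) - max(s, r.start) for r in reps), default=0)
                if best >= 25 and best / (e - s) > 0.5:
                    expect.add((s, e))
            assert got == expect

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            AluExonRecord(chrom="c", start=0, end=100, transcript_id="T", gene_id="G",
                          strand="+", overlap_bp=24, overlap_fraction=0.9, subfamily="AluY")
        with pytest.raises(ValueError):
            AluExonRecord(chrom="c", start=0, end=100, transcript_id="T", gene_id="G",
                          strand="+", overlap_bp=50, overlap_fraction=0.5, subfamily="AluY")


class TestRegionClassification:
    tx_plus = _tx([(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)],
                  cds=(250, 850))

    def test_partition(self):
        assert classify_exon_region((400, 500), self.tx_plus) is RegionClass.CDS
        assert classify_exon_region((0, 100), self.tx_plus) is RegionClass.FIVE_UTR
        assert classify_exon_region((860, 880), self.tx_plus) is RegionClass.THREE_UTR

    def test_any_cds_overlap_counts_as_cds(self):
        assert classify_exon_region((200, 260), self.tx_plus) is RegionClass.CDS

    def test_minus_strand_flips_utr_sides(self):
        tx = _tx([(0, 100), (200, 300), (400, 500)], strand="-", cds=(210, 450))
        assert classify_exon_region((0, 100), tx) is RegionClass.THREE_UTR
        assert classify_exon_region((460, 500), tx) is RegionClass.FIVE_UTR

    def test_non_coding_transcript_signalled(self):
        tx = _tx([(0, 100), (200, 300), (400, 500)])
        with pytest.raises(NonCodingTranscriptError):
            classify_exon_region((200, 300), tx)


class TestInclusionOrf:
    def test_toy_translation(self, toy_gene):
        genome, tx, cassette = toy_gene
        orf = build_inclusion_orf(tx, cassette, genome)
        assert orf.mrna == "ATGGCAGCAGCAGCATAA"
        assert orf.protein == "MAAAA"
        assert orf.stop_mrna == 18
        assert not orf.stop_lost
        assert orf.exon_aa_span == (2, 4)

    def test_minus_strand_translation_identical(self, toy_gene_minus):
        genome, tx, cassette = toy_gene_minus
        orf = build_inclusion_orf(tx, cassette, genome)
        assert orf.protein == "MAAAA"
        assert orf.exon_aa_span == (2, 4)

    def test_in_frame_insertion_preserves_downstream(self, sim_bundle):
        from aluexon.annotation import translate_annotated, splice_in_exon

        cfg, sim = sim_bundle
        by_tx = {t.transcript_id: t for t in sim.transcripts}
        done = 0
        for ev in sim.truth:
            if ev.event_type != "coding" or ev.ptc != "NON_PTC":
                continue
            tx = by_tx[ev.transcript_id]
            orf = build_inclusion_orf(tx, (ev.start, ev.end), sim.genome)
            a, b = orf.exon_aa_span
            skipping_tx = TranscriptModel(
                gene_id=tx.gene_id, transcript_id=tx.transcript_id, chrom=tx.chrom,
                strand=tx.strand, exons=[e for e in tx.exons if e != (ev.start, ev.end)],
                cds_start=tx.cds_start, cds_end=tx.cds_end)
            skipping = translate_annotated(skipping_tx, sim.genome)
            assert orf.protein[:a] == skipping[:a]
            assert orf.protein[b:] == skipping[a:]
            done += 1
        assert done >= 3

    def test_frameshift_changes_downstream_frame(self):
        # 4-nt cassette shifts everything downstream by one base
        seq = "ATGGCA" + "GTAG" + "GCAG" + "GTAG" + "GCATAAA" + "AC"
        genome = GenomeSequence({"c": seq})
        tx = _tx([(0, 6), (18, 25)], cds=(0, 25), chrom="c")
        orf = build_inclusion_orf(tx, (10, 14), genome)
        assert orf.mrna == "ATGGCAGCAGGCATAAA"
        # codons: ATG GCA GCA GGC ATA AA -> no stop in frame until runs out
        assert orf.protein.startswith("MAAG")


class TestPtcRule:
    def _orf(self, stop):
        return OrfResult(mrna="N" * 300, orf_nt="", protein="M", start_mrna=0, stop_mrna=stop)

    tx = _tx([(0, 100), (200, 300), (400, 500)], cds=(0, 450))

    def test_50nt_boundary_is_strict(self):
        # mRNA: 300 nt, last junction at 200
        assert classify_ptc(self._orf(149), self.tx) is PtcClass.PTC       # 51 nt upstream
        assert classify_ptc(self._orf(150), self.tx) is PtcClass.NON_PTC   # exactly 50
        assert classify_ptc(self._orf(250), self.tx) is PtcClass.NON_PTC   # in last exon

    def test_stop_lost_is_non_ptc_with_warning(self):
        orf = OrfResult(mrna="", orf_nt="", protein="M", start_mrna=0,
                        stop_mrna=None, stop_lost=True)
        with pytest.warns(UserWarning):
            assert classify_ptc(orf, self.tx) is PtcClass.NON_PTC

    def test_invariant_to_added_5utr_exons(self):
        tx1 = _tx([(100, 200), (300, 400), (500, 600)], cds=(100, 550))
        tx2 = _tx([(0, 50), (100, 200), (300, 400), (500, 600)], cds=(100, 550))
        shift = 50
        for stop in (120, 149, 150, 151, 250):
            c1 = classify_ptc(self._orf(stop), tx1)
            c2 = classify_ptc(self._orf(stop + shift), tx2)
            assert c1 is c2

    def test_last_junction_position(self):
        assert last_junction_mrna_position(self.tx) == 200
        tx_minus = _tx([(0, 100), (200, 300), (400, 500)], strand="-", cds=(50, 500))
        # sense order reversed: last exon is (0, 100)
        assert last_junction_mrna_position(tx_minus) == 200


class TestSetStatistics:
    def _records(self, n_div, n_total):
        recs = []
        for i in range(n_total):
            length = 99 if i < n_div else 100
            recs.append(AluExonRecord(
                chrom="c", start=1000 * i, end=1000 * i + length, transcript_id=f"T{i}",
                gene_id="G", strand="+", overlap_bp=90, overlap_fraction=0.9,
                subfamily="AluY" if i % 2 else "AluSx"))
        return recs

    def test_reading_frame_preservation_contrast(self):
        counts, fractions, p = frame_divisibility_test(
            self._records(182, 262), self._records(159, 649))
        assert counts["coding_divisible"] == 182 and counts["nmd_total"] == 649
        assert fractions["coding"] == pytest.approx(182 / 262)
        assert p == pytest.approx(2e-36, rel=0.5)

    def test_proportional_table_not_significant(self):
        _, _, p = frame_divisibility_test(self._records(10, 20), self._records(20, 40))
        assert p == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            frame_divisibility_test([], self._records(1, 2))

    def test_subfamily_fraction(self):
        recs = self._records(0, 6)
        n, frac = subfamily_fraction(recs, "AluY")
        assert (n, frac) == (3, 0.5)
        assert subfamily_fraction(recs, "AluJb") == (0, 0.0)
        with pytest.raises(ValueError):
            subfamily_fraction([], "AluY")
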