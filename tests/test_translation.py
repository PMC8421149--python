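"""Ribo-Seq gates: RPF counting, 3'-end offset calibration, A-site profiles."""

import numpy as np
import pytest

from smorfer.io import AlignedRead, GeneFeature, OrfCandidate
from smorfer.simulate import FixtureSpec, make_genome, make_ribo_reads
from smorfer.translation import (OffsetTable, TranslationThresholds,
                                 a_site_position, a_site_vector,
                                 calibrate_offsets, calibrated_profile,
                                 classify_3nt_translated, count_rpfs)


def _orf(start=100, end=130, strand="+"):
    return OrfCandidate("c", strand, start, end, "ATG", "TAA")


class TestCountRpfs:
    def test_strand_specific_any_overlap(self):
        orf = _orf()
        reads = [AlignedRead("c", "+", 95, 123),
                 AlignedRead("c", "+", 110, 138),
                 AlignedRead("c", "-", 110, 138)]
        count_rpfs([orf], reads)
        assert orf.rpf_count == 2

    def test_rpk_arithmetic(self):
        orf = OrfCandidate("c", "+", 0, 150, "ATG", "TAA")
        reads = [AlignedRead("c", "+", 10 + i, 38 + i) for i in range(15)]
        count_rpfs([orf], reads)
        assert orf.rpk == pytest.approx(100.0)

    def test_translated_gate(self):
        orf = _orf()
        reads = [AlignedRead("c", "+", 100 + i, 128 + i) for i in range(5)]
        count_rpfs([orf], reads, TranslationThresholds())
        assert orf.category == "translated"
        orf2 = _orf()
        count_rpfs([orf2], reads[:4], TranslationThresholds())
        assert orf2.category == "putative"

    def test_boundary_overlap_counts(self):
        orf = _orf(100, 130)
        # one shared nt at each side counts; zero-overlap neighbours do not
        reads = [AlignedRead("c", "+", 72, 101), AlignedRead("c", "+", 129, 157),
                 AlignedRead("c", "+", 72, 100), AlignedRead("c", "+", 130, 158)]
        count_rpfs([orf], reads)
        assert orf.rpf_count == 2

    def test_monotone_in_reads(self):
        orf = _orf()
        rng = np.random.default_rng(0)
        reads = [AlignedRead("c", "+", int(s), int(s) + 28)
                 for s in rng.integers(0, 300, size=60)]
        counts = []
        for k in (10, 30, 60):
            o = _orf()
            count_rpfs([o], reads[:k])
            counts.append(o.rpf_count)
        assert counts == sorted(counts)


class TestCalibration:
    def _reads_with_offset(self, anchors, offset, length, n_per, strand="+"):
        reads = []
        for a in anchors:
            for _ in range(n_per):
                if strand == "+":
                    g3 = a + offset
                    reads.append(AlignedRead("c", "+", g3 - length + 1, g3 + 1))
                else:
                    g3 = a - offset
                    reads.append(AlignedRead("c", "-", g3, g3 + length))
        return reads

    def test_planted_offset_recovered(self):
        stops = [GeneFeature("c", "+", 1000 * i, 1000 * i + 300, "CDS", f"g{i}")
                 for i in range(1, 5)]
        anchors = [f.end - 3 for f in stops]
        reads = self._reads_with_offset(anchors, 11, 28, 20)
        table = calibrate_offsets(reads, stops, [28])
        assert table.entries == {28: 11}

    def test_reverse_strand_offset_recovered(self):
        stops = [GeneFeature("c", "-", 1000 * i, 1000 * i + 300, "CDS", f"g{i}")
                 for i in range(1, 5)]
        anchors = [f.start + 2 for f in stops]
        reads = self._reads_with_offset(anchors, 12, 29, 20, strand="-")
        table = calibrate_offsets(reads, stops, [29])
        assert table.entries == {29: 12}

    def test_ambiguous_bin_excluded(self):
        stops = [GeneFeature("c", "+", 1000, 1300, "CDS", "g")]
        anchor = 1297
        good = self._reads_with_offset([anchor], 11, 28, 30)
        # second bin: flat two-peak histogram -> uncalibrated
        flat = (self._reads_with_offset([anchor], 8, 27, 10)
                + self._reads_with_offset([anchor], 14, 27, 10))
        with pytest.warns(UserWarning, match="ambiguous"):
            table = calibrate_offsets(good + flat, stops, [27, 28])
        assert table.entries == {28: 11}

    def test_no_stops_errors(self):
        with pytest.raises(ValueError, match="annotated stop"):
            calibrate_offsets([], [], [28])

    def test_offset_table_validation(self):
        with pytest.raises(ValueError):
            OffsetTable({28: 30})
        with pytest.raises(ValueError):
            OffsetTable({})


class TestASiteProfiles:
    def test_forward_arithmetic(self):
        # 3' end 126, offset 11 -> A-site nt 115 -> in-ORF 15 -> codon 5
        orf = _orf(100, 130, "+")
        read = AlignedRead("c", "+", 99, 127)
        table = OffsetTable({28: 11})
        assert a_site_position(read, table) == 115
        prof = calibrated_profile(orf, [read], table)
        assert prof.counts.tolist() == [0, 0, 0, 0, 0, 1, 0, 0, 0, 0]

    def test_reverse_arithmetic(self):
        # 3' end at genomic 100, offset 11 -> A-site nt 111
        orf = _orf(100, 130, "-")
        read = AlignedRead("c", "-", 100, 128)
        table = OffsetTable({28: 11})
        assert a_site_position(read, table) == 111
        # in-ORF position along translation direction: (end-1) - 111 = 18
        prof = calibrated_profile(orf, [read], table)
        assert prof.counts.tolist() == [0, 0, 0, 0, 0, 0, 1, 0, 0, 0]

    def test_uncalibrated_length_skipped(self):
        orf = _orf()
        read = AlignedRead("c", "+", 99, 130)  # length 31, not in table
        vec = a_site_vector(orf, [read], OffsetTable({28: 11}))
        assert vec.sum() == 0

    def test_count_conservation_on_simulated_reads(self):
        spec = FixtureSpec(seed=5, frame_noise=0.0)
        record, feats, truth = make_genome(spec)
        reads = make_ribo_reads(truth, spec, record.length)
        table = OffsetTable(dict(spec.true_offset_by_length))
        for p in truth.planted[:8]:
            orf = OrfCandidate(p.seq_id, p.strand, p.start, p.end,
                               p.start_codon, "TAA")
            prof = calibrated_profile(orf, reads, table)
            expected = [r for r in truth.read_a_site_codons
                        if tuple(r["orf"]) == orf.key]
            assert prof.total == len(expected)
            # noise-free round trip: planted per-codon counts reproduced
            planted_counts = np.zeros(orf.length_nt // 3, int)
            for r in expected:
                planted_counts[r["codon"]] += 1
            assert prof.counts.tolist() == planted_counts.tolist()


class TestClassify:
    def _scored_orf(self, vec, rpf=50, L=90):
        orf = OrfCandidate("c", "+", 0, L, "ATG", "TAA",
                           rpf_count=rpf, rpk=rpf * 1000 / L,
                           category="translated")
        classify_3nt_translated([orf], {orf.key: vec})
        return orf

    def test_in_frame_signal_promotes(self):
        vec = np.zeros(90)
        vec[::3] = 5
        orf = self._scored_orf(vec)
        assert orf.rpf_ft_score > 2 and orf.category == "3nt_translated"

    def test_shuffled_signal_does_not(self):
        rng = np.random.default_rng(9)
        vec = np.zeros(90)
        vec[::3] = 5
        rng.shuffle(vec)
        orf = self._scored_orf(vec)
        assert orf.category == "translated" and orf.rpf_ft_score < 2

    def test_rpk_gate_blocks_scoring(self):
        vec = np.zeros(90)
        vec[::3] = 5
        orf = OrfCandidate("c", "+", 0, 90, "ATG", "TAA",
                           rpf_count=8, rpk=99.9, category="translated")
        classify_3nt_translated([orf], {orf.key: vec})
        assert orf.rpf_ft_score is None and orf.category == "translated"

    def test_category_nesting(self):
        """Every 3nt_translated candidate also satisfies the translated gate."""
        vec = np.zeros(90)
        vec[::3] = 5
        orf = self._scored_orf(vec)
        thr = TranslationThresholds()
        assert orf.category == "3nt_translated"
        assert orf.rpf_count >= thr.min_rpf and orf.rpk >= thr.min_rpk
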