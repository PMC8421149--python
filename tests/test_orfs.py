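"""Putative-ORF enumeration against an independent six-frame oracle."""

import numpy as np
import pytest

from smorfer.io import GeneFeature, GenomeRecord, OrfCandidate
from smorfer.orfs import (OrfConfig, filter_unannotated, find_long_orfs,
                          find_orfs, group_by_stop)

STARTS = {"ATG", "GTG", "TTG", "CTG"}
STOPS = {"TGA", "TAG", "TAA"}
COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s):
    return s.translate(COMP)[::-1]


def oracle_orfs(seq, min_len=9, max_len=150):
    """Brute force: from every start codon, walk codons to the first in-frame
    stop; codons containing N kill the walk.  Returns {(start, end, strand)}
    in genomic coordinates."""
    n = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - 2):
            if s[i:i + 3] not in STARTS:
                continue
            j, stop_at = i + 3, None
            while j + 3 <= n:
                codon = s[j:j + 3]
                if "N" in codon:
                    break
                if codon in STOPS:
                    stop_at = j
                    break
                j += 3
            if stop_at is None:
                continue
            length = stop_at + 3 - i
            if min_len <= length <= max_len:
                if strand == "+":
                    found.add((i, stop_at + 3, "+"))
                else:
                    found.add((n - (stop_at + 3), n - i, "-"))
    return found


def random_dna(rng, n, with_n=0.0):
    bases = "ACGT" + ("N" if with_n else "")
    p = [0.25, 0.25, 0.25, 0.25]
    if with_n:
        p = [0.25 * (1 - with_n)] * 4 + [with_n]
    return "".join(rng.choice(list(bases), size=n, p=p))


class TestFindOrfs:
    def test_smallest_construct(self):
        g = GenomeRecord("c", "ATGAAATAA")
        orfs = find_orfs(g, OrfConfig())
        plus = [o for o in orfs if o.strand == "+"]
        assert len(plus) == 1
        o = plus[0]
        assert (o.start, o.end, o.start_codon, o.stop_codon, o.length_nt) == \
            (0, 9, "ATG", "TAA", 9)

    def test_nested_starts_share_stop(self):
        # oracle on this 12-mer: ATG..TAA (len 12) and GTG..TAA (len 9), + only
        g = GenomeRecord("c", "ATGGTGAAATAA")
        orfs = find_orfs(g, OrfConfig())
        got = {(o.start, o.end, o.strand) for o in orfs}
        assert got == oracle_orfs("ATGGTGAAATAA") == {(0, 12, "+"), (3, 12, "+")}
        assert len({o.stop_key for o in orfs}) == 1

    def test_n_codon_aborts_scan(self):
        # start ... N-containing codon ... stop: no ORF may bridge the N
        g = GenomeRecord("c", "ATGAANAAATAA")
        assert all(o.strand == "-" or "N" not in
                   g.sequence[o.start:o.end] for o in find_orfs(g, OrfConfig()))
        got = {(o.start, o.end, o.strand) for o in find_orfs(g, OrfConfig())}
        assert got == oracle_orfs(g.sequence)

    def test_internal_stop_free_and_reextraction(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 1500)
        g = GenomeRecord("c", seq)
        for o in find_orfs(g, OrfConfig()):
            sub = seq[o.start:o.end]
            if o.strand == "-":
                sub = revcomp(sub)
            codons = [sub[k:k + 3] for k in range(0, len(sub), 3)]
            assert codons[0] == o.start_codon in STARTS
            assert codons[-1] == o.stop_codon in STOPS
            assert not any(c in STOPS for c in codons[:-1])

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_with_n(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 600, with_n=0.02)
        g = GenomeRecord("c", seq)
        got = {(o.start, o.end, o.strand) for o in find_orfs(g, OrfConfig())}
        assert got == oracle_orfs(seq)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 900)
        n = len(seq)
        fwd = find_orfs(GenomeRecord("c", seq), OrfConfig())
        rev = find_orfs(GenomeRecord("c", revcomp(seq)), OrfConfig())
        minus = {(n - o.end, n - o.start) for o in fwd if o.strand == "-"}
        plus_of_rc = {(o.start, o.end) for o in rev if o.strand == "+"}
        assert minus == plus_of_rc

    def test_empty_genome(self):
        assert find_orfs(GenomeRecord("c", ""), OrfConfig()) == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OrfConfig(min_len_nt=8)
        with pytest.raises(ValueError):
            OrfConfig(min_len_nt=12, max_len_nt=10)


class TestLongOrfs:
    def test_planted_long_orf_recovered(self):
        rng = np.random.default_rng(3)
        ncod = 400  # 1200 nt
        internal = []
        while len(internal) < ncod - 2:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if c not in STOPS:
                internal.append(c)
        orf = "ATG" + "".join(internal) + "TAA"
        seq = random_dna(rng, 900) + orf + random_dna(rng, 900)
        long_orfs = find_long_orfs(GenomeRecord("c", seq), 1000)
        spans = {(o.start, o.end, o.strand) for o in long_orfs}
        assert (900, 900 + 1200, "+") in spans
        assert all(o.length_nt > 1000 for o in long_orfs)

    def test_short_genome_empty(self):
        g = GenomeRecord("c", "ATG" + "AAA" * 100 + "TAA")
        assert find_long_orfs(g, 1000) == []


class TestAnnotationFilter:
    def _orf(self, start, end, strand="+"):
        return OrfCandidate("chr", strand, start, end, "ATG", "TAA")

    def test_half_open_boundary_kept(self):
        orf = self._orf(100, 130)
        feat = GeneFeature("chr", "+", 130, 200)
        assert filter_unannotated([orf], [feat]) == [orf]
        assert orf.in_annotated_region is False

    def test_one_nt_overlap_removed(self):
        orf = self._orf(100, 130)
        feat = GeneFeature("chr", "+", 129, 200)
        assert filter_unannotated([orf], [feat]) == []
        assert orf.in_annotated_region is True

    def test_stranded_mode_ignores_opposite_strand(self):
        orf = self._orf(100, 130, "-")
        feat = GeneFeature("chr", "+", 90, 200)
        assert filter_unannotated([orf], [feat], stranded=True) == [orf]
        assert filter_unannotated([orf], [feat], stranded=False) == []

    def test_seq_id_mismatch_errors(self):
        orf = self._orf(100, 130)
        feat = GeneFeature("other", "+", 0, 50)
        with pytest.raises(ValueError, match="other"):
            filter_unannotated([orf], [feat])

    def test_against_bruteforce_overlap(self):
        rng = np.random.default_rng(5)
        orfs = [self._orf(int(s), int(s) + 30) for s in
                rng.integers(0, 5000, size=200)]
        feats = [GeneFeature("chr", "+", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 5000, size=40),
                                 rng.integers(10, 400, size=40))]
        kept = {o.key for o in filter_unannotated(list(orfs), feats)}
        expect = {o.key for o in orfs
                  if not any(f.start < o.end and f.end > o.start for f in feats)}
        assert kept == expect


class TestGroupByStop:
    def test_grouping_and_ordering(self):
        a = OrfCandidate("c", "+", 0, 30, "ATG", "TAA")
        b = OrfCandidate("c", "+", 9, 30, "GTG", "TAA")
        c = OrfCandidate("c", "+", 40, 70, "ATG", "TGA")
        groups = group_by_stop([b, a, c])
        assert len(groups) == 2
        g = groups[a.stop_key]
        assert [o.length_nt for o in g] == [30, 21]  # longest first

    def test_key_count_bound(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        orfs = find_orfs(GenomeRecord("c", seq), OrfConfig())
        groups = group_by_stop(orfs)
        assert len(groups) <= len(orfs)
        sharing = any(len(g) > 1 for g in groups.values())
        assert (len(groups) < len(orfs)) == sharing


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.text(alphabet="ACGTN", min_size=30, max_size=250))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_scanner_matches_oracle_on_arbitrary_dna(seq):
    """Hypothesis-driven cross-check of the scanner against the brute-force
    oracle, including N-rich and degenerate sequences."""
    got = {(o.start, o.end, o.strand)
           for o in find_orfs(GenomeRecord("c", seq), OrfConfig())}
    assert got == oracle_orfs(seq)
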