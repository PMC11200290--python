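"""The missing-region k-mer filter: substring counting, the discard
rule, alignment-based ground truth, and sensitivity/specificity."""

import pytest

from kmerphylo import (
    AlignmentBlock,
    FilterConfig,
    KmerCountTable,
    SequenceRecord,
    candidate_kmers,
    canonical,
    count_kmers,
    filter_kmers,
    label_by_alignment,
    missing_substring_count,
    sensitivity_specificity,
    substring_length,
)
from kmerphylo.filtering import FilterReport

from conftest import random_dna


class TestSubstringLength:
    @pytest.mark.parametrize(
        "K,k", [(16, 13), (9, 8), (10, 8), (13, 11), (19, 16), (15, 12)]
    )
    def test_published_pairs(self, K, k):
        assert substring_length(K) == k

    def test_floor_clamp(self):
        assert substring_length(7) == 7
        assert substring_length(5) == 7

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            substring_length(0)


class TestFilterConfig:
    def test_default_substring_length_and_m(self):
        config = FilterConfig(K=16)
        assert config.k == 13
        assert config.m == 4

    def test_substring_not_shorter_than_K_rejected(self):
        with pytest.raises(ValueError, match="strictly smaller"):
            FilterConfig(K=9, k=9)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="Th"):
            FilterConfig(K=16, k=13, Th=0)


class TestCandidateKmers:
    def test_identical_tables_empty(self):
        t = KmerCountTable(K=3, counts={"A": {"AAA": 1}, "B": {"AAA": 2}})
        assert candidate_kmers(t) == set()

    def test_disjoint_tables_all_candidates(self):
        t = KmerCountTable(K=3, counts={"A": {"AAA": 1}, "B": {"AAC": 1}})
        assert candidate_kmers(t) == {"AAA", "AAC"}

    def test_set_algebra_oracle(self, rng):
        counts = {
            sp: {canonical(random_dna(rng, 5)): 1 for _ in range(30)}
            for sp in ("A", "B", "C")
        }
        t = KmerCountTable(K=5, counts=counts)
        union = set().union(*counts.values())
        inter = set.intersection(*map(set, counts.values()))
        assert len(candidate_kmers(t)) == len(union) - len(inter)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            candidate_kmers(KmerCountTable(K=3, counts={"A": {"AAA": 1}}))


class TestMissingSubstringCount:
    def test_full_kmer_present_means_zero(self):
        seq = "ACGTACGTA"
        sub = count_kmers([SequenceRecord("B", seq)], 8).counts["B"]
        assert missing_substring_count(seq, sub, 8) == 0

    def test_no_shared_substring_means_m(self):
        sub = count_kmers([SequenceRecord("B", "T" * 30)], 8).counts["B"]
        assert missing_substring_count("ACGCCGTAC", sub, 8) == 2  # m = 9-8+1

    def test_toy_single_absent_window(self):
        # B contains ACGTACGT (first window) but not CGTACGTA (second)
        kmer = "ACGTACGTA"
        b_seq = "ACGTACGTT" + "G" * 20
        sub = count_kmers([SequenceRecord("B", b_seq)], 8).counts["B"]
        assert canonical("ACGTACGT") in sub
        assert canonical("CGTACGTA") not in sub
        assert missing_substring_count(kmer, sub, 8) == 1

    def test_substring_length_must_be_shorter(self):
        with pytest.raises(ValueError):
            missing_substring_count("ACGT", {}, 4)


def _tables_for(seqs: dict[str, str], K: int, k: int):
    records = [SequenceRecord(sp, s) for sp, s in seqs.items()]
    return count_kmers(records, K), count_kmers(records, k)


class TestFilterKmers:
    def test_region_deletion_discards(self, rng):
        """A k-mer whose whole neighbourhood is absent from one species
        (both substrings missing) is attributed to a missing region."""
        a = random_dna(rng, 200)
        kmer = a[50:59]
        b = a[:30] + a[90:]  # B lacks the region around positions 50-59
        tables, sub = _tables_for({"A": a, "B": b}, 9, 8)
        assert canonical(kmer) not in tables.counts["B"]
        filtered, report = filter_kmers(tables, sub, FilterConfig(K=9, k=8, Th=2))
        assert canonical(kmer) in report.discarded
        assert canonical(kmer) not in filtered.counts["A"]

    def test_boundary_missing_count_is_kept(self):
        """With m = 2 and Th = 2 the cutoff is m/Th = 1: exactly one
        missing substring (the m/2 boundary) is not enough to discard."""
        a = "ACGTACGTA" + "G" * 40
        b = "ACGTACGTT" + "G" * 40  # one terminal substitution
        tables, sub = _tables_for({"A": a, "B": b}, 9, 8)
        target = canonical("ACGTACGTA")
        assert target not in tables.counts["B"]
        filtered, report = filter_kmers(tables, sub, FilterConfig(K=9, k=8, Th=2))
        assert report.missing_counts[target] == 1
        assert target not in report.discarded
        assert filtered.counts["A"][target] == tables.counts["A"][target]

    def test_kmers_present_everywhere_never_candidates(self, rng):
        seq = random_dna(rng, 100)
        tables, sub = _tables_for({"A": seq, "B": seq}, 9, 8)
        _, report = filter_kmers(tables, sub, FilterConfig(K=9, k=8, Th=2))
        assert report.candidates == set()
        assert report.discarded == set()

    def test_filtered_tables_subset_with_unchanged_counts(self, rng):
        seqs = {sp: random_dna(rng, 150) for sp in "ABC"}
        tables, sub = _tables_for(seqs, 9, 8)
        filtered, report = filter_kmers(tables, sub, FilterConfig(K=9, k=8, Th=2))
        for sp in seqs:
            assert set(filtered.counts[sp]) <= set(tables.counts[sp])
            for kmer, c in filtered.counts[sp].items():
                assert c == tables.counts[sp][kmer]
            assert set(tables.counts[sp]) - set(filtered.counts[sp]) <= report.discarded

    def test_monotone_in_threshold(self, rng):
        """Raising Th lowers the cutoff m/Th, so the discarded set can
        only grow."""
        seqs = {sp: random_dna(rng, 300) for sp in "AB"}
        tables, sub = _tables_for(seqs, 12, 9)
        previous: set[str] = set()
        for th in (1.0, 2.0, 4.0):
            _, report = filter_kmers(tables, sub, FilterConfig(K=12, k=9, Th=th))
            assert previous <= report.discarded
            previous = report.discarded

    def test_mismatched_substring_table_length_rejected(self, rng):
        seqs = {sp: random_dna(rng, 60) for sp in "AB"}
        tables, sub = _tables_for(seqs, 9, 7)
        with pytest.raises(ValueError, match="substring tables"):
            filter_kmers(tables, sub, FilterConfig(K=9, k=8, Th=2))


class TestLabelByAlignment:
    def test_gapped_region_labels_missing(self):
        block = AlignmentBlock({"A": "ACGTACGT", "B": "ACG----T"})
        labels = label_by_alignment(block, K=6)
        # A's first 6-mer spans columns 0-5 where B has 3 gaps; 3 > 6/3
        assert "B" in labels.get(canonical("ACGTAC"), set())

    def test_no_gaps_not_labelled(self):
        block = AlignmentBlock({"A": "ACGTACGT", "B": "ACGTACGT"})
        assert label_by_alignment(block, K=6) == {}

    def test_gap_count_equal_to_third_is_not_missing(self):
        # B has exactly 2 gaps in A's first 6-mer span: 2 > 6/3 is false
        block = AlignmentBlock({"A": "ACGTACGT", "B": "AC--ACGT"})
        labels = label_by_alignment(block, K=6)
        assert canonical("ACGTAC") not in labels


class TestSensitivitySpecificity:
    def test_arithmetic(self):
        labels = {f"m{i}": {"B"} for i in range(50)}
        report = FilterReport(config=FilterConfig(K=16))
        report.candidates = set(labels) | {f"x{i}" for i in range(10)}
        report.discarded = {f"m{i}" for i in range(39)}
        sens, spec = sensitivity_specificity(labels, report)
        assert sens == pytest.approx(78.0)
        assert spec == pytest.approx(100.0)

    def test_everything_kept(self):
        labels = {"m1": {"B"}}
        report = FilterReport(config=FilterConfig(K=16))
        report.candidates = {"m1", "x1"}
        sens, spec = sensitivity_specificity(labels, report)
        assert sens == 0.0
        assert spec == 100.0
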