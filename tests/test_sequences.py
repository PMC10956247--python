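from collections import Counter

import numpy as np
import pytest

from gnnmotif.sequences import (
    GenomicInterval,
    SequenceRecord,
    SequenceSet,
    build_vocabulary,
    extract_kmers,
    make_negative,
    prepare_corpus,
    rank_and_intersect_footprints,
    split_dataset,
    trim_footprint,
)
from oracle_utils import kmer_sets, random_dna


class TestTrimFootprint:
    def test_default_flank_gives_101bp_window_on_center(self):
        iv = trim_footprint(GenomicInterval("chr1", 990, 1010), flank=50)
        assert (iv.start, iv.end) == (950, 1050)
        assert iv.length == 101

    def test_single_base_footprint_centers_on_itself(self):
        iv = trim_footprint(GenomicInterval("chr1", 500, 500), flank=50)
        assert (iv.start, iv.end) == (450, 550)

    def test_zero_flank_degenerates_to_center_base(self):
        iv = trim_footprint(GenomicInterval("chr1", 100, 101), flank=0)
        assert (iv.start, iv.end) == (100, 100)

    def test_window_off_contig_is_skipped(self):
        assert trim_footprint(GenomicInterval("chr1", 10, 12), flank=50) is None
        assert trim_footprint(GenomicInterval("chr1", 90, 95),
                              flank=50, contig_length=100) is None


class TestRankAndIntersect:
    def test_truncates_to_top_n_by_score(self):
        primary = [GenomicInterval("c", 10 * i, 10 * i + 5, score=i)
                   for i in range(5)]
        secondary = [GenomicInterval("c", 0, 100)]
        kept = rank_and_intersect_footprints(primary, secondary, top_n=3)
        assert [iv.score for iv in kept] == [4, 3, 2]

    def test_no_overlap_yields_empty(self):
        primary = [GenomicInterval("c", 1, 5, score=1.0)]
        secondary = [GenomicInterval("c", 50, 60)]
        assert rank_and_intersect_footprints(primary, secondary) == []

    def test_score_ties_broken_by_contig_then_start(self):
        primary = [
            GenomicInterval("chr2", 30, 35, score=7.0),
            GenomicInterval("chr1", 40, 45, score=7.0),
            GenomicInterval("chr1", 10, 15, score=7.0),
            GenomicInterval("chr1", 20, 25, score=9.0),
        ]
        secondary = [GenomicInterval("chr1", 1, 100),
                     GenomicInterval("chr2", 1, 100)]
        kept = rank_and_intersect_footprints(primary, secondary, top_n=3)
        assert [(iv.contig, iv.start) for iv in kept] == [
            ("chr1", 20), ("chr1", 10), ("chr1", 40)]

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            rank_and_intersect_footprints([GenomicInterval("c", 1, 5)], [])


class TestMakeNegative:
    def test_preserves_base_multiset(self):
        rec = SequenceRecord(id="p", bases="AAACCC", label=1)
        neg = make_negative(rec, np.random.default_rng(0))
        assert neg.label == 0
        assert Counter(neg.bases) == Counter("AAACCC")

    def test_homopolymer_is_fixed_point(self):
        rec = SequenceRecord(id="p", bases="AAAA", label=1)
        assert make_negative(rec, np.random.default_rng(0)).bases == "AAAA"

    def test_deterministic_under_seed(self):
        rec = SequenceRecord(id="p", bases="ACGTACGTAC", label=1)
        a = make_negative(rec, np.random.default_rng(7)).bases
        b = make_negative(rec, np.random.default_rng(7)).bases
        assert a == b

    def test_rejects_negative_input(self):
        rec = SequenceRecord(id="n", bases="ACGT", label=0)
        with pytest.raises(ValueError):
            make_negative(rec, np.random.default_rng(0))


def _paired_set(n_pairs):
    records = []
    rng = np.random.default_rng(0)
    for i in range(n_pairs):
        pos = SequenceRecord(id=f"p{i}", bases=random_dna(rng, 20), label=1)
        records.append(pos)
        records.append(make_negative(pos, rng))
    return SequenceSet(records)


class TestSplitDataset:
    @pytest.mark.parametrize("n_pairs,expect", [(100, (80, 10, 10)),
                                                (10, (8, 1, 1))])
    def test_split_sizes(self, n_pairs, expect):
        out = split_dataset(_paired_set(n_pairs), seed=3)
        pos = [r for r in out if r.label == 1]
        counts = Counter(r.split for r in pos)
        assert (counts["train"], counts["val"], counts["test"]) == expect

    def test_pairs_share_split(self):
        out = split_dataset(_paired_set(30), seed=1)
        split_of = {r.id: r.split for r in out}
        for r in out:
            if r.label == 0:
                assert r.split == split_of[r.paired_id]

    def test_deterministic(self):
        a = split_dataset(_paired_set(20), seed=9)
        b = split_dataset(_paired_set(20), seed=9)
        assert [r.split for r in a] == [r.split for r in b]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_paired_set(5))


class TestExtractKmers:
    def test_enumerates_all_windows_in_order(self):
        assert extract_kmers("ACGTAC", 5) == [("ACGTA", 1), ("CGTAC", 2)]

    def test_101bp_sequence_yields_97_fivemers(self):
        rng = np.random.default_rng(0)
        assert len(extract_kmers(random_dna(rng, 101), 5)) == 97

    def test_kmer_equal_to_sequence_length(self):
        assert extract_kmers("ACGT", 4) == [("ACGT", 1)]

    def test_too_short_sequence_gives_empty(self):
        assert extract_kmers("ACG", 5) == []


class TestBuildVocabulary:
    def test_duplicate_sequences_double_occurrence_counts(self):
        records = SequenceSet([SequenceRecord(id="a", bases="ACGTT"),
                               SequenceRecord(id="b", bases="ACGTT")])
        vocab = build_vocabulary(records, 3)
        assert (vocab.num() == 2).all()

    def test_homopolymer_positions_and_tf(self):
        vocab = build_vocabulary(
            SequenceSet([SequenceRecord(id="a", bases="AAAAAA")]), 5)
        assert vocab.kmers == ["AAAAA"]
        assert vocab.tf[0, 0] == 2
        assert vocab.starts(0, "AAAAA") == [1, 2]

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(4)
        seqs = [random_dna(rng, 15) for _ in range(10)]
        records = SequenceSet([SequenceRecord(id=str(i), bases=s)
                               for i, s in enumerate(seqs)])
        vocab = build_vocabulary(records, 3)
        kmers, sk, tf = kmer_sets(seqs, 3)
        assert vocab.kmers == kmers
        for k in kmers:
            assert vocab.sk(k) == sk[k]
            p = vocab.index[k]
            for i in range(10):
                assert vocab.tf[p, i] == tf.get((k, i), 0)

    def test_window_count_identity_and_symmetry(self):
        rng = np.random.default_rng(8)
        records = SequenceSet([SequenceRecord(id=str(i),
                                              bases=random_dna(rng, 25))
                               for i in range(6)])
        vocab = build_vocabulary(records, 4)
        # every window of every sequence counted exactly once
        assert (vocab.tf.sum(axis=0) == 25 - 4 + 1).all()
        nums = vocab.nums()
        assert (nums == nums.T).all()
        assert (np.diag(nums) == vocab.num()).all()


class TestPrepareCorpus:
    def test_interleaves_pairs_with_matched_composition(self):
        rng = np.random.default_rng(2)
        positives = SequenceSet([
            SequenceRecord(id=f"p{i}", bases=random_dna(rng, 30))
            for i in range(12)])
        corpus = prepare_corpus(positives, seed=0)
        assert len(corpus) == 24
        for pos, neg in zip(corpus.records[::2], corpus.records[1::2]):
            assert (pos.label, neg.label) == (1, 0)
            assert Counter(pos.bases) == Counter(neg.bases)
            assert pos.split == neg.split

    def test_drops_records_with_ambiguous_bases(self):
        rng = np.random.default_rng(2)
        recs = [SequenceRecord(id=f"p{i}", bases=random_dna(rng, 30))
                for i in range(11)]
        recs.append(SequenceRecord(id="bad", bases="ACGTNNACGT" * 3))
        corpus = prepare_corpus(SequenceSet(recs), seed=0)
        assert all("N" not in r.bases for r in corpus)
        assert len(corpus) == 22
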