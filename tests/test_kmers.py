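"""Median k-mer copy-number filtering against brute-force oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circex.kmers import (
    build_kmer_table,
    filter_by_median_copy,
    median_kmer_copy,
    random_downsample,
)
from circex.seqio import SequenceRecord, reverse_complement
from tests.conftest import random_dna


def oracle_counts(reads, k):
    """Naive canonical k-mer counting."""
    counts = Counter()
    for r in reads:
        for i in range(len(r.sequence) - k + 1):
            kmer = r.sequence[i : i + k]
            if "N" in kmer:
                continue
            counts[min(kmer, reverse_complement(kmer))] += 1
    return dict(counts)


def oracle_median(read, reads, k):
    counts = oracle_counts(reads, k)
    copies = []
    for i in range(len(read.sequence) - k + 1):
        kmer = read.sequence[i : i + k]
        if "N" in kmer:
            continue
        copies.append(counts[min(kmer, reverse_complement(kmer))])
    return float(np.median(copies))


def recs(*seqs):
    return [SequenceRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)]


class TestBuildKmerTable:
    def test_overlapping_and_canonical(self):
        # AAAA has AAA at two positions; TTT canonicalises to AAA
        table = build_kmer_table(recs("AAAA"), k=3)
        assert table.as_dict() == {"AAA": 2}

    def test_palindromic_kmer(self):
        table = build_kmer_table(recs("ACGT"), k=4)
        assert table.as_dict() == {"ACGT": 1}

    def test_n_kmers_skipped(self):
        table = build_kmer_table(recs("ACGNA"), k=3)
        assert table.as_dict() == {"ACG": 1}

    def test_matches_oracle_on_random_reads(self, rng):
        reads = recs(*(random_dna(rng, int(rng.integers(20, 60))) for _ in range(20)))
        table = build_kmer_table(reads, k=5)
        assert table.as_dict() == oracle_counts(reads, 5)

    def test_k_larger_than_reads(self):
        with pytest.raises(ValueError):
            build_kmer_table(recs("ACGT"), k=10)


class TestMedianKmerCopy:
    def test_even_multiset_is_mean_of_central_pair(self):
        # read GGGGG: 2x GGGG... construct copy numbers [2, 8]:
        # use a read with two k-mers of known counts
        reads = recs("ACGTA", "ACGT", "CGTA" * 2)
        # k=4: ACGTA -> ACGT, CGTA
        table = build_kmer_table(reads, k=4)
        read = reads[0]
        counts = sorted(
            (oracle_counts(reads, 4)[min(km, reverse_complement(km))])
            for km in ("ACGT", "CGTA")
        )
        expected = (counts[0] + counts[1]) / 2
        assert median_kmer_copy(read, table) == expected

    def test_repeated_unique_kmer(self):
        # one distinct 3-mer repeated: median equals its total count
        reads = recs("AAAAAA")
        table = build_kmer_table(reads, k=3)
        assert median_kmer_copy(reads[0], table) == 4.0

    def test_matches_oracle(self, rng):
        reads = recs(*(random_dna(rng, 40) for _ in range(10)))
        table = build_kmer_table(reads, k=7)
        for r in reads:
            assert median_kmer_copy(r, table) == oracle_median(r, reads, 7)

    def test_no_countable_kmer(self):
        reads = recs("ACGTACGT", "NNNNN")
        table = build_kmer_table(reads, k=4)
        with pytest.raises(ValueError, match="median"):
            median_kmer_copy(reads[1], table)


class TestFilterByMedianCopy:
    def test_unique_reads_all_discarded(self, rng):
        reads = recs(*(random_dna(rng, 100) for _ in range(20)))
        kept, report = filter_by_median_copy(reads, k=21, min_median=5)
        assert kept == []
        assert report.kept_count == 0
        assert report.input_count == 20

    def test_boundary_median_exactly_at_threshold_is_retained(self):
        # 5 identical reads: every k-mer has copy number exactly 5
        reads = recs(*(["ACGTACGTAATG"] * 5))
        kept, _ = filter_by_median_copy(reads, k=5, min_median=5)
        assert len(kept) == 5

    def test_high_copy_separated_from_unique(self, rng):
        # reads drawn from one short circle (high copy) vs unique reads
        circle = random_dna(rng, 500)
        doubled = circle + circle
        high = [
            SequenceRecord(id=f"h{i}", sequence=doubled[s : s + 200])
            for i, s in enumerate(rng.integers(0, 500, 30))
        ]
        unique = recs(*(random_dna(rng, 200) for _ in range(30)))
        reads = high + unique
        kept, report = filter_by_median_copy(reads, k=15, min_median=5)
        assert {r.id for r in kept} == {r.id for r in high}
        assert report.discarded_count == 30

    def test_monotone_in_threshold(self, rng):
        circle = random_dna(rng, 300)
        reads = [
            SequenceRecord(id=f"r{i}", sequence=(circle + circle)[s : s + 100])
            for i, s in enumerate(rng.integers(0, 300, 40))
        ]
        sizes = [
            len(filter_by_median_copy(reads, k=9, min_median=m)[0])
            for m in (1, 3, 5, 10, 100)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invariant_to_reverse_complementing_inputs(self, rng):
        circle = random_dna(rng, 400)
        reads = [
            SequenceRecord(id=f"r{i}", sequence=(circle + circle)[s : s + 150])
            for i, s in enumerate(rng.integers(0, 400, 30))
        ]
        flipped = [
            SequenceRecord(id=r.id, sequence=reverse_complement(r.sequence))
            if i % 2
            else r
            for i, r in enumerate(reads)
        ]
        kept_a, _ = filter_by_median_copy(reads, k=11, min_median=4)
        kept_b, _ = filter_by_median_copy(flipped, k=11, min_median=4)
        assert {r.id for r in kept_a} == {r.id for r in kept_b}

    def test_short_reads_counted_separately(self):
        reads = recs("ACGTACGTACGT", "ACG")
        kept, report = filter_by_median_copy(reads, k=5, min_median=1)
        assert report.no_kmer_count == 1
        assert report.kept_count == 1

    def test_fraction_mode_matches_stacks_rule(self, rng):
        # discard iff >= 80% of k-mers are below the threshold
        circle = random_dna(rng, 300)
        reads = [
            SequenceRecord(id=f"r{i}", sequence=(circle + circle)[s : s + 120])
            for i, s in enumerate(rng.integers(0, 300, 25))
        ] + recs(*(random_dna(rng, 120) for _ in range(10)))
        kept, _ = filter_by_median_copy(reads, k=9, min_median=3, mode="fraction", fraction=0.8)
        table_counts = oracle_counts(reads, 9)
        for r in reads:
            kms = [
                table_counts[min(r.sequence[i : i + 9], reverse_complement(r.sequence[i : i + 9]))]
                for i in range(len(r.sequence) - 8)
            ]
            below = sum(1 for c in kms if c < 3) / len(kms)
            assert (r in kept) == (below < 0.8)


class TestRandomDownsample:
    def test_full_sample_is_identity_set(self, rng):
        reads = recs(*(random_dna(rng, 30) for _ in range(10)))
        assert {r.id for r in random_downsample(reads, 10, seed=1)} == {
            r.id for r in reads
        }

    def test_deterministic_given_seed(self, rng):
        reads = recs(*(random_dna(rng, 30) for _ in range(50)))
        a = random_downsample(reads, 7, seed=42)
        b = random_downsample(reads, 7, seed=42)
        assert [r.id for r in a] == [r.id for r in b]

    def test_uniformity(self, rng):
        reads = recs(*(random_dna(rng, 30) for _ in range(10)))
        hits = Counter()
        for s in range(5000):
            (pick,) = random_downsample(reads, 1, seed=s)
            hits[pick.id] += 1
        freqs = np.array([hits[r.id] for r in reads]) / 5000
        assert np.allclose(freqs, 0.1, atol=0.02)

    def test_oversample_is_error(self, rng):
        with pytest.raises(ValueError):
            random_downsample(recs("ACGT"), 2, seed=0)
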