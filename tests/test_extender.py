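"""Consensus building, fork detection, circularisation and the loop."""

import pytest

from circex.extender import (
    Contig,
    assemble,
    canonical_rotation,
    check_circular,
    circular_identity,
    consensus_overhangs,
    detect_fork,
    extend_iteration,
)
from circex.overlap import EdgeAlignment, ExtenderConfig
from circex.seqio import Interval, SequenceRecord, reverse_complement, rotate_circular
from circex.simulate import simulate_genome, simulate_reads
from tests.conftest import random_dna


def ov(seq, read_id="r"):
    return EdgeAlignment(
        read_id=read_id,
        orientation="forward",
        identity=100.0,
        mapped_span_on_edge=Interval("edge", 0, 1),
        mapped_length=8000,
        overhang=seq,
    )


@pytest.fixture
def cfg():
    return ExtenderConfig(min_support=3)


class TestConsensusOverhangs:
    def test_unanimous(self, cfg):
        clusters = consensus_overhangs([ov("ACGTACGT", f"r{i}") for i in range(10)], cfg)
        assert clusters == [("ACGTACGT", 10)]

    def test_single_substitution_outvoted(self, rng, cfg):
        base = random_dna(rng, 200)
        mutant = "C" + base[1:] if base[0] != "C" else "G" + base[1:]
        overhangs = [ov(base, f"r{i}") for i in range(9)] + [ov(mutant, "m")]
        clusters = consensus_overhangs(overhangs, cfg)
        assert clusters == [(base, 10)]

    def test_divergent_prefixes_split_clusters(self, rng, cfg):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        overhangs = [ov(a, f"a{i}") for i in range(5)] + [ov(b, f"b{i}") for i in range(5)]
        clusters = consensus_overhangs(overhangs, cfg)
        assert sorted(s for _, s in clusters) == [5, 5]
        assert {c for c, _ in clusters} == {a, b}

    def test_truncated_at_min_support_coverage(self, rng, cfg):
        long, short = random_dna(rng, 500), None
        short = long[:200]
        overhangs = [ov(long, "l1"), ov(long, "l2")] + [ov(short, f"s{i}") for i in range(4)]
        (consensus, support), = consensus_overhangs(overhangs, cfg)
        # beyond 200 bp only 2 members cover the columns: below min_support 3
        assert consensus == long[:200]
        assert support == 6

    def test_empty_input(self, cfg):
        assert consensus_overhangs([], cfg) == []


class TestDetectFork:
    def test_even_split_is_fork(self, rng):
        cfg = ExtenderConfig(min_support=3, fork_fraction=0.2)
        a, b = random_dna(rng, 100), random_dna(rng, 100)
        is_fork, alts = detect_fork([(a, 50), (b, 50)], cfg)
        assert is_fork and len(alts) == 2

    def test_minor_branch_not_a_fork(self, rng):
        cfg = ExtenderConfig(min_support=3, fork_fraction=0.2)
        is_fork, alts = detect_fork([("A" * 10, 97), ("C" * 10, 3)], cfg)
        assert not is_fork

    def test_single_cluster_never_forks(self):
        cfg = ExtenderConfig()
        assert detect_fork([("ACGT", 100)], cfg) == (False, [])

    def test_low_support_pair_not_a_fork(self):
        # two stray overhangs in a coverage dip must not mimic a branch
        cfg = ExtenderConfig(min_support=3, fork_fraction=0.2)
        assert not detect_fork([("AAAA", 1), ("CCCC", 1)], cfg)[0]


class TestCheckCircular:
    def test_exact_terminal_duplication(self, rng):
        cfg = ExtenderConfig(min_support=3)
        truth = random_dna(rng, 30000)
        grown = truth + truth[:2000]
        circular, trimmed = check_circular(grown, cfg)
        assert circular
        assert trimmed == truth

    def test_random_sequence_not_circular(self, rng):
        cfg = ExtenderConfig()
        circular, trimmed = check_circular(random_dna(rng, 30000), cfg)
        assert not circular

    def test_identity_threshold_bracketing(self, rng):
        truth = random_dna(rng, 30000)
        dup = list(truth[:2000])
        for pos in rng.choice(2000, size=40, replace=False):  # 98% identity copy
            dup[pos] = "ACGT"[("ACGT".index(dup[pos]) + 1) % 4]
        grown = truth + "".join(dup)
        at100 = ExtenderConfig(min_read_similarity=100)
        at99 = ExtenderConfig(min_read_similarity=99)
        at97 = ExtenderConfig(min_read_similarity=97)
        assert not check_circular(grown, at100)[0]
        assert not check_circular(grown, at99)[0]
        assert check_circular(grown, at97)[0]

    def test_short_contig_never_circular(self, rng):
        cfg = ExtenderConfig(circular_min_overlap=1000)
        assert not check_circular(random_dna(rng, 1500), cfg)[0]


class TestExtendIteration:
    def test_zero_overhangs_is_dead_end(self, rng, cfg):
        contig = Contig(id="c", sequence=random_dna(rng, 20000))
        reads = [SequenceRecord(id="r", sequence=random_dna(rng, 9000))]
        outcome = extend_iteration(contig, reads, cfg)
        assert outcome.status == "dead_end"

    def test_unanimous_extension(self, rng, cfg):
        seq = random_dna(rng, 20000)
        ext = random_dna(rng, 2000)
        reads = [
            SequenceRecord(id=f"r{i}", sequence=seq[-9000:] + ext) for i in range(6)
        ]
        contig = Contig(id="c", sequence=seq)
        outcome = extend_iteration(contig, reads, cfg)
        assert outcome.status == "extended"
        assert outcome.support == 6
        assert contig.sequence == seq + ext

    def test_grown_past_junction_circularises(self, rng, cfg):
        truth = random_dna(rng, 25000)
        contig = Contig(id="c", sequence=truth + truth[:1500])
        reads = [
            SequenceRecord(id=f"r{i}", sequence=(truth * 2)[1000:10500]) for i in range(6)
        ]
        outcome = extend_iteration(contig, reads, cfg)
        assert outcome.status == "circularized"
        assert contig.circular
        assert contig.sequence == truth


class TestAssembleRoundTrips:
    """Small, fast end-to-end round trips (the full-scale versions of
    these live in the acceptance tests)."""

    def fixture(self, length, seed, circular=True, error=0.0):
        g = simulate_genome([length], seed=seed, circular=circular)
        rs = simulate_reads(
            g,
            coverage=40,
            read_length=(4000, 400, 3000, 5000),
            error_rate=(error, 0, 0),
            seed=seed + 100,
        )
        return g, rs

    def cfg(self):
        # anchors scaled to the small fixture reads
        return ExtenderConfig(
            min_mapped_part=2500, edge_size=6000, min_support=3,
            circular_min_overlap=500,
        )

    def test_circle_recovered_exactly(self):
        g, rs = self.fixture(12000, seed=31)
        contig = assemble(rs.reads[0], rs.reads, self.cfg())
        assert contig.status == "circularized"
        assert contig.circular
        assert canonical_rotation(contig.sequence) == canonical_rotation(
            g.chromosomes[0].sequence
        )

    def test_history_is_ordered_and_lengths_nondecreasing(self):
        g, rs = self.fixture(12000, seed=32)
        contig = assemble(rs.reads[0], rs.reads, self.cfg())
        iters = [h.iteration for h in contig.history]
        assert iters == list(range(1, len(iters) + 1))
        lengths = [h.contig_length for h in contig.history if h.status == "extended"]
        assert lengths == sorted(lengths)

    def test_deterministic(self):
        g, rs = self.fixture(12000, seed=33)
        a = assemble(rs.reads[0], rs.reads, self.cfg())
        b = assemble(rs.reads[0], rs.reads, self.cfg())
        assert a.sequence == b.sequence
        assert [h.status for h in a.history] == [h.status for h in b.history]

    def test_linear_truth_dead_ends_at_terminus(self):
        g, rs = self.fixture(12000, seed=34, circular=False)
        starter = None
        for r, o in zip(rs.reads, rs.origins):
            if o.start == 0:
                seq = r.sequence if o.strand == "+" else reverse_complement(r.sequence)
                starter = SequenceRecord(id=r.id, sequence=seq)
                break
        assert starter is not None
        contig = assemble(starter, rs.reads, self.cfg())
        assert contig.status == "dead_end"
        assert not contig.circular
        assert abs(len(contig) - 12000) <= self.cfg().end_slack


class TestCircularComparison:
    def test_canonical_rotation_invariants(self, rng):
        s = random_dna(rng, 500)
        rot = rotate_circular(SequenceRecord(id="r", sequence=s), 123).sequence
        assert canonical_rotation(s) == canonical_rotation(rot)
        assert canonical_rotation(s) == canonical_rotation(reverse_complement(s))
        # brute-force least-rotation oracle
        doubled = s + s
        brute = min(
            min(doubled[i : i + len(s)] for i in range(len(s))),
            min(
                (reverse_complement(s) * 2)[i : i + len(s)] for i in range(len(s))
            ),
        )
        assert canonical_rotation(s) == brute

    def test_circular_identity_on_rotated_noisy_copy(self, rng):
        s = random_dna(rng, 5000)
        noisy = list((s + s)[700 : 700 + 5000])
        for pos in rng.choice(5000, size=25, replace=False):
            noisy[pos] = "ACGT"[("ACGT".index(noisy[pos]) + 1) % 4]
        ident = circular_identity("".join(noisy), s)
        assert ident == pytest.approx(99.5, abs=0.05)
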