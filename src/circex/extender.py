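"""The iterative 3'-extension assembly loop.

Starting from a seed sequence (a contig from another assembler or a
single read), each iteration maps all reads to the contig's 3' edge,
gathers the parts of reads that overhang the end, builds a consensus
of the overhangs and appends it. The loop stops when

* the contig's two ends are found to be identical — the molecule is
  circular (the duplicated terminal overlap is trimmed);
* two or more alternative extensions are each supported by a
  substantial share of the overhanging reads — a fork, typically a
  long repeat shared between molecules, which is reported rather than
  guessed through;
* no extension reaches the support threshold — a dead end (the true
  terminus of a linear molecule, or loss of coverage);
* the iteration cap is reached.

Everything in the loop is deterministic: identical reads and
configuration give identical contigs and logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from circex.align import align_global, align_prefix, cigar_columns
from circex.overlap import (
    EdgeAlignment,
    ExtenderConfig,
    collect_overhangs,
)
from circex.seqio import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"  # fixed tie-break order for consensus columns


@dataclass
class ExtensionOutcome:
    """Result of one extension iteration."""

    status: str                    # extended | dead_end | fork | circularized | max_iterations
    iteration: int
    consensus: str = ""
    support: int = 0
    alternatives: list[tuple[str, int]] = field(default_factory=list)
    contig_length: int = 0
    rejections: dict[str, int] = field(default_factory=dict)


@dataclass
class Contig:
    """The growing (or finished) assembly with its full history."""

    id: str
    sequence: str
    circular: bool = False
    history: list[ExtensionOutcome] = field(default_factory=list)
    starter_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def status(self) -> str:
        return self.history[-1].status if self.history else "new"


# ---------------------------------------------------------------------------
# Consensus of overhangs


def _prefix_identity(a: str, b: str) -> float:
    """Identity of the common-length prefixes of two strings."""
    n = min(len(a), len(b))
    return align_global(a[:n], b[:n]).identity


def _cluster_votes(members: list[str]) -> np.ndarray:
    """Per-column base/gap votes of a star alignment on the longest
    member (the anchor).

    Every other member is aligned to a prefix of the anchor and votes
    per anchor column; member insertions relative to the anchor are
    dropped (they create no anchor column), member deletions vote gap.
    """
    anchor = members[0]
    n = len(anchor)
    votes = np.zeros((n, 5), dtype=np.int64)  # A C G T gap
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}
    for member in members:
        if member == anchor:
            for i, ch in enumerate(anchor):
                votes[i, base_idx.get(ch, 4)] += 1  # N votes count as gap
            continue
        aln = align_prefix(member, anchor)
        q = t = 0
        for op in cigar_columns(aln.cigar):
            if op in ("=", "X"):
                votes[t, base_idx.get(member[q], 4)] += 1
                q += 1
                t += 1
            elif op == "I":
                q += 1
            else:  # D: member lacks this anchor base
                votes[t, 4] += 1
                t += 1
    return votes


def _consensus_from_votes(
    votes: np.ndarray, floor: int, max_len: Optional[int] = None
) -> str:
    """Column-plurality consensus, truncated at the first column with
    fewer than *floor* votes (and optionally at *max_len* columns).

    Plurality wins each column (ties broken A<C<G<T); a gap wins a
    column only with a strict majority of the column's votes, in which
    case the column is omitted.
    """
    out: list[str] = []
    for i in range(votes.shape[0]):
        coverage = int(votes[i].sum())
        if coverage < floor:
            break
        if votes[i, 4] * 2 > coverage:
            continue  # gap majority: omit the column
        out.append(_BASE_ORDER[int(np.argmax(votes[i, :4]))])
        if max_len is not None and len(out) >= max_len:
            break
    return "".join(out)


def _conflict_truncation(consensus: str, votes: np.ndarray, config: ExtenderConfig) -> str:
    """Stop the consensus at the first seriously contested column.

    Reads whose continuation diverges only a short way past the
    contig end co-cluster with the majority (their common prefix
    dominates the identity) and are then outvoted column by column. A
    column where the runner-up symbol holds at least two votes and at
    least ``fork_fraction`` of the column's coverage marks such a
    buried divergence; extending past it would commit to the majority
    branch on thin, contested evidence. Isolated read errors never
    reach two agreeing votes at realistic error rates, so this
    truncation is inert on clean single-origin clusters.
    """
    out_len = 0
    i = 0  # column index in votes
    for ch in consensus:
        # advance to the column this consensus base came from
        # (gap-majority columns were omitted by _consensus_from_votes)
        while i < votes.shape[0]:
            cov = int(votes[i].sum())
            if votes[i, 4] * 2 > cov:
                i += 1
                continue
            break
        if i >= votes.shape[0]:
            break
        col = votes[i]
        cov = int(col.sum())
        order = np.sort(col)[::-1]
        runner_up = int(order[1])
        # the first few columns carry systematic noise from +-1 bp
        # wobble in the overhang split point, not branch signal
        if out_len >= 10 and runner_up >= 2 and runner_up >= config.fork_fraction * cov:
            return consensus[:out_len]
        out_len += 1
        i += 1
    return consensus


def _member_divergence_truncation(
    consensus: str, members: list[str], config: ExtenderConfig
) -> str:
    """Cap the consensus where any of its own members truly departs.

    A read continuing into a different branch only a short way past
    the contig end still co-clusters with the majority (the shared
    prefix dominates its identity) and is then simply outvoted. Such
    a member is recognisable all the same: past its exact common
    prefix with the consensus, its remaining sequence aligns to the
    consensus at near-random identity, unlike an isolated sequencing
    error which is followed by renewed agreement. The consensus is
    truncated at the departure point so the decision is deferred to
    the branch itself, where the fork test has full support.
    """
    cap = len(consensus)
    for member in members:
        lcp = _common_prefix_len(member, consensus)
        if lcp == 0 or lcp >= min(len(member), len(consensus)):
            continue
        n = min(len(member) - lcp, len(consensus) - lcp, 500)
        if n < 20:
            continue
        if align_global(consensus[lcp : lcp + n], member[lcp : lcp + n]).identity < 80.0:
            cap = min(cap, lcp)
    return consensus[:cap]


def _build_clusters(
    overhangs: Sequence[EdgeAlignment], config: ExtenderConfig
) -> list[list[str]]:
    """Greedy prefix-similarity clustering of overhang sequences,
    largest cluster first; within a cluster the longest member leads."""
    clusters: list[list[str]] = []
    # overhangs arrive longest-first, so each cluster's first member anchors it
    for ov in sorted(overhangs, key=lambda a: (-len(a.overhang), a.read_id)):
        seq = ov.overhang
        placed = False
        for members in clusters:
            if _prefix_identity(seq, members[0]) >= config.cluster_identity:
                members.append(seq)
                placed = True
                break
        if not placed:
            clusters.append([seq])
    clusters.sort(key=lambda m: (-len(m), m[0]))
    return clusters


def consensus_overhangs(
    overhangs: Sequence[EdgeAlignment], config: ExtenderConfig
) -> list[tuple[str, int]]:
    """Cluster overhangs by prefix similarity and build per-cluster
    consensus sequences.

    Two overhangs co-cluster when their common-length prefixes align
    at >= ``config.cluster_identity`` (twice the read-vs-contig
    tolerance, since two reads may each carry independent errors).
    Each cluster's consensus is truncated at the first column covered
    by fewer than ``min_support`` members. Clusters are returned as
    (consensus, support) sorted by descending support.
    """
    clusters = _build_clusters(overhangs, config)
    result = [
        (_consensus_from_votes(_cluster_votes(members), config.min_support), len(members))
        for members in clusters
    ]
    result.sort(key=lambda cs: (-cs[1], cs[0]))
    return result


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _branch_guard_truncation(
    winning: str, others: list[tuple[list[str], "np.ndarray"]], config: ExtenderConfig
) -> str:
    """Cap the winning consensus at any credible competing branch.

    Extending past a divergence point on thin evidence commits the
    contig to one branch and silently locks the other branch's reads
    out (their anchors then mismatch the appended unique tail). So the
    chosen extension is truncated at the longest common prefix with
    every competing cluster that is credible: two or more members, or
    a single member whose sequence past the divergence is genuinely
    different (not just a read error followed by more agreement).
    Extension beyond the branch then only happens once the branch
    point itself is reached, where overhang support is full and the
    fork test is decisive; a competitor that still cannot qualify as a
    fork there is treated as a minor variant and overridden.
    """
    capped = winning
    for members, votes in others:
        guard = _consensus_from_votes(votes, 1)
        if not guard:
            continue
        lcp = _common_prefix_len(capped, guard)
        if lcp >= len(capped):
            continue
        if len(members) < 2:
            # singleton: only guard if its continuation truly diverges
            n = min(len(capped) - lcp, len(guard) - lcp, 500)
            if n < 20:
                continue
            if align_global(capped[lcp : lcp + n], guard[lcp : lcp + n]).identity >= 80.0:
                continue  # isolated error, not a branch
        if lcp == 0:
            continue  # at the branch: fork logic decides, not the guard
        capped = capped[:lcp]
    return capped


def detect_fork(
    clusters: Sequence[tuple[str, int]], config: ExtenderConfig
) -> tuple[bool, list[tuple[str, int]]]:
    """Decide whether alternative extensions constitute a fork.

    A fork exists when at least two clusters each hold
    >= ``fork_fraction`` of the total overhang support; an alternative
    must also reach ``min_support`` reads on its own, so that a couple
    of stray overhangs in a coverage dip cannot mimic a branch point.
    Returns (is_fork, qualifying alternatives).
    """
    total = sum(s for _, s in clusters)
    if total == 0 or len(clusters) < 2:
        return False, []
    qualifying = [
        cs
        for cs in clusters
        if cs[1] >= config.fork_fraction * total and cs[1] >= config.min_support
    ]
    if len(qualifying) >= 2:
        return True, qualifying
    return False, []


# ---------------------------------------------------------------------------
# Circularity


def check_circular(
    contig: SequenceRecord | str, config: ExtenderConfig
) -> tuple[bool, str]:
    """Test whether the contig's 3' end has grown back onto its 5' end.

    Circular iff a suffix of length >= ``circular_min_overlap`` aligns
    to a prefix at >= ``min_read_similarity`` identity with both
    termini anchored. Returns (circular, trimmed sequence): on success
    the duplicated suffix is removed so the sequence represents the
    circle exactly once.
    """
    seq = contig.sequence if isinstance(contig, SequenceRecord) else contig
    n = len(seq)
    min_ov = config.circular_min_overlap
    if n <= 2 * min_ov:
        return False, seq
    max_ov = n // 2
    seed_len = 21
    candidates: set[int] = set()
    # exact seeds taken at several offsets into the prefix tolerate
    # occasional consensus errors near the very start
    for off in range(0, min_ov - seed_len, 64):
        seed = seq[off : off + seed_len]
        start = max(off + 1, n - max_ov)
        pos = seq.find(seed, start)
        while pos != -1:
            j = pos - off
            if n - min_ov >= j >= n - max_ov:
                candidates.add(j)
            pos = seq.find(seed, pos + 1)
    best: Optional[tuple[float, int]] = None
    for j in sorted(candidates):
        overlap_len = n - j
        aln = align_global(seq[j:], seq[:overlap_len])
        if aln.identity >= config.min_read_similarity:
            if best is None or (aln.identity, overlap_len) > (best[0], n - best[1]):
                best = (aln.identity, j)
    if best is None:
        return False, seq
    return True, seq[: best[1]]


# ---------------------------------------------------------------------------
# The loop


def extend_iteration(
    contig: Contig, reads: Sequence[SequenceRecord], config: ExtenderConfig
) -> ExtensionOutcome:
    """Run one iteration of the extension loop and update the contig.

    Status precedence: circularized > fork > dead_end > extended.
    """
    iteration = len(contig.history) + 1
    record = SequenceRecord(id=contig.id, sequence=contig.sequence)
    overhangs, tally = collect_overhangs(reads, record, config)
    member_lists = _build_clusters(overhangs, config)
    scored = []
    for members in member_lists:
        votes = _cluster_votes(members)
        consensus = _consensus_from_votes(votes, config.min_support)
        scored.append((members, votes, consensus))
    scored.sort(key=lambda t: (-len(t[0]), t[2]))
    clusters = [(consensus, len(members)) for members, _, consensus in scored]
    is_fork, alternatives = detect_fork(clusters, config)
    is_circular, trimmed = check_circular(contig.sequence, config)

    if is_circular:
        contig.sequence = trimmed
        contig.circular = True
        outcome = ExtensionOutcome(
            status="circularized",
            iteration=iteration,
            contig_length=len(trimmed),
            rejections=dict(tally),
        )
    elif is_fork:
        outcome = ExtensionOutcome(
            status="fork",
            iteration=iteration,
            alternatives=alternatives,
            contig_length=len(contig.sequence),
            rejections=dict(tally),
        )
    else:
        consensus, support = clusters[0] if clusters else ("", 0)
        if support >= config.min_support and consensus:
            pass  # fully supported extension
        elif support >= config.min_extension_coverage:
            # local coverage dip: bridge a bounded step at reduced
            # coverage rather than declaring a dead end — the columns
            # still need min_extension_coverage reads each
            members, votes, _ = scored[0]
            consensus = _consensus_from_votes(
                votes, config.min_extension_coverage, max_len=config.bridge_step
            )
        else:
            consensus = ""
        if consensus:
            consensus = _conflict_truncation(consensus, scored[0][1], config)
        if consensus:
            consensus = _member_divergence_truncation(
                consensus, scored[0][0], config
            )
        if consensus and len(scored) > 1:
            consensus = _branch_guard_truncation(
                consensus, [(m, v) for m, v, _ in scored[1:]], config
            )
        if consensus:
            contig.sequence = contig.sequence + consensus
            outcome = ExtensionOutcome(
                status="extended",
                iteration=iteration,
                consensus=consensus,
                support=support,
                contig_length=len(contig.sequence),
                rejections=dict(tally),
            )
        else:
            outcome = ExtensionOutcome(
                status="dead_end",
                iteration=iteration,
                contig_length=len(contig.sequence),
                rejections=dict(tally),
            )
    contig.history.append(outcome)
    return outcome


def assemble(
    starter: SequenceRecord,
    reads: Sequence[SequenceRecord],
    config: Optional[ExtenderConfig] = None,
    contig_id: str = "contig1",
) -> Contig:
    """Extend a starter sequence until it circularises, forks, dead-ends
    or hits the iteration cap.

    The returned :class:`Contig` carries the per-iteration history; a
    fork outcome lists every qualifying alternative so a run can be
    restarted from a chosen branch.
    """
    if config is None:
        config = ExtenderConfig()
    if not reads:
        raise ValueError("no reads supplied")
    contig = Contig(id=contig_id, sequence=starter.sequence, starter_id=starter.id)
    for _ in range(config.max_iterations):
        outcome = extend_iteration(contig, reads, config)
        logger.info(
            "iteration %d: %s, length %d, support %d",
            outcome.iteration,
            outcome.status,
            outcome.contig_length,
            outcome.support,
        )
        if outcome.status != "extended":
            return contig
    contig.history.append(
        ExtensionOutcome(
            status="max_iterations",
            iteration=len(contig.history) + 1,
            contig_length=len(contig.sequence),
        )
    )
    return contig


# ---------------------------------------------------------------------------
# Comparing circular sequences


def canonical_rotation(sequence: str) -> str:
    """Canonical form of a circular sequence: the lexicographically
    least rotation of the sequence or its reverse complement.

    Two error-free assemblies of the same circle agree exactly after
    this normalisation regardless of start point and strand.
    """
    return min(_least_rotation(sequence), _least_rotation(reverse_complement(sequence)))


def _least_rotation(s: str) -> str:
    # Booth's algorithm, O(n)
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def circular_identity(assembly: str, truth: str) -> float:
    """Percent identity of an assembled circle against the true circle,
    maximised over rotation and strand.

    The assembly is aligned as an infix of the doubled truth so that
    any rotation scores without artificial end penalties.
    """
    doubled = truth + truth
    best = 0.0
    for seq in (assembly, reverse_complement(assembly)):
        res = edlib.align(seq, doubled, mode="HW", task="path")
        if res["editDistance"] == -1:
            continue
        cols = matches = 0
        for op in cigar_columns(res["cigar"]):
            cols += 1
            if op == "=":
                matches += 1
        if cols:
            best = max(best, 100.0 * matches / cols)
    return best
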