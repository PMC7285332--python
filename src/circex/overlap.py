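"""Finding reads that overhang the contig's 3' end.

Each extension iteration maps every read (both strands) against a
window at the contig's 3' end. A read supports extension when it
aligns to the window at sufficient identity, anchors a long enough
part, reaches the window's 3' terminus and continues past it; its
unaligned suffix — the overhang — supplies candidate new sequence.

Mapping is seed-and-verify: exact k-mer seeds locate the read on the
window (diagonal clustering tolerates indel drift), and edlib
semi-global alignment of the window suffix against the read verifies
identity and fixes the overhang split point exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from circex.align import SeedIndex, align_prefix, cluster_seeds
from circex.seqio import Interval, SequenceRecord, reverse_complement

#: default seed length for read-to-edge matching
SEED_K = 13
#: minimum co-linear seeds before a candidate mapping is verified —
#: genuine anchors of thousands of bases yield hundreds of seeds, while
#: chance k-mer collisions give isolated ones
MIN_SEED_COUNT = 5


@dataclass
class ExtenderConfig:
    """Tunable parameters of the extension loop.

    The mapping defaults correspond to targeted assembly of PacBio
    CCS/HiFi-grade reads: at least 8 kb of a read must anchor on the
    last 15 kb of the contig at >= 99% identity for the read to count.
    """

    min_read_similarity: float = 99.0   # percent identity over alignment columns
    min_mapped_part: int = 8000         # bp of read anchored on the edge window
    edge_size: int = 15000              # bp of contig 3' end used for mapping
    min_support: int = 5                # reads required to extend
    fork_fraction: float = 0.2          # min share of support for an alternative
    max_iterations: int = 1000
    circular_min_overlap: int = 1000    # bp of terminal duplication for circularity
    end_slack: int = 10                 # bp tolerance for "reaches the 3' terminus"
    min_extension_coverage: int = 1     # absolute per-column floor when bridging
    bridge_step: int = 500              # max bp appended per low-coverage bridge

    @property
    def cluster_identity(self) -> float:
        """Identity threshold for two overhangs to co-cluster.

        Two reads each within ``100 - min_read_similarity`` percent of
        the true sequence can differ from each other by twice that, so
        the read-vs-read threshold is ``2 * min_read_similarity - 100``
        (floored at 80 for permissive settings).
        """
        return max(2.0 * self.min_read_similarity - 100.0, 80.0)

    def __post_init__(self) -> None:
        if not (0 < self.min_read_similarity <= 100):
            raise ValueError("min_read_similarity must be in (0, 100]")
        if self.min_mapped_part > self.edge_size:
            raise ValueError("min_mapped_part cannot exceed edge_size")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_extension_coverage < 1:
            raise ValueError("min_extension_coverage must be >= 1")
        if not (0 < self.fork_fraction <= 0.5):
            raise ValueError("fork_fraction must be in (0, 0.5]")


@dataclass
class EdgeAlignment:
    """One read accepted as overhanging the contig's 3' edge."""

    read_id: str
    orientation: str                    # "forward" | "reverse"
    identity: float                     # percent over alignment columns
    mapped_span_on_edge: Interval
    mapped_length: int                  # read bases aligned within the window
    overhang: str                       # read suffix past the contig end, contig orientation
    reaches_contig_end: bool = True


@dataclass
class Rejection:
    read_id: str
    reason: str  # unmapped | internal_only | low_identity | short_mapped_part | no_overhang


def extract_edge(contig: SequenceRecord, edge_size: int) -> str:
    """Last ``min(edge_size, len(contig))`` bases of the contig."""
    if len(contig.sequence) == 0:
        raise ValueError("empty contig")
    return contig.sequence[-edge_size:]


def _try_orientation(
    read_seq: str, edge: str, index: SeedIndex, config: ExtenderConfig
):
    """Attempt one orientation; returns (status, payload, n_seeds).

    status: 'accepted' -> payload is (identity, a, b, overhang);
    otherwise status is a rejection reason and payload is None.
    """
    qpos, tpos = index.matches(read_seq)
    if qpos.size == 0:
        return "unmapped", None, 0
    clusters = cluster_seeds(qpos, tpos, diag_band=50, max_gap=500)
    best = clusters[0]
    n_seeds = best.count
    if n_seeds < MIN_SEED_COUNT:
        return "unmapped", None, n_seeds
    # last seed predicts whether the read reaches the window's 3' end
    i_last = best.qpos.argmax()
    rp_last, tp_last = int(best.qpos[i_last]), int(best.tpos[i_last])
    read_tail = len(read_seq) - rp_last
    edge_tail = len(edge) - tp_last
    if read_tail < edge_tail - config.end_slack:
        return "internal_only", None, n_seeds
    # first seed fixes the alignment start on read and window
    i_first = best.qpos.argmin()
    rp0, tp0 = int(best.qpos[i_first]), int(best.tpos[i_first])
    d0 = tp0 - rp0
    a = max(0, -d0)          # first aligned read base
    c = max(0, d0)           # first aligned window base
    aln = align_prefix(edge[c:], read_seq[a:])
    identity = aln.identity
    b = a + aln.target_span[1]      # read base just past the aligned part
    mapped_length = b - a
    overhang = read_seq[b:]
    if identity < config.min_read_similarity:
        return "low_identity", None, n_seeds
    if mapped_length < config.min_mapped_part:
        return "short_mapped_part", None, n_seeds
    if not overhang:
        return "no_overhang", None, n_seeds
    return "accepted", (identity, c, mapped_length, overhang), n_seeds


def align_read_to_edge(
    read: SequenceRecord,
    edge: str,
    config: ExtenderConfig,
    index: Optional[SeedIndex] = None,
) -> EdgeAlignment | Rejection:
    """Map a read (both strands) onto the contig's edge window.

    Returns an :class:`EdgeAlignment` when the read anchors at
    >= ``min_read_similarity`` identity over >= ``min_mapped_part``
    read bases, reaches the window's 3' terminus (within
    ``end_slack``) and continues past it; otherwise a
    :class:`Rejection` with a machine-readable reason.
    """
    if index is None:
        index = SeedIndex(edge, k=SEED_K)
    candidates = []
    for orientation, seq in (
        ("forward", read.sequence),
        ("reverse", reverse_complement(read.sequence)),
    ):
        status, payload, n_seeds = _try_orientation(seq, edge, index, config)
        candidates.append((n_seeds, orientation, status, payload))
    accepted = [c for c in candidates if c[2] == "accepted"]
    if accepted:
        n_seeds, orientation, _, (identity, c0, mapped_length, overhang) = max(
            accepted, key=lambda x: x[0]
        )
        return EdgeAlignment(
            read_id=read.id,
            orientation=orientation,
            identity=identity,
            mapped_span_on_edge=Interval("edge", c0, len(edge)),
            mapped_length=mapped_length,
            overhang=overhang,
        )
    # report the rejection from the orientation with the stronger seed signal
    candidates.sort(key=lambda x: -x[0])
    return Rejection(read_id=read.id, reason=candidates[0][2])


def collect_overhangs(
    reads: Sequence[SequenceRecord],
    contig: SequenceRecord,
    config: ExtenderConfig,
) -> tuple[list[EdgeAlignment], Counter]:
    """All accepted edge alignments, longest overhang first.

    Also returns a tally of rejection reasons for the iteration log.
    """
    edge = extract_edge(contig, config.edge_size)
    index = SeedIndex(edge, k=SEED_K)
    accepted: list[EdgeAlignment] = []
    tally: Counter = Counter()
    for read in reads:
        result = align_read_to_edge(read, edge, config, index=index)
        if isinstance(result, EdgeAlignment):
            accepted.append(result)
        else:
            tally[result.reason] += 1
    accepted.sort(key=lambda a: (-len(a.overhang), a.read_id))
    return accepted, tally
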