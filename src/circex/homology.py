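"""Repeat and plastid-insert detection, and plastid-region variant masking.

Plant mitochondrial genomes carry long repeats (recombination
hotspots) and stretches of DNA of plastid origin (MIPT). Both are
found here as local alignments filtered purely by minimum length and
minimum percent identity — no e-value statistics — with the field's
customary thresholds as defaults: 500 bp / 95% for repeats, 100 bp /
90% for mito-vs-plastid hits. MIPT hits overlapping annotated
mitochondrial protein-coding or RNA genes are suppressed, since
shared genes (*atp*, *rrn*, plastid-like tRNAs) are homologous
without being inserts.

Because the plastid genome is typically covered an order of magnitude
deeper than the mitogenome, reads of true plastid origin pile up on
MIPT regions and generate spurious variant calls there;
:func:`mask_variants` partitions a call set into calls outside and
inside plastid-origin regions.

The search is seed-and-verify: exact k-mer matches are clustered into
co-linear diagonal bands, each band is verified by alignment, and the
best-scoring local stretch is reported when it clears both thresholds.
This is deliberately not BLAST-bit-exact; the contract is the
length/identity filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from circex.align import SeedIndex, best_local_subpath, cluster_seeds
from circex.seqio import Interval, SequenceRecord, reverse_complement

#: seed length for homology search (shorter than the read-mapping seed:
#: hits down to 90% identity must still seed reliably)
HOMOLOGY_SEED_K = 11
_PAD = 50          # bp added around a seed cluster before verification
_DIAG_BAND = 30
_MAX_GAP = 200


@dataclass(frozen=True)
class HomologyHit:
    """One local alignment between two genomic segments."""

    query: Interval
    subject: Interval
    strand: str       # "forward" | "reverse"
    length: int       # alignment columns
    identity: float   # percent matches over columns

    def swapped(self) -> "HomologyHit":
        return HomologyHit(
            query=self.subject,
            subject=self.query,
            strand=self.strand,
            length=self.length,
            identity=self.identity,
        )


@dataclass
class VariantRecord:
    """A minimal variant call; extra fields ride along in attributes."""

    seq_id: str
    position: int          # 0-based
    ref: str
    alt: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("variant with empty REF")

    @property
    def span(self) -> Interval:
        return Interval(self.seq_id, self.position, self.position + len(self.ref))


def local_homology_search(
    query: SequenceRecord,
    subject: SequenceRecord,
    min_length: int,
    min_identity: float,
    _self: bool = False,
) -> list[HomologyHit]:
    """Local alignments between two sequences passing both thresholds.

    Both strands of the subject are searched. When the two records are
    the same sequence (``_self``), the trivial full-length
    self-alignment is excluded and each repeat pair is reported once
    (query interval starting before the subject interval). Hits
    contained in another hit on both axes are dropped.
    """
    hits: list[HomologyHit] = []
    for strand in ("forward", "reverse"):
        subj_seq = (
            subject.sequence if strand == "forward" else reverse_complement(subject.sequence)
        )
        index = SeedIndex(subj_seq, k=HOMOLOGY_SEED_K, max_occ=100)
        qpos, tpos = index.matches(query.sequence)
        if _self and strand == "forward":
            keep = qpos < tpos  # drop the main diagonal and mirror seeds
            qpos, tpos = qpos[keep], tpos[keep]
        for cluster in cluster_seeds(qpos, tpos, diag_band=_DIAG_BAND, max_gap=_MAX_GAP):
            q_lo, q_hi = cluster.q_span
            t_lo, t_hi = cluster.t_span
            if q_hi - q_lo + HOMOLOGY_SEED_K + 2 * _PAD < min_length:
                # even with padding the window cannot reach min_length
                continue
            q0 = max(0, q_lo - _PAD)
            q1 = min(len(query.sequence), q_hi + HOMOLOGY_SEED_K + _PAD)
            t0 = max(0, t_lo - _PAD)
            t1 = min(len(subj_seq), t_hi + HOMOLOGY_SEED_K + _PAD)
            aln = best_local_subpath(query.sequence[q0:q1], subj_seq[t0:t1])
            if aln is None or aln.columns < min_length or aln.identity < min_identity:
                continue
            q_iv = Interval(query.id, q0 + aln.query_span[0], q0 + aln.query_span[1])
            ts, te = t0 + aln.target_span[0], t0 + aln.target_span[1]
            if strand == "reverse":
                n = len(subject.sequence)
                ts, te = n - te, n - ts
            s_iv = Interval(subject.id, ts, te)
            if _self and (q_iv.start, q_iv.end) == (s_iv.start, s_iv.end):
                continue  # palindromic self-match
            if _self and q_iv.start > s_iv.start:
                q_iv, s_iv = s_iv, q_iv  # canonical order within one sequence
            hits.append(
                HomologyHit(
                    query=q_iv,
                    subject=s_iv,
                    strand=strand,
                    length=aln.columns,
                    identity=aln.identity,
                )
            )
    return _drop_contained(hits)


def _drop_contained(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Remove duplicates and hits contained in a larger hit on both axes."""

    def contains(a: Interval, b: Interval) -> bool:
        return a.seq_id == b.seq_id and a.start <= b.start and b.end <= a.end

    hits = sorted(set(hits), key=lambda h: (-h.length, h.query, h.subject))
    kept: list[HomologyHit] = []
    for h in hits:
        redundant = any(
            k.strand == h.strand
            and contains(k.query, h.query)
            and contains(k.subject, h.subject)
            for k in kept
        )
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.query, h.subject))
    return kept


def find_repeats(
    genome: Sequence[SequenceRecord],
    min_length: int = 500,
    min_identity: float = 95.0,
) -> list[HomologyHit]:
    """All intra- and inter-chromosome repeats passing the thresholds.

    Each unordered pair of repeat copies is reported once; strand
    "forward" marks direct repeats and "reverse" inverted ones. The
    trivial self-alignment of every chromosome is excluded.
    """
    if not genome:
        raise ValueError("empty genome")
    hits: list[HomologyHit] = []
    for i, qrec in enumerate(genome):
        for j in range(i, len(genome)):
            srec = genome[j]
            hits.extend(
                local_homology_search(
                    qrec, srec, min_length, min_identity, _self=(i == j)
                )
            )
    return _drop_contained(hits)


def find_plastid_inserts(
    mito: Sequence[SequenceRecord],
    plastid: SequenceRecord,
    annotations: Sequence[Interval] = (),
    min_length: int = 100,
    min_identity: float = 90.0,
) -> list[HomologyHit]:
    """Mitochondrial regions of plastid origin (MIPT).

    Mito-vs-plastid local alignments passing the thresholds, minus any
    hit whose mitochondrial interval overlaps an annotated gene
    interval by at least one base.
    """
    hits: list[HomologyHit] = []
    for chrom in mito:
        for h in local_homology_search(chrom, plastid, min_length, min_identity):
            if any(h.query.overlaps(a) for a in annotations):
                continue
            hits.append(h)
    return _drop_contained(hits)


def mask_variants(
    variants: Sequence[VariantRecord],
    mipt_intervals: Sequence[Interval],
    known_seq_ids: Optional[set[str]] = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition variants into (kept, excluded) by plastid-origin regions.

    A variant is excluded when its reference span
    ``[position, position + len(ref))`` overlaps any masked interval
    (half-open: a variant starting exactly at an interval's end is
    kept). Input order is preserved in both lists. If
    ``known_seq_ids`` is given, a variant on any other sequence raises.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in mipt_intervals:
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
    kept: list[VariantRecord] = []
    excluded: list[VariantRecord] = []
    for v in variants:
        if known_seq_ids is not None and v.seq_id not in known_seq_ids:
            raise ValueError(f"variant on unknown sequence {v.seq_id!r}")
        tree = trees.get(v.seq_id)
        if tree is not None and tree.overlap(v.position, v.position + len(v.ref)):
            excluded.append(v)
        else:
            kept.append(v)
    return kept, excluded
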