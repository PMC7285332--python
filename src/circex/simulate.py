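"""Truth-tracked simulation of multipartite circular genomes and long reads.

The generator emulates the structure targeted assembly has to cope
with in plant organelle data: several independent circular
chromosomes, long direct or inverted repeats shared within or between
chromosomes, segments copied from a (simulated) plastid genome into a
mitochondrial chromosome, and low-error long reads sampled uniformly
around each circle, wrapping the origin.

Background sequence is i.i.d. uniform over {A,C,G,T}. Planted
features are copies of real segments with point divergence at a
stated identity, so the homology scanner can be checked against exact
truth coordinates. Reads carry an i.i.d. per-base error model with
independent substitution, insertion and deletion rates — adequate to
exercise identity thresholds, with no homopolymer or instrument bias.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from circex.homology import HomologyHit
from circex.seqio import (
    Interval,
    SequenceRecord,
    reverse_complement,
    write_bed,
    write_sequences,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: CCS/HiFi-like per-base error rates (substitution, insertion, deletion)
DEFAULT_ERROR_RATE = (0.004, 0.0005, 0.0005)
#: read length (mean, sd, min, max) — 5-15 kb long reads
DEFAULT_READ_LENGTH = (10000, 1500, 5000, 15000)


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat to plant: copied segment at a given percent identity."""

    length: int
    identity: float = 100.0
    orientation: str = "direct"     # direct | inverted
    placement: str = "intra"        # intra | inter

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.placement not in ("intra", "inter"):
            raise ValueError(f"bad placement {self.placement!r}")


@dataclass(frozen=True)
class MiptSpec:
    """A plastid-origin insert to plant into one mito chromosome."""

    length: int
    identity: float = 100.0
    chromosome: int = 0             # index into the chromosome list


@dataclass
class ReadOrigin:
    """Where one simulated read truly comes from."""

    read_id: str
    chrom_id: str
    start: int                      # 0-based start on the (circular) source
    strand: str                     # "+" | "-"
    length: int                     # error-free template length
    n_errors: int


@dataclass
class SimulatedGenome:
    chromosomes: list[SequenceRecord]
    plastid: SequenceRecord
    planted_repeats: list[HomologyHit]
    planted_mipts: list[HomologyHit]
    seed: int
    circular: bool = True

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequences(self.chromosomes, outdir / "genome.fasta")
        write_sequences([self.plastid], outdir / "plastid.fasta")
        if self.planted_repeats:
            write_bed([h.query for h in self.planted_repeats], outdir / "repeats.bed")
        if self.planted_mipts:
            write_bed([h.query for h in self.planted_mipts], outdir / "mipt.bed")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("feature\tquery\tsubject\tstrand\tlength\tidentity\n")
            for kind, hits in (
                ("repeat", self.planted_repeats),
                ("mipt", self.planted_mipts),
            ):
                for h in hits:
                    fh.write(
                        f"{kind}\t{h.query.seq_id}:{h.query.start}-{h.query.end}"
                        f"\t{h.subject.seq_id}:{h.subject.start}-{h.subject.end}"
                        f"\t{h.strand}\t{h.length}\t{h.identity:g}\n"
                    )


@dataclass
class SimulatedReadSet:
    reads: list[SequenceRecord]
    origins: list[ReadOrigin]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _diverge(rng: np.random.Generator, segment: str, identity: float) -> str:
    """Substitute bases so the copy matches the original at identity%.

    The number of substitutions is exact (``round(n * (1 - id/100))``),
    not binomial, so a feature planted at 96% cannot drift below a 95%
    detection threshold by sampling noise.
    """
    n_sub = int(round(len(segment) * (1.0 - identity / 100.0)))
    if n_sub <= 0:
        return segment
    codes = np.frombuffer(segment.encode(), dtype=np.uint8).copy()
    hit = np.zeros(codes.size, dtype=bool)
    hit[rng.choice(codes.size, size=n_sub, replace=False)] = True
    # replace each hit base with one of the other three
    shift = rng.integers(1, 4, size=n_sub)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    old = lut[codes[hit]]
    codes[hit] = _BASES[(old + shift) % 4]
    return codes.tobytes().decode()


def _place(
    rng: np.random.Generator,
    occupied: dict[int, list[tuple[int, int]]],
    chrom_lengths: Sequence[int],
    chrom: int,
    length: int,
    margin: int = 200,
    tries: int = 1000,
) -> int:
    """Pick a start for a feature of *length* on *chrom* avoiding other
    planted features (with a margin so features stay distinct)."""
    limit = chrom_lengths[chrom] - length
    if limit <= 0:
        raise ValueError(
            f"feature of {length} bp does not fit chromosome of "
            f"{chrom_lengths[chrom]} bp"
        )
    for _ in range(tries):
        start = int(rng.integers(0, limit))
        span = (start - margin, start + length + margin)
        if all(
            span[1] <= s or e <= span[0] for s, e in occupied.get(chrom, [])
        ):
            occupied.setdefault(chrom, []).append((start, start + length))
            return start
    raise ValueError("could not place feature without overlap; genome too crowded")


def simulate_genome(
    lengths: Sequence[int],
    repeat_spec: Sequence[RepeatSpec | tuple] = (),
    mipt_spec: Sequence[MiptSpec | tuple] = (),
    seed: int = 0,
    plastid_length: int = 30000,
    circular: bool = True,
) -> SimulatedGenome:
    """Generate a multipartite genome with planted repeats and MIPTs.

    ``lengths`` gives one circular chromosome per entry. Repeats are
    planted by copying a segment (with point divergence down to the
    stated identity) either within one chromosome (``intra``) or from
    the first to the second chromosome (``inter``); ``inverted``
    repeats are reverse-complemented copies. MIPT segments are copied
    from the simulated plastid into the stated chromosome. All planted
    coordinates are recorded as truth.
    """
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    repeat_spec = [r if isinstance(r, RepeatSpec) else RepeatSpec(*r) for r in repeat_spec]
    mipt_spec = [m if isinstance(m, MiptSpec) else MiptSpec(*m) for m in mipt_spec]
    rng = np.random.default_rng(seed)
    chrom_seqs = [bytearray(_random_dna(rng, l), "ascii") for l in lengths]
    plastid = SequenceRecord(id="plastid", sequence=_random_dna(rng, plastid_length))
    occupied: dict[int, list[tuple[int, int]]] = {}
    planted_repeats: list[HomologyHit] = []
    planted_mipts: list[HomologyHit] = []

    for spec in repeat_spec:
        if spec.placement == "inter" and len(lengths) < 2:
            raise ValueError("inter-chromosome repeat needs >= 2 chromosomes")
        src_chrom = 0
        dst_chrom = 1 if spec.placement == "inter" else 0
        src = _place(rng, occupied, lengths, src_chrom, spec.length)
        dst = _place(rng, occupied, lengths, dst_chrom, spec.length)
        segment = chrom_seqs[src_chrom][src : src + spec.length].decode()
        copy = _diverge(rng, segment, spec.identity)
        if spec.orientation == "inverted":
            copy = reverse_complement(copy)
        chrom_seqs[dst_chrom][dst : dst + spec.length] = copy.encode()
        q = Interval(f"chr{src_chrom + 1}", src, src + spec.length)
        s = Interval(f"chr{dst_chrom + 1}", dst, dst + spec.length)
        if (q.seq_id, q.start) > (s.seq_id, s.start):
            q, s = s, q
        planted_repeats.append(
            HomologyHit(
                query=q,
                subject=s,
                strand="forward" if spec.orientation == "direct" else "reverse",
                length=spec.length,
                identity=spec.identity,
            )
        )

    for spec in mipt_spec:
        if not (0 <= spec.chromosome < len(lengths)):
            raise ValueError(f"no chromosome index {spec.chromosome}")
        if spec.length > plastid_length:
            raise ValueError("MIPT longer than the plastid genome")
        p_start = int(rng.integers(0, plastid_length - spec.length + 1))
        dst = _place(rng, occupied, lengths, spec.chromosome, spec.length)
        segment = plastid.sequence[p_start : p_start + spec.length]
        copy = _diverge(rng, segment, spec.identity)
        chrom_seqs[spec.chromosome][dst : dst + spec.length] = copy.encode()
        planted_mipts.append(
            HomologyHit(
                query=Interval(f"chr{spec.chromosome + 1}", dst, dst + spec.length),
                subject=Interval("plastid", p_start, p_start + spec.length),
                strand="forward",
                length=spec.length,
                identity=spec.identity,
            )
        )

    chromosomes = [
        SequenceRecord(id=f"chr{i + 1}", sequence=bytes(s).decode())
        for i, s in enumerate(chrom_seqs)
    ]
    return SimulatedGenome(
        chromosomes=chromosomes,
        plastid=plastid,
        planted_repeats=planted_repeats,
        planted_mipts=planted_mipts,
        seed=seed,
        circular=circular,
    )


def _apply_errors(
    rng: np.random.Generator, template: str, error_rate: tuple[float, float, float]
) -> tuple[str, int]:
    sub, ins, dele = error_rate
    if sub == ins == dele == 0:
        return template, 0
    codes = np.frombuffer(template.encode(), dtype=np.uint8)
    n = codes.size
    r = rng.random(n)
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    out = codes.copy()
    sub_mask = r < sub
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        out[sub_mask] = _BASES[(lut[out[sub_mask]] + shift) % 4]
    del_mask = (r >= sub) & (r < sub + dele)
    ins_mask = rng.random(n) < ins
    n_errors = int(sub_mask.sum() + del_mask.sum() + ins_mask.sum())
    if not (del_mask.any() or ins_mask.any()):
        return out.tobytes().decode(), n_errors
    pieces: list[bytes] = []
    ins_positions = np.nonzero(ins_mask)[0]
    ins_bases = _BASES[rng.integers(0, 4, size=ins_positions.size)]
    keep = ~del_mask
    prev = 0
    for pos, base in zip(ins_positions, ins_bases):
        chunk = out[prev : pos + 1][keep[prev : pos + 1]]
        pieces.append(chunk.tobytes() + bytes([base]))
        prev = pos + 1
    pieces.append(out[prev:][keep[prev:]].tobytes())
    return b"".join(pieces).decode(), n_errors


def simulate_reads(
    genome: SimulatedGenome,
    coverage: float = 50.0,
    read_length: tuple[float, float, int, int] = DEFAULT_READ_LENGTH,
    error_rate: tuple[float, float, float] = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> SimulatedReadSet:
    """Sample long reads from every chromosome of a simulated genome.

    Start positions are uniform on each circle (reads wrap the
    origin); on a linear genome (``genome.circular`` false) starts are
    uniform over positions where the read fits. Strands are uniform,
    lengths truncated-normal, and per-base errors i.i.d. at the stated
    (substitution, insertion, deletion) rates. Per-read truth is
    recorded. Deterministic given the seed.
    """
    mean, sd, lo, hi = read_length
    if not (lo <= mean <= hi):
        raise ValueError("read length bounds must satisfy min <= mean <= max")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    origins: list[ReadOrigin] = []
    counter = 0
    for chrom in genome.chromosomes:
        L = len(chrom.sequence)
        n_reads = max(1, int(round(coverage * L / mean)))
        doubled = chrom.sequence + chrom.sequence
        for _ in range(n_reads):
            length = int(np.clip(round(rng.normal(mean, sd)), lo, hi))
            length = min(length, L)
            if genome.circular:
                start = int(rng.integers(0, L))
                template = doubled[start : start + length]
            else:
                # fragments of a linear molecule are clipped at its
                # termini, so read ends pile up exactly on the ends
                s0 = int(rng.integers(lo - length, L - lo + 1))
                start = max(0, s0)
                end = min(L, s0 + length)
                length = end - start
                template = chrom.sequence[start:end]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                template = reverse_complement(template)
            seq, n_errors = _apply_errors(rng, template, error_rate)
            counter += 1
            read_id = f"read{counter}_{chrom.id}"
            reads.append(SequenceRecord(id=read_id, sequence=seq))
            origins.append(
                ReadOrigin(
                    read_id=read_id,
                    chrom_id=chrom.id,
                    start=start,
                    strand=strand,
                    length=length,
                    n_errors=n_errors,
                )
            )
    return SimulatedReadSet(reads=reads, origins=origins)
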