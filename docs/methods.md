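# Methods

## Scope and model of the data

circex targets the assembly situation typical of plant organelle
genomes sequenced with low-error long reads (PacBio CCS/HiFi-grade,
< 1% error, 5–15 kb): one or several *circular* molecules present at
high copy number inside a whole-genome read set dominated by nuclear
sequence, with long repeats shared within and between molecules and
with stretches of plastid DNA integrated into mitochondrial
chromosomes (MIPT). The package does four things around that
situation: enrich reads for organellar origin (median k-mer copy
filter), assemble a target molecule by iterative 3' extension from a
seed, scan assemblies for repeats and plastid-origin inserts, and
mask variant calls that fall into plastid-origin regions.

## The extension loop

A contig starts as a user-supplied seed — a contig from another
assembler or a single read. Each iteration:

1. **Edge mapping.** Every read (both strands) is mapped against the
   last `edge_size` bases of the contig (default 15,000). Candidate
   placements come from exact 13-mer seeds clustered by diagonal
   (band 50, gap 500; at least 5 co-linear seeds, which a genuine
   multi-kilobase anchor always has and chance k-mer collisions never
   do). The placement is verified by aligning the edge-window suffix
   against the read semi-globally (edlib); identity is matches over
   all alignment columns, gaps included. A read is accepted iff
   identity ≥ `min_read_similarity` (default 99%), the aligned read
   part is ≥ `min_mapped_part` (default 8,000 bp), the alignment
   reaches the window's 3' terminus (±`end_slack`, 10 bp, absorbing
   terminal indel wobble), and the read continues past it. The
   defaults are the run parameters appropriate for ~10 kb CCS reads
   at deep coverage; all are exposed on the CLI.

2. **Overhang consensus.** Accepted overhangs (read suffixes past the
   contig end, in contig orientation) are clustered greedily by
   common-prefix identity. Two overhangs co-cluster at
   `2·min_read_similarity − 100` percent (floored at 80): each read
   may individually deviate from the true sequence by
   `100 − min_read_similarity`, so the read-vs-read tolerance is
   twice the read-vs-contig one (triangle inequality). Within a
   cluster the longest overhang anchors a star alignment; every
   member votes per anchor column (member insertions relative to the
   anchor create no column and are dropped; deletions vote "gap").
   Plurality wins a column, ties broken A<C<G<T for determinism; a
   gap wins only with a strict majority of the column's votes, and
   the column is then omitted. The consensus stops at the first
   column covered by fewer than `min_support` members.

3. **Branch protection.** Committing past a divergence point on thin
   evidence silently locks the minority branch's reads out (their
   anchors then mismatch the appended unique tail), so two
   truncations cap the winning consensus before it is appended:
   *conflicted columns* — a runner-up symbol with ≥ 2 votes and
   ≥ `fork_fraction` of the column's coverage marks a divergence
   buried inside the cluster (short-crossing reads co-cluster with
   the majority because their common prefix dominates the identity;
   the first ten columns are exempt, since ±1–2 bp wobble in the
   overhang split point produces systematic double votes there);
   *departing members* — a member whose sequence past its exact
   common prefix with the consensus aligns at near-random identity
   (< 80% over ≥ 20 bp) marks a branch seen by a single read, unlike
   an isolated error which is followed by renewed agreement; and
   *competing clusters* — the consensus is cut at the longest common
   prefix with any credible alternative cluster (two or more members,
   or a singleton that truly diverges). Extension beyond a branch can
   therefore only happen at the branch point itself, where overhang
   support is full and the fork test is decisive.

4. **Fork test.** If at least two clusters each hold
   ≥ `fork_fraction` (default 0.2) of the total overhang support and
   ≥ `min_support` reads, the run stops and reports every qualifying
   alternative with its support, so the user can restart from a
   chosen branch. An alternative that cannot reach these bars even at
   zero distance from the branch is treated as a minor variant and
   the majority is followed.

5. **Circularity.** The contig is circular when a suffix of
   ≥ `circular_min_overlap` bp (default 1,000) aligns to a prefix at
   ≥ `min_read_similarity` with both termini anchored. Candidate
   junctions come from exact 21-mer seeds of the prefix found again
   near the end (several prefix offsets are probed so an error near
   position 0 cannot hide the junction); each candidate is verified
   by global alignment. On success the duplicated suffix is trimmed,
   so the returned sequence covers the circle exactly once. Status
   precedence per iteration is circularized > fork > dead_end >
   extended.

6. **Coverage dips.** The `min_support` column truncation makes any
   position spanned (with a full `min_mapped_part` anchor plus
   overhang) by fewer than `min_support` reads an absolute barrier:
   overhang coverage at a column never exceeds the number of reads
   spanning that position. At modest coverage such positions exist —
   for 8–12 kb reads with an 8 kb anchor at 50× the expected spanning
   support is ~10 but its minimum around a 30 kb circle is 1–4 in
   nearly every simulation. When the fully supported consensus is
   empty, the loop therefore *bridges*: it appends at most
   `bridge_step` (500) bases at a reduced per-column floor of
   `min_extension_coverage` (default 1, i.e. the locally deepest
   reads carry the contig across the dip). Bridged stretches are
   short and rare, so their contribution to consensus error is
   bounded; a dead end is declared only when no read overhangs the
   end at all.

Everything in the loop is deterministic: identical reads and
configuration reproduce identical contigs, histories and logs.

### Parameter defaults and coverage scaling

`min_read_similarity` 99%, `min_mapped_part` 8,000 bp and `edge_size`
15,000 bp are the appropriate settings for deep (several-hundred-fold)
organellar CCS coverage and are the package defaults. `min_support`
defaults to 5, which at such coverage is a tiny fraction of the
overhanging reads. At desk-scale coverage (the 50× used throughout the
test fixtures) the equivalent support threshold must scale with
coverage; the fixtures and the acceptance script use `min_support` 3.
For reads carrying ~1% errors a 99% mapping threshold is
self-contradictory (half of all reads fall below it against a perfect
reference, and all of them against a read-derived starter), so noisy
fixtures map at 97% — twice the read error rate plus margin — and
start from an error-free 10 kb slice, mirroring real usage where
starters come from a prior assembly.

## Median k-mer copy filter

Canonical k-mers (lexicographic minimum of k-mer and reverse
complement) are counted across the read set with overlapping
occurrences; k-mers containing N are skipped. A read's statistic is
the median of its k-mers' copy numbers (even count → mean of the
central pair); reads with median ≥ `min_median` (default 5) are
retained, so a read exactly at the threshold stays. The classic
fraction rule (discard when ≥ 80% of k-mers are below the threshold)
is available as `mode="fraction"`. k defaults to 15 — long enough to
be specific at organelle scale, small enough that the packed 2-bit
table stays trivial in memory. Reads shorter than k (or all-N) have no
median and are dropped with a warning, tallied separately in the
report.

## Homology scanning

Repeats and MIPT are local alignments filtered purely by minimum
length and minimum identity — no e-value model. Defaults: repeats
500 bp / 95%, MIPT 100 bp / 90%; a MIPT hit overlapping an annotated
mitochondrial protein-coding or RNA gene interval by ≥ 1 bp is
suppressed (shared genes such as *atp*/*rrn* and plastid-like tRNAs
are homologous without being inserts — the caller supplies the
annotation intervals). The search seeds with exact 11-mers (hits at
90% identity still seed densely), clusters them into co-linear
diagonal bands (band 30, gap 200), pads each band by 50 bp, aligns
the padded windows globally, and extracts the best-scoring local
stretch of the alignment path (match +1, mismatch −2.5, gap −3.5,
maximum-sum run). This recovers planted features with boundary error
≤ ~10 bp across simulations while scoring random background negative
(break-even identity ≈ 71%). Hits contained in a larger hit on both
axes are dropped; within one sequence each repeat pair is reported
once (query interval first) and the trivial self-alignment is
excluded. The scanner is deliberately not BLAST-bit-exact; the
contract is the threshold filter.

Variant masking partitions a call set by overlap of the reference
span `[POS, POS+len(REF))` with the supplied plastid-origin intervals
(half-open; a variant starting exactly at an interval end is kept),
preserving order and passing record attributes through untouched.

## The simulator

`simulate_genome` builds i.i.d.-uniform background chromosomes plus a
separate plastid sequence, then plants features by copy-with-
divergence: the substitution count is exact
(`round(n·(1−identity/100))`), not binomial, so a feature planted at
96% cannot drift below a 95% detection threshold by sampling noise.
Repeats are direct or reverse-complemented copies, within one
chromosome or from the first to the second; MIPT segments are copied
from the plastid. Placements avoid other planted features by ≥ 200 bp.
All truth coordinates are recorded.

`simulate_reads` samples starts uniformly on each circle (reads wrap
the origin), strands uniformly, lengths truncated-normal (default
10 ± 1.5 kb in [5, 15] kb), and applies i.i.d. per-base substitution/
insertion/deletion errors (default 0.4%/0.05%/0.05%, CCS-like ~0.5%
total). On linear molecules reads are clipped at the termini, as
fragmentation of a linear molecule produces — read ends pile up
exactly on the molecule ends, which is what lets an assembler
terminate at the true terminus. Per-read origins (chromosome, start,
strand, error count) are recorded; everything is deterministic given
the seed.

What the simulator does **not** emulate: homopolymer-biased or
context-dependent error profiles, chimeric reads, coverage biases,
heteroplasmy or structural-variant mixtures, GC skew. Tests passing
on this generator show the algorithms implement their contracts
(thresholds, consensus, termination, truth recovery); they do not
certify performance on instrument-specific artefacts.

## Test and acceptance problem sizes

Fixtures use 30 kb circles (or two 25 kb circles sharing a 20 kb
repeat) at 50× with 8–12 kb reads — large enough that every parameter
(8 kb anchor, 15 kb window, 1 kb circular overlap) is exercised at
its real value, small enough that a full round trip runs in about a
minute on one core. Unit-scale assemblies use 12 kb circles with
3–5 kb reads and proportionally scaled anchors. The k-mer filter
oracle check runs 200 × 2 kb reads at k=21 against naive counting.

## Known limitations

* No polishing: consensus errors appended during low-coverage
  bridging are never revisited (~1% of bridged columns at 1% read
  error; bridges are rare and ≤ 500 bp each).
* Star-alignment consensus drops member insertions relative to the
  anchor; at CCS-like indel rates the effect on consensus accuracy is
  below the bridging contribution.
* The homology scanner reports alignment columns as hit length; for
  gapped hits this differs slightly from either interval's span.
* `check_circular` assumes the terminal duplication is at most half
  the contig; a starter already containing the whole circle twice is
  not recognised.
* Fork reporting stops the run; restarting from a chosen branch is a
  manual step (the alternatives are in the log and the return value).
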