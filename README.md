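# circex

Targeted seed-and-extend assembly of circular organelle genomes from
long low-error reads, with the surrounding workflow: k-mer based read
enrichment, repeat and plastid-insert detection, and variant masking.

## The problem

Plant mitochondrial genomes often exist not as one "master circle"
but as several independent circular chromosomes, interconverting
through recombination at long repeats. General-purpose assemblers
tend to collapse or join such molecules, so a claim like "this
mitogenome is ten separate circles" needs an independent check: take
a seed sequence from each candidate molecule and extend it read by
read; if the extension closes on itself without ever meeting an
ambiguous branch, the molecule is a real, distinct circle. circex
implements that check for PacBio CCS/HiFi-grade reads (5–15 kb,
< 1% error), together with the steps around it:

* **downsample** — whole-genome read sets are mostly nuclear; a read's
  *median k-mer copy number* across the set separates high-copy
  organellar reads (median ≫ 1) from single-copy nuclear ones
  (median ≈ 1). Reads with median < 5 are discarded by default.
* **assemble** — iterative 3'-extension from a starter (a contig or a
  single read), described below.
* **repeats / mipt** — local-alignment scans with pure length/identity
  cut-offs (repeats: ≥ 500 bp, ≥ 95%; mitochondrial inserts of
  plastid origin: ≥ 100 bp, ≥ 90%, suppressed where they overlap
  annotated mitochondrial genes).
* **mask-variants** — plastid reads piling onto plastid-origin regions
  of the mitogenome produce spurious calls there; this partitions a
  VCF into calls outside/inside those regions.
* **simulate** — a truth-tracked generator of multipartite circular
  genomes, planted repeats/inserts and long reads, used by the test
  suite and usable for your own sanity checks.

## The extension loop

Given contig *c* and read set *R*, each iteration:

1. maps every read (both strands) to the last *w* bases of *c*
   (default *w* = 15,000), accepting read *r* iff its alignment
   identity ≥ *s* (default 99%), its aligned part ≥ *m* bp (default
   8,000), and it reaches the contig's 3' terminus and continues past
   it — the unaligned suffix is the read's *overhang*;
2. clusters overhangs by prefix similarity and takes a column-
   plurality consensus per cluster, truncated at the first column
   supported by fewer than *k* reads (default *k* = 5) and at any
   point where a credible minority of reads departs from the
   majority (so the contig never commits through a branch on thin
   evidence);
3. stops with status **fork** if two or more clusters each hold
   ≥ 20% of the overhang support (a repeat-mediated branch point; all
   alternatives are reported so the run can be restarted on a chosen
   branch), **circularized** if a ≥ 1 kb suffix of *c* aligns to its
   prefix at ≥ *s*% (the duplicated overlap is trimmed), **dead_end**
   if no read overhangs the end, and otherwise appends the winning
   consensus and repeats.

The loop is fully deterministic. See `docs/methods.md` for the
consensus details, the branch-protection rules, the low-coverage
bridging behavior and the parameter/coverage scaling discussion.

## Worked example

Simulate a 30 kb circular chromosome with a planted 800 bp repeat
(97% identity) and a 1.2 kb plastid insert, sample 50× of error-free
8–12 kb reads, and assemble the circle back from a single read:

```
$ circex simulate --chromosomes 30000 --repeat 800:97:direct:intra \
    --mipt 1200:95:1 --coverage 50 --read-mean 10000 --read-sd 1000 \
    --read-min 8000 --read-max 12000 --error 0 --seed 7 -o sim/
wrote genome (1 chromosome(s)) and 150 reads to sim

$ cat sim/truth.tsv
feature	query	subject	strand	length	identity
repeat	chr1:14616-15416	chr1:24110-24910	forward	800	97
mipt	chr1:8819-10019	plastid:6033-7233	forward	1200	95

$ seqkit head -n 1 sim/reads.fastq | seqkit fq2fa > starter.fasta
$ circex assemble --starter starter.fasta --reads sim/reads.fastq \
    --minimum-read-similarity 99 --minimum-length-of-mapped-read-part 8000 \
    --contig-edge-size-to-use-for-mapping 15000 --minimum-support 3 \
    -o contig.fasta --log-tsv log.tsv
contig1: circularized, 30000 bp, circular=true
```

The assembled length equals the 30,000 bp truth: the terminal overlap
that proved circularity has been trimmed, and the FASTA header
records `circular=true`. The TSV log has one row per iteration —
status, contig length, supporting reads, and rejection tallies (the
`low_identity` rejections here are reads from the other copy of the
97% repeat, correctly refused at the 99% threshold). A `fork` outcome
instead prints every alternative extension with its read support.

Scanning the simulated genome recovers both planted features at their
truth coordinates:

```
$ circex repeats sim/genome.fasta --tsv repeats.tsv
1 repeat pair(s) at >= 500 bp, >= 95.0% identity
$ cat repeats.tsv
query_seq	query_start	query_end	subject_seq	subject_start	subject_end	strand	length	identity
chr1	14616	15416	chr1	24110	24910	forward	801	97.00

$ circex mipt sim/genome.fasta sim/plastid.fasta --bed mipt.bed
1 plastid-origin insert(s)
$ cat mipt.bed
chr1	8819	10019
```

`mask-variants` then splits a VCF by those intervals
(`circex mask-variants calls.vcf --regions mipt.bed --kept kept.vcf
--excluded excluded.vcf`), keeping calls outside plastid-origin
regions and writing the rest to the excluded file, headers intact.

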