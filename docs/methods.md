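# Methods

## The container model

A container is a sequence of independently compressed, record-aligned
blocks plus an explicit index. The design assumption is minimal: the
underlying compressor is a black box that maps a byte string to a byte
string and back. Splittability is obtained entirely by *where* the file is
cut, never by *how* it is compressed, so the compression behaviour of any
wrapped tool — including specialized FASTA/Q compressors whose field-wise
modelling has been benchmarked elsewhere — is preserved exactly.

Chunking is greedy: whole records are appended while the chunk stays
within the target uncompressed block size (default 8 MiB, configurable);
a single record larger than the target gets a chunk of its own. Chunks are
record-aligned even though nothing in the block machinery requires it:
this makes every block independently *parseable*, so a worker never has to
stitch a partial record across blocks. The cost is at most one record of
slack per block, negligible at read-file record sizes.

The index stores four fields — codec format id, block count, the list of
compressed block sizes, and the maximum uncompressed block size (the
decompression buffer bound; we store the maximum actual chunk size, which
also covers the oversized-record case). It is serialized at the end of the
file with a fixed-size trailer pointing to it, enabling single-pass
writing; all integers are fixed-width 64-bit little-endian, and the magic
appears both at file start and in the trailer so truncation is detected
cheaply. There are no per-block checksums in v1: corruption surfaces as a
codec failure or a size-sum mismatch (header + blocks + index + trailer
must equal the file size, checked on every open).

Byte offsets are 0-based and ranges half-open throughout.

## Parsing and boundary scanning

FASTQ is strict 4-line; wrapped FASTQ is rejected, which keeps record-
boundary confirmation decidable with bounded look-ahead. The boundary
scanner (`find_record_start`) confirms a candidate `@` line structurally:
its own 4-line group must be complete and valid, and a 4-line parse from
there must stay consistent to the end of the buffer (a record cut short by
the buffer end is tolerated in the tail, never in the candidate itself).
This resolves the classic ambiguity of quality lines that begin with `@`:
of two adjacent candidates, only the one whose structure validates
recursively survives. The synthetic quality model deliberately includes
`@` so this path is exercised routinely, not incidentally.

Letter counting is case-insensitive over {A, C, G, T, N}; other symbols
are ignored. Counts are element-wise additive, which is what makes
per-split partial counts combinable without coordination.

Line terminator is LF; CRLF input is accepted (CR stripped from parsed
fields), and since containers carry raw byte ranges, round trips remain
byte-exact either way.

## Codecs

Built-ins are the identity codec ("store", id 0) and the standard-library
family — deflate (zlib level 6, id 1), bzip2 (level 9, id 2), xz (preset
1, id 3) — plus zstd (id 4) and lz4 (id 5) when their bindings are
importable. Levels are fixed so per-block output is deterministic; xz uses
a fast preset because the container's value is splittability, not squeezing
the last percent from a generic codec — heavier compression belongs to the
wrapped specialized tools. Ids ≥ 16 are reserved for user-configured
external codecs.

External tools run per block, either through standard streams or through
temporary files in a RAM-backed directory (`/dev/shm`) when one exists,
falling back silently to the system temporary directory — correctness
never depends on the fast path. Non-deterministic compressed output
(e.g. timestamps in headers) is tolerated: equality is always asserted
after decompression, never on compressed bytes, except for tools that are
documented deterministic.

## Split planning

Storage blocks are purely logical — offset arithmetic over one local
file — because replication and transport affect fault tolerance and
scheduling, not correctness. The assignment key is a block's starting
byte; a block starting exactly on a boundary belongs to the storage block
beginning there. A block spanning more than two storage blocks (possible
with the tiny layouts used in tests) generalizes p1/p2 to p1..pk, all
owned by the start's split. Header and index bytes belong to no split.
Test and demo configurations shrink the storage-block size (kilobytes
instead of 128 MiB) so straddling occurs at desk scale; all engine results
are invariant to this parameter, which is asserted, not assumed.

## Engine

Each split is one unit of work. Worker pools use process-level parallelism
(fork start method where available); partial results are reduced in
ascending split order, and since payloads are integer counts the totals
are bit-stable and invariant to worker count, strategy, storage-block size
and codec. Task 2's map phase emits one count vector per record — the
literal reading of per-sequence emission — so the emitted-item count (the
shuffle volume) equals the record count; this is reported because the
number of map tasks, hence splits, is what drives shuffle cost at cluster
scale. Wall-clock timings are recorded for reporting but never asserted.

## Metrics

`space_savings_hdfs_blocks` uses ceiling division by the storage-block
size ("128 MB" is interpreted as 128 MiB, the usual convention, and is
configurable); `space_savings_bytes` is the plain byte ratio;
`overhead(CS, CH) = CH/CS − 1` may be negative; `speedup > 1` is a win.
Rendering follows the usual table style — integer percent for savings,
two-decimal percent for overhead, two-decimal ratios — as presentation
only; the underlying values are exact floats.

## Synthetic data

The generator emulates two dataset shapes: a fixed number of reads
sampled uniformly at random from a synthetic reference (size-controlled
files), and reads at a stated fold-coverage (1.6×, 14.4×, 26.6× are the
reference points), where `n_reads = ⌈coverage · reference_length /
read_length⌉` and coverage controls redundancy. Defaults: uniform
A/C/G/T with 1% N, read length 100, uniform Phred 0–40 qualities
(including `@`). Every operation draws from an independent substream
keyed by `(seed, operation tag)` via NumPy seed sequences, so output is
byte-identical across runs and platforms.

What the generator does **not** emulate: real base composition and GC
structure, sequencing error profiles, duplicate-read structure beyond
coverage, quality-score correlation along reads, and real-data scale
(reference files of tens of GB are emulated in shape only). Passing tests
therefore demonstrate the container/planner/engine contracts and the
redundancy *trend* under coverage, not the absolute compression ratios a
specialized compressor achieves on real data — those require the real
tools and datasets.

## Problem sizes

The test suite and the reproduction script run at desk scale by choice:
round-trip sweeps use 100 files log-skewed from 0 bytes to 32 MiB,
engine checks use tens-of-KB containers with kilobyte storage blocks to
force straddling, and the overhead comparison uses a 64 MiB FASTQ against
whole-file bzip2 — large enough that block-wise compression at 8 MiB
blocks must sit within 2% of the stand-alone result, small enough to run
anywhere. The worked split-planning layout (8 equal blocks over 4 storage
blocks, CB5 straddling) is reconstructed exactly; with equal blocks and
four equal file partitions, boundaries other than the one inside CB5 also
fall inside blocks — the planner handles them identically, and the split
counts (8 compressed-block, 4 enhanced) are unaffected.

## Known limitations

* No in-place append or update; a container is written in one pass.
* No per-block checksums (v1); corruption detection relies on codec
  failure and the size-sum invariant.
* Only 4-line FASTQ; multi-line FASTA is supported.
* The engine exposes the two letter-counting benchmark tasks rather than
  a general user-defined-function API; the per-record callback pattern in
  `engine._split_records` is the extension point.
* Storage emulation ignores replication, data locality and network
  transport — by design, since they do not affect result correctness.
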