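# fqpack

Splittable block-compressed containers for FASTA/FASTQ data — plus the
machinery that makes them useful: a universal wrapper that turns any
command-line compressor into a splittable codec, input-split planning over
an emulated distributed storage layout, a parallel letter-counting engine,
and the space/time metrics used to benchmark compressed genomic storage.

## The problem

Sequencing read files (FASTA/FASTQ) dominate genomic storage costs, and
specialized sequence compressors beat generic ones by a wide margin. But
distributed processing frameworks can only parallelize over a compressed
file if it is **splittable**: divided into blocks that can be compressed
and decompressed separately, so each worker handles its region of the file
independently. Almost no specialized FASTA/Q compressor is splittable.

`fqpack` solves this without touching any compressor's internals. The
input file is cut into *record-aligned* uncompressed chunks; each chunk is
compressed independently (by a built-in codec or by any external
command-line tool, treated as a black box); and the container stores an
explicit index — codec id, block count, the list of compressed block
sizes, and the maximum uncompressed block size — so a reader can locate
and decompress any block from its byte range and the index alone.

On a distributed file system a stored file is physically partitioned into
fixed-size **storage blocks** (128 MiB by default), which generally do not
line up with the compressed blocks. The split planner emulates that layout
and resolves these *disalignments* two ways:

* **compressed-block strategy** — one input split per compressed block;
* **enhanced strategy** — all compressed blocks *starting* in the same
  storage block form one split, so the split count drops to at most the
  number of storage blocks. A block straddling a boundary stays whole in
  the split of its starting storage block; its remainder (p2) is fetched
  and concatenated with p1 before decompression.

The metrics module computes the standard benchmark quantities: block-
granular space savings `1 − ⌈c/b⌉ / ⌈u/b⌉`, byte-granular savings
`1 − c/u`, the container-vs-stand-alone overhead `CH/CS − 1`, and the
read-time speed-up `t_uncompressed / t_compressed`.

## Worked example

```sh
$ fqpack synth reads.fastq --format fastq --reference-length 100000 \
      --n-reads 5000 --seed 7
$ fqpack compress reads.fastq reads.fqpk --format fastq --codec bzip2 \
      --block-size 256k
wrote reads.fqpk: 5 blocks, codec bzip2 (id 2)
$ fqpack inspect reads.fqpk
format_id       2
payload_format  fastq
target_block_size       262144
block_count     5
max_uncompressed_block_size     262062
compressed_sizes        122920,123095,123117,122577,3036
```

The 1,053,893-byte synthetic FASTQ file (5,000 reads of 100 bases drawn
uniformly at random from a 100 kb reference) became a 494,845-byte
container of 5 independently compressed blocks: the index reports each
block's compressed size and the 262,062-byte decompression buffer bound.

```sh
$ fqpack splits reads.fqpk --strategy enhanced --storage-block-size 128k
split_id        block_ids       straddling
0       0,1     block 1: sb0[122944:131072]+sb1[131072:246039]
1       2       block 2: sb1[246039:262144]+sb2[262144:369156]
2       3       block 3: sb2[369156:393216]+sb3[393216:491733]
3       4      -
```

With 128 KiB emulated storage blocks the enhanced strategy plans 4 splits
for the 5 compressed blocks; blocks 1–3 straddle storage-block boundaries,
and each is kept whole in the split of its starting storage block with the
p1/p2 byte ranges listed.

```sh
$ fqpack bench reads.fqpk --task task2 --strategy enhanced --workers 2
A       124047
C       122287
G       124804
T       123787
N       5075
records 5000
shuffle_items   5000
$ fqpack decompress reads.fqpk restored.fastq
restored 1053893 bytes to restored.fastq
$ cmp reads.fastq restored.fastq && echo IDENTICAL
IDENTICAL
```

Task 2 counts the letters {A, C, G, T, N} with a map phase that emits one
count per record (5,000 emitted items — the shuffle volume) and a reduce
phase that sums them; the round trip restores the input byte-exactly.

External compressors plug in through a YAML config, e.g.

```yaml
codecs:
  - format_id: 16
    name: gz
    compress_cmd: gzip -c -n
    decompress_cmd: gzip -dc
```

passed as `--codec-config codecs.yaml --codec gz`.

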