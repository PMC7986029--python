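"""The splittable block-compressed container format.

A container holds the original FASTA/FASTQ bytes cut into record-aligned
chunks, each chunk compressed independently, plus an explicit index that
lets a reader locate and decompress any block without touching the others.
That independence is the splittability contract: a worker holding one
block's byte range and a copy of the index can reconstruct its part of the
input on its own.

Byte-exact layout (all integers unsigned little-endian)::

    offset 0   magic           4 bytes  b"FQPK"
           4   version         u16      (currently 1)
           6   flags           u16      bit 0: 0 = FASTA payload, 1 = FASTQ
           8   format_id       u64      codec identifier
          16   target size     u64      nominal uncompressed block size
          24   data blocks     compressed blocks, back to back, in order
           D   index           format_id u64, block_count u64,
                               compressed_sizes u64 x block_count,
                               max_uncompressed_block_size u64
         EOF-12 trailer        index offset u64 + magic b"FQPK"

The index repeats the four fields of the container's self-description:
codec format id, number of compressed data blocks, the list of their sizes,
and the size bound needed to allocate the decompression buffer.  Placing it
at the end (found via the fixed-size trailer) permits single-pass writing.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO

from .codecs import (CodecRegistry, CodecSpec, compress_block_bytes,
                     decompress_block_bytes, default_registry)
from .errors import CodecError, FormatError
from .seqio import SeqFormat, record_spans

__all__ = [
    "MAGIC",
    "HEADER_SIZE",
    "TRAILER_SIZE",
    "DEFAULT_TARGET_BLOCK_SIZE",
    "BlockIndex",
    "ContainerLayout",
    "ContainerHeader",
    "chunk_records",
    "write_container",
    "read_header",
    "read_index",
    "decompress_block",
    "decompress_container",
]

MAGIC = b"FQPK"
VERSION = 1
HEADER_SIZE = 24
TRAILER_SIZE = 12
FLAG_FASTQ = 0x1
DEFAULT_TARGET_BLOCK_SIZE = 8 * 1024 * 1024  # 8 MiB

_HEADER = struct.Struct("<4sHHQQ")
_TRAILER = struct.Struct("<Q4s")
_U64 = struct.Struct("<Q")


@dataclass(frozen=True)
class BlockIndex:
    """The explicit container index (four fields, see module docstring)."""

    format_id: int
    block_count: int
    compressed_sizes: tuple[int, ...]
    max_uncompressed_block_size: int

    def __post_init__(self) -> None:
        if len(self.compressed_sizes) != self.block_count:
            raise FormatError(
                f"index lists {len(self.compressed_sizes)} block sizes but "
                f"declares {self.block_count} blocks")
        if self.block_count > 0 and min(self.compressed_sizes) < 1:
            raise FormatError("compressed block sizes must be >= 1")

    def serialize(self) -> bytes:
        out = bytearray()
        out += _U64.pack(self.format_id)
        out += _U64.pack(self.block_count)
        for size in self.compressed_sizes:
            out += _U64.pack(size)
        out += _U64.pack(self.max_uncompressed_block_size)
        return bytes(out)

    @classmethod
    def parse(cls, buf: bytes) -> "BlockIndex":
        if len(buf) < 24:
            raise FormatError("index buffer too short")
        format_id = _U64.unpack_from(buf, 0)[0]
        block_count = _U64.unpack_from(buf, 8)[0]
        expect = 16 + 8 * block_count + 8
        if len(buf) != expect:
            raise FormatError(
                f"index declares {block_count} blocks, so it should occupy "
                f"{expect} bytes, but {len(buf)} are present")
        sizes = tuple(
            _U64.unpack_from(buf, 16 + 8 * i)[0] for i in range(block_count))
        max_size = _U64.unpack_from(buf, 16 + 8 * block_count)[0]
        return cls(format_id, block_count, sizes, max_size)

    @property
    def serialized_size(self) -> int:
        return 16 + 8 * self.block_count + 8

    @property
    def data_size(self) -> int:
        return sum(self.compressed_sizes)


@dataclass(frozen=True)
class ContainerHeader:
    format_id: int
    flags: int
    target_block_size: int

    @property
    def format(self) -> SeqFormat:
        return SeqFormat.FASTQ if self.flags & FLAG_FASTQ else SeqFormat.FASTA


@dataclass(frozen=True)
class ContainerLayout:
    """Byte ranges of the compressed data blocks, from index prefix sums."""

    data_start_offset: int
    block_ranges: tuple[tuple[int, int], ...]  # (offset, length) half-open

    @classmethod
    def from_index(cls, index: BlockIndex,
                   data_start_offset: int = HEADER_SIZE) -> "ContainerLayout":
        ranges = []
        offset = data_start_offset
        for size in index.compressed_sizes:
            ranges.append((offset, size))
            offset += size
        return cls(data_start_offset, tuple(ranges))

    @property
    def data_end_offset(self) -> int:
        if not self.block_ranges:
            return self.data_start_offset
        off, length = self.block_ranges[-1]
        return off + length


# ---------------------------------------------------------------------------
# chunking


def chunk_records(data: bytes, format: SeqFormat | str,
                  target_block_size: int) -> list[bytes]:
    """Cut ``data`` into record-aligned chunks of at most the target size.

    Whole records are packed greedily while the chunk stays within
    ``target_block_size``; a single record longer than the target gets a
    chunk of its own.  The concatenation of the chunks equals ``data``
    byte-exactly.
    """
    if target_block_size < 1:
        raise ValueError("target_block_size must be >= 1")
    spans = record_spans(data, format)
    chunks: list[bytes] = []
    chunk_start = None
    chunk_end = None
    for start, end in spans:
        size = end - start
        if chunk_start is None:
            chunk_start, chunk_end = start, end
            continue
        if (chunk_end - chunk_start) + size <= target_block_size:
            chunk_end = end
        else:
            chunks.append(data[chunk_start:chunk_end])
            chunk_start, chunk_end = start, end
    if chunk_start is not None:
        chunks.append(data[chunk_start:chunk_end])
    return chunks


# ---------------------------------------------------------------------------
# writing


def write_container(input_path: str | Path, format: SeqFormat | str,
                    codec: CodecSpec, out_path: str | Path,
                    target_block_size: int = DEFAULT_TARGET_BLOCK_SIZE,
                    ) -> BlockIndex:
    """Pack a FASTA/FASTQ file into a container; returns the index written.

    The per-block decompressions of the output concatenate back to the
    input bytes exactly.
    """
    fmt = SeqFormat.coerce(format)
    data = Path(input_path).read_bytes()
    chunks = chunk_records(data, fmt, target_block_size)
    flags = FLAG_FASTQ if fmt is SeqFormat.FASTQ else 0
    sizes: list[int] = []
    max_uncompressed = 0
    with open(out_path, "wb") as out:
        out.write(_HEADER.pack(MAGIC, VERSION, flags, codec.format_id,
                               target_block_size))
        for ordinal, chunk in enumerate(chunks):
            try:
                blob = compress_block_bytes(codec, chunk)
            except CodecError as exc:
                raise CodecError(
                    f"codec {codec.name!r} failed on block {ordinal}: "
                    f"{exc}") from exc
            out.write(blob)
            sizes.append(len(blob))
            max_uncompressed = max(max_uncompressed, len(chunk))
        index = BlockIndex(codec.format_id, len(chunks), tuple(sizes),
                           max_uncompressed)
        index_offset = HEADER_SIZE + index.data_size
        out.write(index.serialize())
        out.write(_TRAILER.pack(index_offset, MAGIC))
    return index


# ---------------------------------------------------------------------------
# reading


def read_header(container: str | Path | BinaryIO) -> ContainerHeader:
    if hasattr(container, "read"):
        container.seek(0)
        raw = container.read(HEADER_SIZE)
    else:
        with open(container, "rb") as fh:
            raw = fh.read(HEADER_SIZE)
    if len(raw) < HEADER_SIZE:
        raise FormatError("file too short to hold a container header")
    magic, version, flags, format_id, target = _HEADER.unpack(raw)
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r} at file start")
    if version != VERSION:
        raise FormatError(f"unsupported container version {version}")
    return ContainerHeader(format_id, flags, target)


def read_index(container: str | Path) -> BlockIndex:
    """Parse and validate the index of a container file.

    Checks: both magics, the trailer, index-size consistency, and the
    size-sum invariant (header + blocks + index + trailer == file size).
    """
    path = Path(container)
    file_size = path.stat().st_size
    if file_size < HEADER_SIZE + TRAILER_SIZE:
        raise FormatError(
            f"file is {file_size} bytes, too short for header and trailer")
    with open(path, "rb") as fh:
        header = read_header(fh)
        fh.seek(file_size - TRAILER_SIZE)
        trailer = fh.read(TRAILER_SIZE)
        if len(trailer) != TRAILER_SIZE:
            raise FormatError("truncated trailer")
        index_offset, magic = _TRAILER.unpack(trailer)
        if magic != MAGIC:
            raise FormatError(f"bad magic {magic!r} in trailer")
        if not HEADER_SIZE <= index_offset <= file_size - TRAILER_SIZE:
            raise FormatError(
                f"trailer points the index at offset {index_offset}, "
                f"outside the file body")
        fh.seek(index_offset)
        index_bytes = fh.read(file_size - TRAILER_SIZE - index_offset)
    index = BlockIndex.parse(index_bytes)
    if index.format_id != header.format_id:
        raise FormatError(
            f"header format id {header.format_id} != index format id "
            f"{index.format_id}")
    expect = HEADER_SIZE + index.data_size + index.serialized_size \
        + TRAILER_SIZE
    if expect != file_size:
        raise FormatError(
            f"size-sum check failed: header + blocks + index + trailer = "
            f"{expect} bytes but the file has {file_size}")
    return index


def decompress_block(block_bytes: bytes, index: BlockIndex, i: int,
                     registry: CodecRegistry | None = None) -> bytes:
    """Decompress the ``i``-th block from its own byte range alone.

    Consumes only ``block_bytes`` plus the index — the splittability
    contract; no other part of the container is touched.
    """
    if not 0 <= i < index.block_count:
        raise FormatError(
            f"block ordinal {i} out of range [0, {index.block_count})")
    if len(block_bytes) != index.compressed_sizes[i]:
        raise FormatError(
            f"block {i} should be {index.compressed_sizes[i]} bytes, got "
            f"{len(block_bytes)}")
    reg = registry if registry is not None else default_registry()
    spec = reg.lookup(index.format_id)
    return decompress_block_bytes(
        spec, block_bytes, size_hint=index.max_uncompressed_block_size)


def decompress_container(container: str | Path,
                         out_path: str | Path,
                         registry: CodecRegistry | None = None) -> int:
    """Restore the original file; returns the number of bytes written."""
    index = read_index(container)
    layout = ContainerLayout.from_index(index)
    written = 0
    with open(container, "rb") as src, open(out_path, "wb") as dst:
        for i, (offset, length) in enumerate(layout.block_ranges):
            src.seek(offset)
            blob = src.read(length)
            try:
                chunk = decompress_block(blob, index, i, registry)
            except CodecError as exc:
                raise CodecError(
                    f"failed to decompress block {i}: {exc}") from exc
            dst.write(chunk)
            written += len(chunk)
    return written
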