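"""Input-split planning over an emulated distributed-block layout.

A distributed file system stores a file as fixed-size *storage blocks*
(128 MiB by default).  The container's compressed data blocks generally do
not line up with those boundaries, so a compressed block can be cut into
parts living in different storage blocks — a *disalignment*.  This module
emulates the storage partitioning with plain offset arithmetic on one local
file and plans the unit of work handed to each worker:

* **compressed-block strategy** — every compressed data block becomes its
  own input split;
* **enhanced strategy** — all compressed blocks *starting* in the same
  storage block are grouped into one split, so the number of splits drops
  to at most the number of storage blocks.  A block straddling a boundary
  stays whole in the split of its starting storage block; its remainder
  (p2) is flagged so the owner can fetch and concatenate it before
  decompressing.

A block whose start falls exactly on a boundary belongs to the storage
block beginning there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .container import ContainerLayout
from .errors import PlanningError

__all__ = [
    "DEFAULT_STORAGE_BLOCK_SIZE",
    "StorageLayout",
    "InputSplit",
    "Strategy",
    "plan_splits",
    "split_block_parts",
    "fetch_split_bytes",
]

DEFAULT_STORAGE_BLOCK_SIZE = 128 * 1024 * 1024  # 128 MiB

STRATEGIES = ("compressed_block", "enhanced")
Strategy = str


@dataclass(frozen=True)
class StorageLayout:
    """Fixed-size partitioning of a file into emulated storage blocks."""

    storage_block_size: int
    file_size: int

    def __post_init__(self) -> None:
        if self.storage_block_size < 1:
            raise ValueError("storage_block_size must be >= 1")
        if self.file_size < 0:
            raise ValueError("file_size must be >= 0")

    @property
    def n_storage_blocks(self) -> int:
        return -(-self.file_size // self.storage_block_size)

    def storage_block_of(self, offset: int) -> int:
        """Owning storage block of a byte offset (boundary ties go right)."""
        return offset // self.storage_block_size

    def boundaries(self) -> list[int]:
        """Interior boundary offsets k * storage_block_size."""
        return [k * self.storage_block_size
                for k in range(1, self.n_storage_blocks)]


@dataclass(frozen=True)
class InputSplit:
    """One worker's unit of work: an ordered group of compressed blocks.

    ``parts`` maps each straddling block id to its sub-ranges
    ``(storage_block_id, (offset, length))`` in file order — p1, p2 (and
    further parts when a block spans more than two storage blocks).
    """

    split_id: int
    block_ids: tuple[int, ...]
    parts: dict[int, tuple[tuple[int, tuple[int, int]], ...]] = \
        field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.block_ids:
            raise ValueError("a split must hold at least one block")
        if list(self.block_ids) != sorted(self.block_ids):
            raise ValueError("block_ids must be ascending")


def split_block_parts(layout: StorageLayout,
                      block_range: tuple[int, int],
                      ) -> list[tuple[int, tuple[int, int]]]:
    """Partition one block's byte range by the storage-block boundaries.

    Returns ``(storage_block_id, (offset, length))`` pieces whose lengths
    sum to the block length.  A block starting exactly on a boundary is
    owned by the storage block starting there, yielding a single part.
    """
    offset, length = block_range
    if length < 1:
        raise PlanningError(f"empty block range at offset {offset}")
    parts = []
    pos = offset
    end = offset + length
    bsize = layout.storage_block_size
    while pos < end:
        sb = pos // bsize
        sb_end = (sb + 1) * bsize
        piece_end = min(end, sb_end)
        parts.append((sb, (pos, piece_end - pos)))
        pos = piece_end
    return parts


def plan_splits(layout: StorageLayout, container_layout: ContainerLayout,
                strategy: Strategy = "enhanced") -> list[InputSplit]:
    """Plan the input splits for one container under a storage layout.

    ``compressed_block`` yields exactly one split per compressed data
    block.  ``enhanced`` yields one split per storage block that contains
    at least one block start, each compressed block going to the split of
    the storage block holding its starting byte.  Every block appears in
    exactly one split, in file order.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; "
                         f"expected one of {STRATEGIES}")
    ranges = container_layout.block_ranges
    if not ranges:
        return []
    if container_layout.data_end_offset > layout.file_size:
        raise PlanningError(
            f"container data section ends at byte "
            f"{container_layout.data_end_offset} but the storage layout "
            f"covers only {layout.file_size} bytes")

    def parts_for(block_id: int):
        parts = split_block_parts(layout, ranges[block_id])
        return tuple(parts) if len(parts) > 1 else None

    splits: list[InputSplit] = []
    if strategy == "compressed_block":
        for block_id in range(len(ranges)):
            p = parts_for(block_id)
            splits.append(InputSplit(
                split_id=block_id, block_ids=(block_id,),
                parts={block_id: p} if p else {}))
        return splits

    # enhanced: group by the storage block containing each block's start
    groups: dict[int, list[int]] = {}
    for block_id, (offset, _length) in enumerate(ranges):
        groups.setdefault(layout.storage_block_of(offset), []).append(
            block_id)
    for split_id, sb in enumerate(sorted(groups)):
        block_ids = tuple(groups[sb])
        parts = {}
        for block_id in block_ids:
            p = parts_for(block_id)
            if p:
                parts[block_id] = p
        splits.append(InputSplit(split_id, block_ids, parts))
    return splits


def fetch_split_bytes(container: str | Path, split: InputSplit,
                      container_layout: ContainerLayout,
                      ) -> dict[int, bytes]:
    """Read the complete compressed bytes of every block in a split.

    Straddling blocks are read part by part (p1, p2, ...) and concatenated
    in order, emulating the owner pulling the remainder from the storage
    block holding it; the result is byte-equal to a direct read of the
    block's full range.
    """
    out: dict[int, bytes] = {}
    with open(container, "rb") as fh:
        for block_id in split.block_ids:
            if block_id in split.parts:
                pieces = []
                for _sb, (offset, length) in split.parts[block_id]:
                    fh.seek(offset)
                    pieces.append(fh.read(length))
                out[block_id] = b"".join(pieces)
            else:
                offset, length = container_layout.block_ranges[block_id]
                fh.seek(offset)
                out[block_id] = fh.read(length)
    return out
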