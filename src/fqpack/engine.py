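"""Parallel map / map-reduce execution over input splits.

Two benchmark tasks are built in, both counting the nucleotide letters
{A, C, G, T, N} over the records of a container:

* **task 1** (map-only): each worker decompresses the blocks of its split,
  parses the records and accumulates one partial count; the total is the
  sum of the partials.  No data moves between workers.
* **task 2** (map + reduce): the map phase emits one per-record count for
  every record it sees; the reduce phase groups by letter and sums.  The
  number of emitted items is the shuffle volume — it equals the record
  count, which is why fewer, larger splits reduce communication in a real
  cluster.

Results are pure integer sums reduced in split order, so they are
bit-stable and invariant to worker count, split strategy, storage block
size and codec.
"""

from __future__ import annotations

import hashlib
import multiprocessing
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .codecs import CodecRegistry, default_registry
from .container import ContainerLayout, decompress_block, read_index
from .errors import FqpackError
from .seqio import LetterCounts, SeqFormat, count_letters, iter_records
from .splitter import (DEFAULT_STORAGE_BLOCK_SIZE, StorageLayout,
                       fetch_split_bytes, plan_splits)

__all__ = [
    "LetterCounts",
    "TaskResult",
    "Task2Result",
    "IndexBroadcast",
    "broadcast_index",
    "run_task1",
    "run_task2",
]


@dataclass(frozen=True)
class TaskResult:
    """Per-split outcome: the task payload plus bookkeeping counters."""

    split_id: int
    payload: Any
    records_processed: int
    bytes_read: int


@dataclass(frozen=True)
class Task2Result:
    total: LetterCounts
    emitted_items: int  # shuffle volume: one item per record
    partials: tuple[TaskResult, ...]


@dataclass(frozen=True)
class IndexBroadcast:
    """Acknowledgment that every worker holds the full index.

    Emulates distributing the index through the framework's configuration
    channel before any block is processed; each worker acknowledges with a
    digest of the serialized index, and all digests must agree.
    """

    digest: str
    acks: tuple[str, ...]

    @property
    def acknowledged(self) -> bool:
        return bool(self.acks) and all(a == self.digest for a in self.acks)


def broadcast_index(index, workers: int) -> IndexBroadcast:
    if workers < 1:
        raise ValueError("workers must be >= 1")
    digest = hashlib.sha256(index.serialize()).hexdigest()
    return IndexBroadcast(digest, tuple(digest for _ in range(workers)))


# ---------------------------------------------------------------------------
# split-level map functions (top level so they pickle for worker processes)


def _split_records(args):
    container, split, index, layout, registry, fmt = args
    blocks = fetch_split_bytes(container, split, layout)
    records = []
    bytes_read = 0
    for block_id in split.block_ids:
        blob = blocks[block_id]
        bytes_read += len(blob)
        try:
            chunk = decompress_block(blob, index, block_id, registry)
        except FqpackError as exc:
            raise FqpackError(
                f"split {split.split_id}, block {block_id}: {exc}") from exc
        records.extend(iter_records(chunk, fmt))
    return records, bytes_read


def _map_task1(args) -> TaskResult:
    split = args[1]
    records, bytes_read = _split_records(args)
    counts = LetterCounts()
    for rec in records:
        counts += count_letters(rec.sequence)
    return TaskResult(split.split_id, counts, len(records), bytes_read)


def _map_task2(args) -> TaskResult:
    split = args[1]
    records, bytes_read = _split_records(args)
    emitted = tuple(count_letters(rec.sequence).as_tuple()
                    for rec in records)
    return TaskResult(split.split_id, emitted, len(records), bytes_read)


# ---------------------------------------------------------------------------
# drivers


def _prepare(container, strategy, workers, storage_block_size, registry):
    if workers < 1:
        raise ValueError("workers must be >= 1")
    reg = registry if registry is not None else default_registry()
    index = read_index(container)
    layout = ContainerLayout.from_index(index)
    storage = StorageLayout(storage_block_size,
                            Path(container).stat().st_size)
    splits = plan_splits(storage, layout, strategy)
    broadcast_index(index, workers)  # index reaches workers before any block
    return reg, index, layout, splits


def _run_mapper(mapper, container, splits, index, layout, reg, fmt,
                workers: int) -> list[TaskResult]:
    args = [(str(container), split, index, layout, reg, fmt)
            for split in splits]
    if workers == 1 or len(args) <= 1:
        results = [mapper(a) for a in args]
    else:
        method = "fork" if "fork" in multiprocessing.get_all_start_methods() \
            else None
        ctx = multiprocessing.get_context(method)
        with ctx.Pool(processes=min(workers, max(1, len(args)))) as pool:
            results = pool.map(mapper, args)
    return sorted(results, key=lambda r: r.split_id)


def run_task1(container: str | Path, format: SeqFormat | str,
              strategy: str = "enhanced", workers: int = 1,
              storage_block_size: int = DEFAULT_STORAGE_BLOCK_SIZE,
              registry: CodecRegistry | None = None,
              ) -> tuple[LetterCounts, list[TaskResult]]:
    """Map-only letter counting; returns (total, per-split partials)."""
    fmt = SeqFormat.coerce(format)
    reg, index, layout, splits = _prepare(
        container, strategy, workers, storage_block_size, registry)
    partials = _run_mapper(_map_task1, container, splits, index, layout,
                           reg, fmt, workers)
    total = LetterCounts()
    for part in partials:
        total += part.payload
    return total, partials


def run_task2(container: str | Path, format: SeqFormat | str,
              strategy: str = "enhanced", workers: int = 1,
              storage_block_size: int = DEFAULT_STORAGE_BLOCK_SIZE,
              registry: CodecRegistry | None = None) -> Task2Result:
    """Map + reduce letter counting.

    The map phase emits one count vector per record; the reduce phase
    groups by letter and sums.  The total equals task 1's total, and the
    emitted-item count (the shuffle volume) equals the number of records.
    """
    fmt = SeqFormat.coerce(format)
    reg, index, layout, splits = _prepare(
        container, strategy, workers, storage_block_size, registry)
    partials = _run_mapper(_map_task2, container, splits, index, layout,
                           reg, fmt, workers)
    # reduce: group the emitted per-record items by letter and sum
    sums = [0, 0, 0, 0, 0]
    emitted = 0
    for part in partials:
        for item in part.payload:
            emitted += 1
            for k in range(5):
                sums[k] += item[k]
    return Task2Result(LetterCounts.from_tuple(sums), emitted,
                       tuple(partials))
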