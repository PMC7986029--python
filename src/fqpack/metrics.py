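"""Space-savings, overhead and speed-up formulas, and benchmark tables.

The quantities:

* block-granular space savings ``1 - blocks(F') / blocks(F)`` where
  ``blocks(x) = ceil(x / storage_block_size)`` — what compression buys on a
  distributed file system that allocates whole storage blocks (128 MiB
  each by default);
* byte-granular space savings ``1 - bytes(F') / bytes(F)``;
* container overhead ``CH / CS - 1`` where CS is the stand-alone
  compressor's whole-file output and CH the block-wise container for the
  same data — the price of splittability, which is near zero for local
  compressors (bzip2 works on ~900 KB chunks internally) and grows with
  global strategies that exploit whole-file redundancy;
* read-time speed-up ``t_uncompressed / t_compressed`` (> 1 is a win).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "DEFAULT_HDFS_BLOCK_SIZE",
    "MetricsInput",
    "storage_blocks",
    "space_savings_hdfs_blocks",
    "space_savings_bytes",
    "overhead",
    "speedup",
    "experiment_report",
    "render_report",
]

DEFAULT_HDFS_BLOCK_SIZE = 128 * 1024 * 1024  # "128 MB" as 128 MiB


@dataclass(frozen=True)
class MetricsInput:
    """Measured sizes for one (dataset, codec) cell.

    ``uncompressed_size`` is the original file F, ``container_size`` the
    splittable container F', ``standalone_compressed_size`` CS and
    ``container_compressed_size`` CH.  Unused fields may stay None.
    """

    uncompressed_size: int | None = None
    container_size: int | None = None
    standalone_compressed_size: int | None = None
    container_compressed_size: int | None = None
    t_uncompressed: float | None = None
    t_compressed: float | None = None

    def __post_init__(self) -> None:
        for name in ("uncompressed_size", "container_size",
                     "standalone_compressed_size",
                     "container_compressed_size"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


def storage_blocks(nbytes: int, storage_block_size: int) -> int:
    """Number of fixed-size storage blocks a file occupies (ceiling)."""
    if storage_block_size < 1:
        raise ValueError("storage_block_size must be >= 1")
    return math.ceil(nbytes / storage_block_size)


def space_savings_hdfs_blocks(
        uncompressed_size: int, compressed_size: int,
        storage_block_size: int = DEFAULT_HDFS_BLOCK_SIZE) -> float:
    """1 - blocks(compressed) / blocks(uncompressed), ceiling division."""
    if uncompressed_size < 1:
        raise ValueError("uncompressed_size must be >= 1")
    return 1.0 - (storage_blocks(compressed_size, storage_block_size)
                  / storage_blocks(uncompressed_size, storage_block_size))


def space_savings_bytes(uncompressed_size: int,
                        compressed_size: int) -> float:
    """1 - bytes(compressed) / bytes(uncompressed)."""
    if uncompressed_size < 1:
        raise ValueError("uncompressed_size must be >= 1")
    return 1.0 - compressed_size / uncompressed_size


def overhead(standalone_size: int, container_size: int) -> float:
    """CH / CS - 1; may be negative when the container is smaller."""
    if standalone_size < 1:
        raise ValueError("standalone_size must be >= 1")
    return container_size / standalone_size - 1.0


def speedup(t_uncompressed: float, t_compressed: float) -> float:
    """t_uncompressed / t_compressed; > 1 denotes a speed-up."""
    if t_compressed <= 0:
        raise ValueError("t_compressed must be > 0")
    return t_uncompressed / t_compressed


_METRICS = ("savings_blocks", "savings_bytes", "overhead", "speedup")


def _cell_value(metric: str, m: MetricsInput,
                storage_block_size: int) -> float:
    if metric == "savings_blocks":
        return space_savings_hdfs_blocks(
            m.uncompressed_size, m.container_size, storage_block_size)
    if metric == "savings_bytes":
        return space_savings_bytes(m.uncompressed_size, m.container_size)
    if metric == "overhead":
        return overhead(m.standalone_compressed_size,
                        m.container_compressed_size)
    if metric == "speedup":
        return speedup(m.t_uncompressed, m.t_compressed)
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def experiment_report(
        measurements: Mapping[tuple[str, str], MetricsInput],
        metric: str,
        storage_block_size: int = DEFAULT_HDFS_BLOCK_SIZE) -> pd.DataFrame:
    """Benchmark-style table: datasets on rows, codecs on columns.

    ``measurements`` maps ``(dataset, codec)`` to a :class:`MetricsInput`;
    cells hold the requested metric as a float (savings and overhead as
    fractions, speed-up as a ratio).  Missing cells become NaN.
    """
    datasets: list[str] = []
    codecs: list[str] = []
    for dataset, codec in measurements:
        if dataset not in datasets:
            datasets.append(dataset)
        if codec not in codecs:
            codecs.append(codec)
    df = pd.DataFrame(index=datasets, columns=codecs, dtype=float)
    for (dataset, codec), m in measurements.items():
        df.loc[dataset, codec] = _cell_value(metric, m, storage_block_size)
    df.index.name = "dataset"
    return df


def render_report(df: pd.DataFrame, metric: str,
                  style: str = "tsv") -> str:
    """Format a report the way the benchmark tables print their cells:
    integer percent for savings, two-decimal percent for overhead, and a
    two-decimal ratio for speed-up.  ``style`` is ``tsv`` or ``markdown``.
    """
    if metric in ("savings_blocks", "savings_bytes"):
        fmt = lambda v: "" if pd.isna(v) else f"{round(v * 100):d}%"
    elif metric == "overhead":
        fmt = lambda v: "" if pd.isna(v) else f"{v * 100:.2f}%"
    elif metric == "speedup":
        fmt = lambda v: "" if pd.isna(v) else f"{v:.2f}"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    shown = df.map(fmt)
    if style == "markdown":
        return shown.to_markdown()
    if style == "tsv":
        return shown.to_csv(sep="\t").rstrip("\n")
    raise ValueError(f"unknown style {style!r}")
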