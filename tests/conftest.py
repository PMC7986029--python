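"""Shared fixtures and builders for the fqpack test suite."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from fqpack.codecs import default_registry
from fqpack.container import write_container
from fqpack.seqio import SeqFormat, SequenceRecord, write_records
from fqpack.synthdata import (DatasetSpec, generate_dataset,
                              generate_reference, sample_reads)

settings.register_profile(
    "fqpack",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fqpack")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_dataset(seed: int, fmt: str = "fastq", n_reads: int = 100,
                 reference_length: int = 2000,
                 read_length: int = 50) -> bytes:
    """Small deterministic synthetic dataset (default quality model, so
    FASTQ output contains '@'-initial quality lines)."""
    return generate_dataset(DatasetSpec(
        reference_length=reference_length, read_length=read_length,
        n_reads=n_reads, format=SeqFormat.coerce(fmt), seed=seed))


def make_container(tmp_path: Path, data: bytes, fmt: str,
                   codec_name: str = "deflate",
                   target_block_size: int = 1024,
                   stem: str = "data"):
    """Write data to disk, pack it, and return (container_path, index,
    input_path)."""
    reg = default_registry()
    input_path = tmp_path / f"{stem}.{fmt}"
    input_path.write_bytes(data)
    container = tmp_path / f"{stem}.fqpk"
    index = write_container(input_path, fmt, reg.lookup_name(codec_name),
                            container, target_block_size=target_block_size)
    return container, index, input_path


def fixed_width_fasta_records(n: int, record_size: int,
                              seed: int = 0) -> list[SequenceRecord]:
    """n FASTA records of exactly record_size bytes each when serialized
    unwrapped: '>rNN\\n' + sequence + '\\n'."""
    assert n < 100, "two-digit ids keep the record size fixed"
    header = 5  # '>' + 'rNN' + '\n'
    seq_len = record_size - header - 1
    assert seq_len > 0
    reference = generate_reference(max(1000, seq_len * 4), seed=seed)
    reads = sample_reads(reference, seq_len, n, seed=seed)
    return [SequenceRecord(f"r{i + 1:02d}", r.sequence)
            for i, r in enumerate(reads)]


def build_worked_layout_container(tmp_path: Path, seed: int = 0):
    """A container reproducing the worked example layout: a header, a
    footer and 8 equal compressed data blocks, laid over 4 equal emulated
    storage blocks so that block CB5 straddles a storage-block boundary.

    Uses the store codec and 16 fixed-width FASTA records (2 per block) so
    the 8 compressed blocks are 100 bytes each.  Returns (container_path,
    index, storage_block_size).
    """
    records = fixed_width_fasta_records(16, 50, seed=seed)
    data = write_records(records)
    assert len(data) == 800
    container, index, _ = make_container(
        tmp_path, data, "fasta", codec_name="store",
        target_block_size=100, stem="worked")
    assert index.block_count == 8
    assert set(index.compressed_sizes) == {100}
    file_size = container.stat().st_size
    storage_block_size = -(-file_size // 4)  # 4 equal storage blocks
    return container, index, storage_block_size
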