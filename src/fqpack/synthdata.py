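"""Seeded synthetic FASTA/FASTQ dataset generation.

Two dataset shapes are produced, mirroring how read collections differ in
practice:

* **type 1** — a fixed number of reads extracted uniformly at random from
  a synthetic reference; file size is controlled by the read count.
* **type 2** — reads drawn at a stated fold-coverage of the reference
  (e.g. 1.6x, 14.4x, 26.6x), which controls redundancy: higher coverage
  re-samples the same reference positions more often, so real codecs
  compress the file increasingly well per read.

Generation is fully deterministic given a seed: every operation derives an
independent substream from ``(seed, operation tag)`` via NumPy's seed
sequences, so files are byte-identical across runs and platforms.  The
default quality model deliberately includes ``@`` (Phred 31) with positive
probability, so generated FASTQ exercises the header/quality-line
ambiguity that boundary scanning must resolve.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import SeqFormat, SequenceRecord, write_records

__all__ = [
    "DatasetSpec",
    "DEFAULT_BASE_COMPOSITION",
    "DEFAULT_QUALITY_SYMBOLS",
    "generate_reference",
    "sample_reads",
    "reads_for_coverage",
    "attach_qualities",
    "generate_dataset",
]

# uniform A/C/G/T with 1% N
DEFAULT_BASE_COMPOSITION: dict[str, float] = {
    "A": 0.2475, "C": 0.2475, "G": 0.2475, "T": 0.2475, "N": 0.01,
}

# Phred 0..40 (+33), a uniform model whose support includes '@' (Phred 31)
DEFAULT_QUALITY_SYMBOLS: bytes = bytes(range(33, 33 + 41))

DEFAULT_READ_LENGTH = 100


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent substream for one operation: keyed by (seed, tag)."""
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  zlib.crc32(tag.encode())])


@dataclass(frozen=True)
class DatasetSpec:
    """Everything needed to regenerate one synthetic dataset."""

    reference_length: int
    read_length: int = DEFAULT_READ_LENGTH
    n_reads: int | None = None
    coverage: float | None = None
    format: SeqFormat = SeqFormat.FASTQ
    base_composition: dict[str, float] = \
        field(default_factory=lambda: dict(DEFAULT_BASE_COMPOSITION))
    quality_symbols: bytes = DEFAULT_QUALITY_SYMBOLS
    quality_probs: tuple[float, ...] | None = None  # None = uniform
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "format", SeqFormat.coerce(self.format))
        if self.read_length > self.reference_length:
            raise ValueError("read_length must be <= reference_length")
        if (self.n_reads is None) == (self.coverage is None):
            raise ValueError("give exactly one of n_reads and coverage")
        if self.coverage is not None and self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        total = sum(self.base_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base composition sums to {total}, not 1")

    def resolved_n_reads(self) -> int:
        if self.n_reads is not None:
            return self.n_reads
        return reads_for_coverage(self.reference_length, self.read_length,
                                  self.coverage)


def generate_reference(length: int,
                       base_composition: dict[str, float] | None = None,
                       seed: int = 0) -> bytes:
    """A random reference sequence with the given base composition."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return b""
    comp = base_composition if base_composition is not None \
        else DEFAULT_BASE_COMPOSITION
    letters = np.frombuffer("".join(comp).encode("ascii"), dtype=np.uint8)
    probs = np.array(list(comp.values()), dtype=float)
    probs = probs / probs.sum()
    rng = _rng(seed, "reference")
    return rng.choice(letters, size=length, p=probs).tobytes()


def reads_for_coverage(reference_length: int, read_length: int,
                       coverage: float) -> int:
    """ceil(coverage * reference_length / read_length)."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length < 1 or reference_length < 1:
        raise ValueError("lengths must be >= 1")
    return math.ceil(coverage * reference_length / read_length)


def sample_reads(reference: bytes, read_length: int, n_reads: int,
                 seed: int = 0, id_prefix: str = "r",
                 format: SeqFormat | str = SeqFormat.FASTA,
                 ) -> list[SequenceRecord]:
    """Reads extracted uniformly at random from the reference.

    Start positions are uniform on ``[0, len(reference) - read_length]``;
    ids are sequential (``r1``, ``r2``, ...).  FASTA records are returned;
    use :func:`attach_qualities` to promote them to FASTQ.
    """
    if read_length > len(reference):
        raise ValueError("read_length exceeds the reference length")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    fmt = SeqFormat.coerce(format)
    if fmt is SeqFormat.FASTQ:
        raise ValueError("sample_reads emits FASTA records; "
                         "attach_qualities converts them to FASTQ")
    rng = _rng(seed, "reads")
    starts = rng.integers(0, len(reference) - read_length + 1, size=n_reads)
    return [
        SequenceRecord(f"{id_prefix}{i + 1}",
                       reference[s:s + read_length])
        for i, s in enumerate(starts)
    ]


def attach_qualities(records: Sequence[SequenceRecord],
                     quality_symbols: bytes = DEFAULT_QUALITY_SYMBOLS,
                     quality_probs: Sequence[float] | None = None,
                     seed: int = 0) -> list[SequenceRecord]:
    """Attach i.i.d. Phred+33 quality strings, making records FASTQ.

    ``quality_probs`` defaults to uniform over ``quality_symbols``.  The
    default symbol set includes ``@``, so generated files contain
    ``@``-initial quality lines with high probability.
    """
    symbols = np.frombuffer(quality_symbols, dtype=np.uint8)
    if quality_probs is not None:
        probs = np.asarray(quality_probs, dtype=float)
        if len(probs) != len(symbols):
            raise ValueError("quality_probs length must match symbols")
        probs = probs / probs.sum()
    else:
        probs = None
    rng = _rng(seed, "qualities")
    total = sum(len(r.sequence) for r in records)
    flat = rng.choice(symbols, size=total, p=probs).tobytes()
    out = []
    pos = 0
    for rec in records:
        n = len(rec.sequence)
        out.append(SequenceRecord(rec.id, rec.sequence,
                                  flat[pos:pos + n], SeqFormat.FASTQ))
        pos += n
    return out


def generate_dataset(spec: DatasetSpec) -> bytes:
    """Generate a complete FASTA/FASTQ file for a dataset spec."""
    reference = generate_reference(spec.reference_length,
                                   spec.base_composition, spec.seed)
    records = sample_reads(reference, spec.read_length,
                           spec.resolved_n_reads(), spec.seed)
    if spec.format is SeqFormat.FASTQ:
        records = attach_qualities(records, spec.quality_symbols,
                                   spec.quality_probs, spec.seed)
    return write_records(records)
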