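"""Byte-level FASTA/FASTQ reading, writing and boundary scanning.

Everything in this module works on raw ``bytes``: the container format
stores verbatim byte ranges of the original file, so record extents must be
expressed as byte spans that tile the input exactly.  Records are the unit
of alignment for compressed blocks — a block always ends at a record
boundary — which is what lets every block be parsed independently of its
neighbours.

Supported formats:

* FASTA: single- or multi-line sequences, ``>`` header lines.
* FASTQ: strict 4-line records (``@`` header, sequence, ``+`` separator,
  quality of equal length).  Wrapped FASTQ is rejected.

Line terminator is LF.  CRLF input is accepted on read (the CR is stripped
from parsed fields) but byte spans always cover the raw bytes, so container
round trips stay byte-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

from .errors import ParseError

__all__ = [
    "SeqFormat",
    "SequenceRecord",
    "LetterCounts",
    "parse_records",
    "record_spans",
    "find_record_start",
    "count_letters",
    "write_records",
]


class SeqFormat(str, Enum):
    FASTA = "fasta"
    FASTQ = "fastq"

    @classmethod
    def coerce(cls, value: "SeqFormat | str") -> "SeqFormat":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA or FASTQ record.

    ``id`` is the full header line without the leading ``>``/``@`` marker
    (description included).  ``quality`` is Phred+33 and present iff the
    record came from FASTQ, in which case it has the sequence's length.
    """

    id: str
    sequence: bytes
    quality: bytes | None = None
    source_format: SeqFormat = SeqFormat.FASTA

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.source_format is SeqFormat.FASTQ:
            if self.quality is None:
                raise ValueError("FASTQ record requires a quality string")
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    "quality length %d != sequence length %d"
                    % (len(self.quality), len(self.sequence))
                )
        elif self.quality is not None:
            raise ValueError("FASTA record must not carry a quality string")


@dataclass
class LetterCounts:
    """Occurrence counts of the nucleotide letters {A, C, G, T, N}.

    Element-wise additive, which is what makes per-split partial counts
    combinable into a total without any cross-worker coordination.
    """

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    n: int = 0

    def __add__(self, other: "LetterCounts") -> "LetterCounts":
        return LetterCounts(
            self.a + other.a,
            self.c + other.c,
            self.g + other.g,
            self.t + other.t,
            self.n + other.n,
        )

    def __iadd__(self, other: "LetterCounts") -> "LetterCounts":
        return self + other

    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.n

    def as_dict(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t,
                "N": self.n}

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.a, self.c, self.g, self.t, self.n)

    @classmethod
    def from_tuple(cls, t: Sequence[int]) -> "LetterCounts":
        return cls(*t)


def count_letters(seq: bytes) -> LetterCounts:
    """Count A/C/G/T/N in ``seq``, case-insensitively.

    Symbols outside {A, C, G, T, N} are ignored.
    """
    u = seq.upper()
    return LetterCounts(
        u.count(b"A"), u.count(b"C"), u.count(b"G"), u.count(b"T"),
        u.count(b"N"),
    )


# ---------------------------------------------------------------------------
# line machinery


def _line_spans(data: bytes) -> list[tuple[int, int]]:
    """Half-open byte spans of lines, newline included in the span."""
    spans = []
    pos = 0
    n = len(data)
    while pos < n:
        nl = data.find(b"\n", pos)
        end = n if nl < 0 else nl + 1
        spans.append((pos, end))
        pos = end
    return spans


def _line_content(data: bytes, span: tuple[int, int]) -> bytes:
    """Line bytes without the trailing LF/CRLF."""
    s, e = span
    line = data[s:e]
    if line.endswith(b"\n"):
        line = line[:-1]
    if line.endswith(b"\r"):
        line = line[:-1]
    return line


# ---------------------------------------------------------------------------
# record spans


def record_spans(data: bytes, format: SeqFormat | str) -> list[tuple[int, int]]:
    """Half-open byte spans of whole records; the spans tile ``data``.

    Raises :class:`ParseError` (with a byte offset) on malformed input.
    """
    fmt = SeqFormat.coerce(format)
    if not data:
        return []
    lines = _line_spans(data)
    if fmt is SeqFormat.FASTQ:
        return _fastq_spans(data, lines)
    return _fasta_spans(data, lines)


def _fastq_spans(data: bytes,
                 lines: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = []
    i = 0
    n = len(lines)
    while i < n:
        hdr = _line_content(data, lines[i])
        if not hdr.startswith(b"@"):
            raise ParseError("FASTQ header line must start with '@'",
                             lines[i][0])
        if i + 3 >= n:
            raise ParseError("truncated FASTQ record", lines[i][0])
        sep = _line_content(data, lines[i + 2])
        if not sep.startswith(b"+"):
            raise ParseError("FASTQ separator line must start with '+'",
                             lines[i + 2][0])
        seq = _line_content(data, lines[i + 1])
        qual = _line_content(data, lines[i + 3])
        if len(qual) != len(seq):
            raise ParseError(
                "FASTQ quality length %d != sequence length %d"
                % (len(qual), len(seq)), lines[i + 3][0])
        spans.append((lines[i][0], lines[i + 3][1]))
        i += 4
    return spans


def _fasta_spans(data: bytes,
                 lines: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not _line_content(data, lines[0]).startswith(b">"):
        raise ParseError("FASTA input must start with a '>' header", 0)
    starts = [lines[i][0] for i in range(len(lines))
              if _line_content(data, lines[i]).startswith(b">")]
    ends = starts[1:] + [len(data)]
    return list(zip(starts, ends))


def parse_records(data: bytes,
                  format: SeqFormat | str) -> list[SequenceRecord]:
    """Parse a whole buffer into records, in file order.

    Multi-line FASTA sequences are concatenated.  Malformed input raises
    :class:`ParseError` carrying the byte offset of the violation.
    """
    fmt = SeqFormat.coerce(format)
    records: list[SequenceRecord] = []
    for start, end in record_spans(data, fmt):
        records.append(_parse_one(data[start:end], fmt, start))
    return records


def _parse_one(raw: bytes, fmt: SeqFormat, base_offset: int) -> SequenceRecord:
    lines = [_line_content(raw, s) for s in _line_spans(raw)]
    header = lines[0][1:]
    if not header:
        raise ParseError("empty record header", base_offset)
    rid = header.decode("ascii", "replace")
    if fmt is SeqFormat.FASTQ:
        return SequenceRecord(rid, lines[1], lines[3], SeqFormat.FASTQ)
    seq = b"".join(lines[1:])
    return SequenceRecord(rid, seq, None, SeqFormat.FASTA)


def iter_records(data: bytes,
                 format: SeqFormat | str) -> Iterator[SequenceRecord]:
    fmt = SeqFormat.coerce(format)
    for start, end in record_spans(data, fmt):
        yield _parse_one(data[start:end], fmt, start)


# ---------------------------------------------------------------------------
# boundary scanning


def find_record_start(buffer: bytes, format: SeqFormat | str,
                      from_offset: int = 0) -> int | None:
    """Smallest offset >= ``from_offset`` that starts a complete record.

    ``buffer`` must begin at a line start.  Returns ``None`` when no record
    starts at or after ``from_offset``.

    For FASTQ a candidate ``@`` line is confirmed structurally: its own
    4-line group must be complete and valid, and the rest of the buffer must
    remain consistent with a 4-line parse from there on (a trailing record
    truncated by the buffer end is tolerated).  This is what disambiguates
    real headers from quality lines that happen to begin with ``@``: of two
    adjacent candidates, only the one whose structure validates recursively
    survives.
    """
    fmt = SeqFormat.coerce(format)
    if from_offset > len(buffer):
        return None
    lines = _line_spans(buffer)
    truncated = not buffer.endswith(b"\n") if buffer else False
    for k, span in enumerate(lines):
        if span[0] < from_offset:
            continue
        content = _line_content(buffer, span)
        if fmt is SeqFormat.FASTA:
            if content.startswith(b">"):
                return span[0]
        else:
            if content.startswith(b"@") and _fastq_valid_from(
                    buffer, lines, k, truncated):
                return span[0]
    return None


def _fastq_valid_from(buffer: bytes, lines: list[tuple[int, int]], k: int,
                      truncated: bool) -> bool:
    """Is a 4-line FASTQ parse starting at line ``k`` consistent to EOF?

    The first group must be complete and fully valid (the candidate must
    start a *complete* record); later groups may be cut short by the buffer
    end, in which case only the constraints that are decidable on the
    available bytes are enforced.
    """
    n = len(lines)
    if k + 3 >= n:
        return False  # candidate's own record must be complete
    i = k
    while i < n:
        if not _line_content(buffer, lines[i]).startswith(b"@"):
            return False
        if i + 2 < n and \
                not _line_content(buffer, lines[i + 2]).startswith(b"+"):
            return False
        if i + 3 < n:
            seq = _line_content(buffer, lines[i + 1])
            qual = _line_content(buffer, lines[i + 3])
            if truncated and i + 3 == n - 1:
                # quality line may be cut short by the buffer end
                if len(qual) > len(seq):
                    return False
            elif len(qual) != len(seq):
                return False
        # a tail group with < 4 lines is a record cut by the buffer end:
        # consistent as far as it is decidable
        i += 4
    return True


# ---------------------------------------------------------------------------
# writing


def write_records(records: Sequence[SequenceRecord],
                  format: SeqFormat | str | None = None,
                  fasta_width: int | None = None) -> bytes:
    """Serialize records back to FASTA/FASTQ bytes.

    ``format`` defaults to the records' own source format.  FASTA sequences
    are written on a single line unless ``fasta_width`` is given.
    """
    out = bytearray()
    for rec in records:
        fmt = SeqFormat.coerce(format) if format is not None \
            else rec.source_format
        rid = rec.id.encode("ascii")
        if fmt is SeqFormat.FASTQ:
            if rec.quality is None:
                raise ValueError(
                    f"record {rec.id!r} has no quality; cannot write FASTQ")
            out += b"@" + rid + b"\n" + rec.sequence + b"\n+\n" \
                + rec.quality + b"\n"
        else:
            out += b">" + rid + b"\n"
            if fasta_width:
                for i in range(0, len(rec.sequence), fasta_width):
                    out += rec.sequence[i:i + fasta_width] + b"\n"
                if not rec.sequence:
                    out += b"\n"
            else:
                out += rec.sequence + b"\n"
    return bytes(out)
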