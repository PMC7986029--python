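"""Exception hierarchy for fqpack.

All package errors derive from :class:`FqpackError` so callers (and the CLI)
can map failures to exit codes: format/parse problems vs codec/process
problems vs planning problems.
"""

from __future__ import annotations


class FqpackError(Exception):
    """Base class for all fqpack errors."""


class ParseError(FqpackError):
    """Malformed FASTA/FASTQ input.

    Carries the byte offset (within the parsed buffer) where the violation
    was detected.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


class FormatError(FqpackError):
    """A container file violates the format contract (bad magic, truncated
    trailer, size-sum mismatch, oversized block, ...)."""


class CodecError(FqpackError):
    """A compression back-end failed."""


class CodecLookupError(CodecError):
    """No codec registered under the requested format id or name."""


class CodecProcessError(CodecError):
    """An external compressor process failed; captured stderr is attached."""

    def __init__(self, message: str, returncode: int | None = None,
                 stderr: bytes = b""):
        detail = message
        if returncode is not None:
            detail += f" (exit code {returncode})"
        if stderr:
            detail += f": {stderr.decode('utf-8', 'replace').strip()}"
        super().__init__(detail)
        self.returncode = returncode
        self.stderr = stderr


class MissingBinaryError(CodecError):
    """The external compressor binary could not be invoked."""


class PlanningError(FqpackError):
    """Storage layout and container layout are mutually inconsistent."""
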