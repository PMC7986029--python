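"""Compression back-ends: built-in block codecs and the universal wrapper.

A codec here is anything that maps a byte string to a byte string and back.
Built-ins use the standard-library bindings (zlib, bz2, lzma) plus zstd/lz4
when their bindings are importable.  Any other compressor is reachable
through the *universal wrapper*: give the pair of command lines that
compress and decompress one file (or one standard-input stream) and the
tool is treated as a black box — its internal compression behaviour is
never touched, which is the whole point: published benchmarking of a
specialized FASTA/Q compressor stays valid when its output is packed into
a splittable container.

Format ids partition the namespace: 0 is the identity ("store") codec,
1–15 are reserved for built-ins, >= 16 for user-configured external tools.
"""

from __future__ import annotations

import bz2
import lzma
import os
import shlex
import subprocess
import tempfile
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import yaml

from .errors import (CodecError, CodecLookupError, CodecProcessError,
                     FormatError, MissingBinaryError)

__all__ = [
    "CodecSpec",
    "CodecRegistry",
    "default_registry",
    "compress_block_bytes",
    "decompress_block_bytes",
    "invoke_external",
    "load_codec_config",
    "EXTERNAL_ID_FLOOR",
]

EXTERNAL_ID_FLOOR = 16

_PLACEHOLDERS = ("{input}", "{output}")


@dataclass(frozen=True)
class CodecSpec:
    """One registered compressor.

    ``kind`` is ``store`` (identity), ``builtin`` (in-process binding) or
    ``external`` (black-box command lines).  External specs in ``tempfile``
    io mode exchange data through files named by the ``{input}`` /
    ``{output}`` placeholders; in ``stream`` mode data flows through the
    process's standard streams.
    """

    format_id: int
    name: str
    kind: str = "builtin"
    compress_cmd: str | None = None
    decompress_cmd: str | None = None
    io_mode: str = "stream"
    timeout: float = 600.0

    def __post_init__(self) -> None:
        if self.format_id < 0:
            raise ValueError("format_id must be non-negative")
        if self.kind not in ("store", "builtin", "external"):
            raise ValueError(f"unknown codec kind {self.kind!r}")
        if self.io_mode not in ("stream", "tempfile"):
            raise ValueError(f"unknown io_mode {self.io_mode!r}")
        if self.kind == "external":
            if not self.compress_cmd or not self.decompress_cmd:
                raise ValueError(
                    "external codec needs both compress_cmd and "
                    "decompress_cmd")
            if self.io_mode == "tempfile":
                for tmpl in (self.compress_cmd, self.decompress_cmd):
                    for ph in _PLACEHOLDERS:
                        if ph not in tmpl:
                            raise ValueError(
                                f"tempfile-mode template {tmpl!r} lacks the "
                                f"{ph} placeholder")


# in-process bindings; levels fixed so per-block output is deterministic
_BUILTIN_IMPLS: dict[str, tuple[Callable[[bytes], bytes],
                                Callable[[bytes], bytes]]] = {
    "deflate": (lambda d: zlib.compress(d, 6), zlib.decompress),
    "bzip2": (lambda d: bz2.compress(d, 9), bz2.decompress),
    "xz": (lambda d: lzma.compress(d, preset=1), lzma.decompress),
}

try:  # optional bindings, mirrored as built-ins only when importable
    import zstandard as _zstd

    _BUILTIN_IMPLS["zstd"] = (
        lambda d: _zstd.ZstdCompressor(level=3).compress(d),
        lambda d: _zstd.ZstdDecompressor().decompress(d),
    )
except ImportError:
    pass

try:
    import lz4.frame as _lz4f

    _BUILTIN_IMPLS["lz4"] = (_lz4f.compress, _lz4f.decompress)
except ImportError:
    pass

_BUILTIN_IDS = {"deflate": 1, "bzip2": 2, "xz": 3, "zstd": 4, "lz4": 5}


class CodecRegistry:
    """Maps format ids (and names) to codec specs; ids are unique."""

    def __init__(self) -> None:
        self._by_id: dict[int, CodecSpec] = {}
        self._by_name: dict[str, CodecSpec] = {}

    def register(self, spec: CodecSpec) -> CodecSpec:
        if spec.format_id in self._by_id:
            raise CodecLookupError(
                f"format id {spec.format_id} already registered "
                f"(as {self._by_id[spec.format_id].name!r})")
        if spec.name in self._by_name:
            raise CodecLookupError(f"codec name {spec.name!r} already "
                                   "registered")
        self._by_id[spec.format_id] = spec
        self._by_name[spec.name] = spec
        return spec

    def lookup(self, format_id: int) -> CodecSpec:
        try:
            return self._by_id[format_id]
        except KeyError:
            raise CodecLookupError(
                f"no codec registered under format id {format_id}") from None

    def lookup_name(self, name: str) -> CodecSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise CodecLookupError(
                f"no codec registered under name {name!r}") from None

    def __iter__(self):
        return iter(sorted(self._by_id.values(),
                           key=lambda s: s.format_id))

    def __contains__(self, format_id: int) -> bool:
        return format_id in self._by_id

    def names(self) -> list[str]:
        return [s.name for s in self]


def default_registry() -> CodecRegistry:
    """Registry holding the identity codec and every available built-in."""
    reg = CodecRegistry()
    reg.register(CodecSpec(0, "store", kind="store"))
    for name, fid in _BUILTIN_IDS.items():
        if name in _BUILTIN_IMPLS:
            reg.register(CodecSpec(fid, name, kind="builtin"))
    return reg


# ---------------------------------------------------------------------------
# block-level (de)compression


def compress_block_bytes(spec: CodecSpec, data: bytes) -> bytes:
    """Compress one block with ``spec``; black box for external tools."""
    if spec.kind == "store":
        return data
    if spec.kind == "builtin":
        comp, _ = _builtin_impl(spec)
        try:
            return comp(data)
        except Exception as exc:  # binding-level failure
            raise CodecError(f"{spec.name} compression failed: {exc}") from exc
    return invoke_external(spec, "compress", data)


def decompress_block_bytes(spec: CodecSpec, data: bytes,
                           size_hint: int | None = None) -> bytes:
    """Decompress one block; ``size_hint`` bounds the expected output.

    ``size_hint`` is the container's max uncompressed block size; output
    exceeding it means the block does not belong to this container and is
    reported as a format error.
    """
    if spec.kind == "store":
        out = data
    elif spec.kind == "builtin":
        _, decomp = _builtin_impl(spec)
        try:
            out = decomp(data)
        except Exception as exc:
            raise CodecError(
                f"{spec.name} decompression failed: {exc}") from exc
    else:
        out = invoke_external(spec, "decompress", data)
    if size_hint is not None and len(out) > size_hint:
        raise FormatError(
            f"decompressed block is {len(out)} bytes, exceeding the "
            f"declared maximum uncompressed block size {size_hint}")
    return out


def _builtin_impl(spec: CodecSpec):
    try:
        return _BUILTIN_IMPLS[spec.name]
    except KeyError:
        raise CodecLookupError(
            f"no built-in implementation for codec {spec.name!r}") from None


# ---------------------------------------------------------------------------
# external process plumbing


def _ram_backed_tmpdir() -> str | None:
    """A memory-backed directory for parking blocks, if the host has one."""
    for cand in ("/dev/shm", "/run/shm"):
        if os.path.isdir(cand) and os.access(cand, os.W_OK):
            return cand
    return None


def invoke_external(spec: CodecSpec, direction: str, data: bytes) -> bytes:
    """Run the external tool once over ``data`` and return its output.

    ``direction`` is ``compress`` or ``decompress``.  Stream mode pipes the
    block through stdin/stdout; tempfile mode parks it as a file in a
    RAM-backed directory when one exists (falling back to the system temp
    dir) and substitutes the ``{input}``/``{output}`` placeholders.
    Temporary files are always removed.
    """
    if spec.kind != "external":
        raise CodecError(f"codec {spec.name!r} is not external")
    if direction == "compress":
        template = spec.compress_cmd
    elif direction == "decompress":
        template = spec.decompress_cmd
    else:
        raise ValueError(f"unknown direction {direction!r}")
    assert template is not None

    if spec.io_mode == "stream":
        argv = shlex.split(template)
        return _run(spec, argv, input_bytes=data)

    base = _ram_backed_tmpdir()
    with tempfile.TemporaryDirectory(prefix="fqpack-", dir=base) as tmpdir:
        in_path = os.path.join(tmpdir, "in.blk")
        out_path = os.path.join(tmpdir, "out.blk")
        Path(in_path).write_bytes(data)
        argv = [tok.replace("{input}", in_path).replace("{output}", out_path)
                for tok in shlex.split(template)]
        _run(spec, argv, input_bytes=None)
        if not os.path.exists(out_path):
            raise CodecProcessError(
                f"{spec.name}: command {template!r} produced no output file")
        return Path(out_path).read_bytes()


def _run(spec: CodecSpec, argv: list[str],
         input_bytes: bytes | None) -> bytes:
    try:
        proc = subprocess.run(
            argv, input=input_bytes, stdout=subprocess.PIPE,
            stderr=subprocess.PIPE, timeout=spec.timeout)
    except FileNotFoundError as exc:
        raise MissingBinaryError(
            f"{spec.name}: cannot invoke {argv[0]!r}: {exc}") from exc
    except subprocess.TimeoutExpired as exc:
        raise CodecProcessError(
            f"{spec.name}: {argv[0]!r} timed out after "
            f"{spec.timeout} s") from exc
    if proc.returncode != 0:
        raise CodecProcessError(f"{spec.name}: {argv[0]!r} failed",
                                returncode=proc.returncode,
                                stderr=proc.stderr)
    return proc.stdout


# ---------------------------------------------------------------------------
# configuration


def load_codec_config(path: str | Path,
                      registry: CodecRegistry | None = None) -> CodecRegistry:
    """Add external codecs from a YAML config file to a registry.

    The file holds a list (or a ``codecs:`` list) of entries with keys
    ``format_id`` (>= 16), ``name``, ``compress_cmd``, ``decompress_cmd``
    and optionally ``io_mode`` (default ``stream``) and ``timeout``.
    """
    reg = registry if registry is not None else default_registry()
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        return reg
    entries = doc.get("codecs", doc) if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise CodecError(f"codec config {path}: expected a list of entries")
    for entry in entries:
        fid = int(entry["format_id"])
        if fid < EXTERNAL_ID_FLOOR:
            raise CodecError(
                f"codec config {path}: external format ids must be >= "
                f"{EXTERNAL_ID_FLOOR}, got {fid}")
        reg.register(CodecSpec(
            format_id=fid,
            name=str(entry["name"]),
            kind="external",
            compress_cmd=str(entry["compress_cmd"]),
            decompress_cmd=str(entry["decompress_cmd"]),
            io_mode=str(entry.get("io_mode", "stream")),
            timeout=float(entry.get("timeout", 600.0)),
        ))
    return reg
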