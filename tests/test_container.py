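"""Container format: chunking, writing, index parsing, block independence."""

from __future__ import annotations

import zlib

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqpack.container import (HEADER_SIZE, TRAILER_SIZE, BlockIndex,
                              ContainerLayout, chunk_records,
                              decompress_block, decompress_container,
                              read_header, read_index)
from fqpack.errors import FormatError
from fqpack.seqio import record_spans, write_records

from conftest import fixed_width_fasta_records, make_container, make_dataset


class TestChunkRecords:
    def test_greedy_packing_worked_example(self):
        # 10 FASTA records of exactly 100 bytes, target 250: greedy packing
        # by record size gives 5 chunks of 200 bytes (2 records each)
        data = write_records(fixed_width_fasta_records(10, 100))
        assert len(data) == 1000
        chunks = chunk_records(data, "fasta", 250)
        assert [len(c) for c in chunks] == [200] * 5

    def test_oversized_record_gets_own_chunk(self):
        data = b">r1\n" + b"A" * 996 + b"\n"
        chunks = chunk_records(data, "fasta", 250)
        assert chunks == [data]

    def test_oversized_record_between_small_ones(self):
        small = b">s\nACGT\n"
        big = b">b\n" + b"G" * 500 + b"\n"
        chunks = chunk_records(small + big + small, "fasta", 100)
        assert chunks == [small, big, small]

    def test_empty_input(self):
        assert chunk_records(b"", "fastq", 100) == []

    @pytest.mark.parametrize("fmt", ["fasta", "fastq"])
    @pytest.mark.parametrize("target", [64, 333, 10_000])
    def test_chunks_tile_input_and_end_on_record_boundaries(self, fmt,
                                                           target):
        data = make_dataset(2, fmt, n_reads=40)
        chunks = chunk_records(data, fmt, target)
        assert b"".join(chunks) == data
        boundaries = {e for _, e in record_spans(data, fmt)}
        pos = 0
        for chunk in chunks:
            pos += len(chunk)
            assert pos in boundaries
            assert len(chunk) <= target or len(
                record_spans(chunk, fmt)) == 1


class TestWriteReadContainer:
    def test_empty_input_round_trips(self, tmp_path):
        container, index, _ = make_container(tmp_path, b"", "fastq")
        assert index.block_count == 0
        assert read_index(container) == index
        out = tmp_path / "restored"
        assert decompress_container(container, out) == 0
        assert out.read_bytes() == b""

    def test_store_codec_data_section_equals_input(self, tmp_path):
        data = make_dataset(4, "fasta", n_reads=30)
        container, index, _ = make_container(tmp_path, data, "fasta",
                                             codec_name="store")
        raw = container.read_bytes()
        data_section = raw[HEADER_SIZE:HEADER_SIZE + index.data_size]
        assert data_section == data

    def test_compressed_sizes_match_independent_compression(self, tmp_path):
        """Oracle: compress each chunk separately with the same codec
        primitive and compare sizes."""
        data = make_dataset(6, "fastq", n_reads=60)
        container, index, _ = make_container(tmp_path, data, "fastq",
                                             codec_name="deflate",
                                             target_block_size=2048)
        assert index.block_count >= 3
        chunks = chunk_records(data, "fastq", 2048)
        expected = tuple(len(zlib.compress(c, 6)) for c in chunks)
        assert index.compressed_sizes == expected

    @pytest.mark.parametrize("codec", ["store", "deflate", "bzip2", "xz"])
    @pytest.mark.parametrize("fmt", ["fasta", "fastq"])
    def test_round_trip_identity(self, tmp_path, codec, fmt):
        data = make_dataset(8, fmt, n_reads=50)
        container, _, _ = make_container(tmp_path, data, fmt,
                                         codec_name=codec)
        out = tmp_path / "restored"
        n = decompress_container(container, out)
        assert n == len(data)
        assert out.read_bytes() == data

    def test_header_records_format_and_target(self, tmp_path):
        data = make_dataset(1, "fastq", n_reads=10)
        container, _, _ = make_container(tmp_path, data, "fastq",
                                         target_block_size=512)
        header = read_header(container)
        assert header.format.value == "fastq"
        assert header.target_block_size == 512

    def test_size_sum_invariant(self, tmp_path):
        data = make_dataset(9, "fasta", n_reads=20)
        container, index, _ = make_container(tmp_path, data, "fasta")
        assert HEADER_SIZE + index.data_size + index.serialized_size \
            + TRAILER_SIZE == container.stat().st_size


class TestIndex:
    def test_serialize_parse_fixpoint(self):
        index = BlockIndex(3, 4, (10, 20, 30, 40), 4096)
        wire = index.serialize()
        assert BlockIndex.parse(wire) == index
        assert BlockIndex.parse(wire).serialize() == wire

    def test_invariant_violations_rejected(self):
        with pytest.raises(FormatError):
            BlockIndex(1, 2, (10,), 100)  # count/list mismatch
        with pytest.raises(FormatError):
            BlockIndex(1, 1, (0,), 100)  # zero-size block

    def test_truncated_trailer_detected(self, tmp_path):
        data = make_dataset(3, "fastq", n_reads=10)
        container, _, _ = make_container(tmp_path, data, "fastq")
        clipped = tmp_path / "clipped.fqpk"
        clipped.write_bytes(container.read_bytes()[:-1])
        with pytest.raises(FormatError):
            read_index(clipped)

    def test_bad_magic_detected(self, tmp_path):
        data = make_dataset(3, "fastq", n_reads=10)
        container, _, _ = make_container(tmp_path, data, "fastq")
        raw = bytearray(container.read_bytes())
        raw[:4] = b"XXXX"
        bad = tmp_path / "bad.fqpk"
        bad.write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_index(bad)

    def test_size_sum_mismatch_detected(self, tmp_path):
        data = make_dataset(3, "fastq", n_reads=10)
        container, _, _ = make_container(tmp_path, data, "fastq")
        raw = container.read_bytes()
        # inject a stray byte between data section and index
        index = read_index(container)
        cut = HEADER_SIZE + index.data_size
        bad = tmp_path / "bad2.fqpk"
        bad.write_bytes(raw[:cut] + b"\x00" + raw[cut:])
        with pytest.raises(FormatError):
            read_index(bad)


class TestBlockDecompression:
    def test_each_block_matches_chunk_oracle(self, tmp_path):
        data = make_dataset(5, "fastq", n_reads=60)
        container, index, _ = make_container(tmp_path, data, "fastq",
                                             target_block_size=2048)
        chunks = chunk_records(data, "fastq", 2048)
        layout = ContainerLayout.from_index(index)
        raw = container.read_bytes()
        for i, (offset, length) in enumerate(layout.block_ranges):
            assert decompress_block(raw[offset:offset + length], index,
                                    i) == chunks[i]

    def test_out_of_range_ordinal(self, tmp_path):
        data = make_dataset(5, "fastq", n_reads=10)
        container, index, _ = make_container(tmp_path, data, "fastq")
        with pytest.raises(FormatError):
            decompress_block(b"x", index, index.block_count)

    def test_independence_from_rest_of_file(self, tmp_path):
        """A block decompressed from a buffer holding only its own byte
        range equals the block decompressed in situ."""
        data = make_dataset(7, "fasta", n_reads=40)
        container, index, _ = make_container(tmp_path, data, "fasta",
                                             target_block_size=1024,
                                             codec_name="bzip2")
        layout = ContainerLayout.from_index(index)
        raw = container.read_bytes()
        for i, (offset, length) in enumerate(layout.block_ranges):
            severed = tmp_path / f"block{i}.bin"
            severed.write_bytes(raw[offset:offset + length])
            isolated = decompress_block(severed.read_bytes(), index, i)
            in_situ = decompress_block(raw[offset:offset + length],
                                       index, i)
            assert isolated == in_situ

    def test_block_ranges_tile_data_section(self, tmp_path):
        data = make_dataset(5, "fastq", n_reads=30)
        container, index, _ = make_container(tmp_path, data, "fastq")
        layout = ContainerLayout.from_index(index)
        pos = HEADER_SIZE
        for offset, length in layout.block_ranges:
            assert offset == pos
            pos += length
        assert pos == HEADER_SIZE + index.data_size


@given(sizes=st.lists(st.integers(1, 1 << 20), max_size=20),
       max_size=st.integers(0, 1 << 22))
@settings(max_examples=50)
def test_index_round_trip_property(sizes, max_size):
    index = BlockIndex(1, len(sizes), tuple(sizes), max_size)
    assert BlockIndex.parse(index.serialize()) == index
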