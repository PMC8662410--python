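"""XDF 1.0 container: bit-exact chunked writer and a fault-tolerant reader.

The extensible data format stores multiple streams in one file as a flat
sequence of chunks:

    "XDF:" magic, then per chunk
    [NumLengthBytes: 1 byte in {1,4,8}]
    [Length: little-endian unsigned int of that width, = len(tag + content)]
    [Tag: 2-byte little-endian]
    [content]

Tags: 1 FileHeader, 2 StreamHeader, 3 Samples, 4 ClockOffset, 5 Boundary,
6 StreamFooter. Stream-scoped chunks (2,3,4,6) begin their content with a
4-byte little-endian stream id. A sample's timestamp is either stored as an
explicit 8-byte double (timestamp-bytes flag 8) or omitted (flag 0), in
which case the reader deduces previous + 1/nominal_srate.

The reader never trusts the file to be complete: a truncated final chunk is
discarded with a warning, unknown tags are skipped, and a missing footer
(recorder killed mid-run) is reported rather than fatal — the samples and
any clock offsets written before the crash all load.
"""

from __future__ import annotations

import os
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import BinaryIO, Sequence

import numpy as np

from .streaming import (
    ClockOffsetRecord,
    OffsetSeries,
    StreamInfo,
    TimedSample,
)

__all__ = [
    "MAGIC",
    "ChunkTag",
    "FooterStats",
    "StreamRecording",
    "XdfRecording",
    "XdfWriter",
    "open_writer",
    "read_xdf",
    "validate_file",
    "XdfFormatError",
]

MAGIC = b"XDF:"


class ChunkTag:
    FILE_HEADER = 1
    STREAM_HEADER = 2
    SAMPLES = 3
    CLOCK_OFFSET = 4
    BOUNDARY = 5
    STREAM_FOOTER = 6


_FORMAT_STRUCT = {"float32": "<f", "double64": "<d", "int32": "<i"}
_FORMAT_DTYPE = {"float32": np.float32, "double64": np.float64, "int32": np.int32}


class XdfFormatError(Exception):
    """The file violates the container format in a non-recoverable way."""


@dataclass
class FooterStats:
    """Per-stream trailing statistics enabling post-hoc synchronization."""

    first_timestamp: float
    last_timestamp: float
    sample_count: int
    measured_srate: float
    offsets: OffsetSeries = field(default_factory=OffsetSeries)


@dataclass
class StreamRecording:
    """One stream as loaded from a file: metadata, data, offsets, footer."""

    stream_id: int
    info: StreamInfo
    values: np.ndarray | list  # (n, channels) array; list of tuples for strings
    timestamps: np.ndarray  # raw source-clock seconds, shape (n,)
    offsets: OffsetSeries
    footer: FooterStats | None = None

    @property
    def sample_count(self) -> int:
        return len(self.timestamps)


@dataclass
class XdfRecording:
    """All streams of one file plus reader warnings."""

    version: str
    streams: dict[int, StreamRecording]
    warnings: list[str] = field(default_factory=list)

    def by_name(self, name: str) -> StreamRecording:
        for s in self.streams.values():
            if s.info.name == name:
                return s
        raise KeyError(f"no stream named {name!r}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _encode_varlen_value(data: bytes) -> bytes:
    """String-format channel value: 1-byte length-width, little-endian length, bytes."""
    n = len(data)
    if n <= 0xFF:
        return b"\x01" + struct.pack("<B", n) + data
    if n <= 0xFFFFFFFF:
        return b"\x04" + struct.pack("<I", n) + data
    return b"\x08" + struct.pack("<Q", n) + data


def _info_to_xml(info: StreamInfo) -> bytes:
    root = ET.Element("info")
    for tag, val in (
        ("name", info.name),
        ("type", info.stream_type),
        ("channel_count", str(info.channel_count)),
        ("nominal_srate", repr(float(info.nominal_srate))),
        ("channel_format", info.channel_format),
        ("source_id", info.source_id),
        ("uid", info.uid),
    ):
        ET.SubElement(root, tag).text = val
    return b'<?xml version="1.0"?>' + ET.tostring(root)


def _footer_to_xml(stats: FooterStats) -> bytes:
    root = ET.Element("info")
    ET.SubElement(root, "first_timestamp").text = repr(float(stats.first_timestamp))
    ET.SubElement(root, "last_timestamp").text = repr(float(stats.last_timestamp))
    ET.SubElement(root, "sample_count").text = str(int(stats.sample_count))
    ET.SubElement(root, "measured_srate").text = repr(float(stats.measured_srate))
    offs = ET.SubElement(root, "clock_offsets")
    for rec in stats.offsets.records:
        o = ET.SubElement(offs, "offset")
        ET.SubElement(o, "time").text = repr(float(rec.collection_time))
        ET.SubElement(o, "value").text = repr(float(rec.offset))
    return b'<?xml version="1.0"?>' + ET.tostring(root)


class XdfWriter:
    """Chunked writer with write-through flushing.

    Every chunk is flushed to the operating system as soon as it is written,
    so after an abnormal termination the on-disk file contains every chunk
    the recorder completed — crash loss is bounded by the recorder's buffer
    interval, never by OS write caching.
    """

    def __init__(self, path: str | os.PathLike, version: str = "1.0") -> None:
        path = os.fspath(path)
        if os.path.exists(path):
            raise FileExistsError(f"refusing to overwrite existing file: {path}")
        self.path = path
        self._fh: BinaryIO = open(path, "xb")
        self._finalized = False
        self._sample_counts: dict[int, int] = {}
        self._stream_info: dict[int, StreamInfo] = {}
        self._last_written_ts: dict[int, float] = {}
        self._fh.write(MAGIC)
        root = ET.Element("info")
        ET.SubElement(root, "version").text = version
        self._write_chunk(ChunkTag.FILE_HEADER, b'<?xml version="1.0"?>' + ET.tostring(root))

    # -- low level -------------------------------------------------------
    def _write_chunk(self, tag: int, content: bytes) -> int:
        """Encode and write one chunk; returns total bytes written."""
        if self._fh.closed:
            raise RuntimeError("writer is closed")
        length = 2 + len(content)
        if length <= 0xFF:
            header = b"\x01" + struct.pack("<B", length)
        elif length <= 0xFFFFFFFF:
            header = b"\x04" + struct.pack("<I", length)
        else:
            header = b"\x08" + struct.pack("<Q", length)
        payload = header + struct.pack("<H", tag) + content
        self._fh.write(payload)
        self._fh.flush()  # write-through: loss model is process death, not OS caching
        return len(payload)

    # -- chunk writers ---------------------------------------------------
    def write_stream_header(self, stream_id: int, info: StreamInfo) -> int:
        if stream_id in self._stream_info:
            raise ValueError(f"stream id {stream_id} already has a header")
        self._stream_info[stream_id] = info
        self._sample_counts[stream_id] = 0
        return self._write_chunk(
            ChunkTag.STREAM_HEADER, struct.pack("<I", stream_id) + _info_to_xml(info)
        )

    def write_samples(self, stream_id: int, samples: Sequence[TimedSample]) -> int:
        """Write one Samples chunk.

        A timestamp is omitted (stored as "deduced") only when it equals
        ``previous + 1/nominal_srate`` *exactly* in double precision, so the
        reader's reconstruction is bit-identical to what was written —
        roundtrips stay lossless. Jittered real-world timestamps are
        therefore always stored explicitly.
        """
        if stream_id not in self._stream_info:
            raise ValueError(f"no stream header written for stream id {stream_id}")
        if not samples:
            return 0
        info = self._stream_info[stream_id]
        srate = info.nominal_srate
        fmt = info.channel_format
        parts = [struct.pack("<I", stream_id)]
        n = len(samples)
        if n <= 0xFF:
            parts.append(b"\x01" + struct.pack("<B", n))
        else:
            parts.append(b"\x04" + struct.pack("<I", n))
        prev = self._last_written_ts.get(stream_id)
        packer = _FORMAT_STRUCT.get(fmt)
        for s in samples:
            ts = float(s.timestamp)
            deduced = srate > 0 and prev is not None and ts == prev + 1.0 / srate
            if deduced:
                parts.append(b"\x00")
            else:
                parts.append(b"\x08" + struct.pack("<d", ts))
            prev = ts
            if packer is not None:
                parts.append(struct.pack("<" + packer[-1] * info.channel_count, *s.values))
            else:  # string channels
                for v in s.values:
                    parts.append(_encode_varlen_value(str(v).encode("utf-8")))
        self._last_written_ts[stream_id] = prev  # deduction state persists across chunks
        self._sample_counts[stream_id] += n
        return self._write_chunk(ChunkTag.SAMPLES, b"".join(parts))

    def write_clock_offset(self, stream_id: int, collection_time: float, offset: float) -> int:
        return self._write_chunk(
            ChunkTag.CLOCK_OFFSET,
            struct.pack("<Idd", stream_id, collection_time, offset),
        )

    def write_boundary(self) -> int:
        """Recovery marker; carries no content."""
        return self._write_chunk(ChunkTag.BOUNDARY, b"")

    def write_stream_footer(self, stream_id: int, stats: FooterStats) -> int:
        written = self._sample_counts.get(stream_id)
        if written is not None and stats.sample_count != written:
            raise ValueError(
                f"stream {stream_id}: footer sample_count {stats.sample_count} "
                f"!= {written} samples actually written"
            )
        return self._write_chunk(
            ChunkTag.STREAM_FOOTER, struct.pack("<I", stream_id) + _footer_to_xml(stats)
        )

    # -- lifecycle -------------------------------------------------------
    def finalize(self, footers: dict[int, FooterStats] | None = None) -> None:
        """Write one footer per stream (if given) and close the file."""
        if self._finalized:
            raise RuntimeError("finalize() called twice")
        for stream_id, stats in (footers or {}).items():
            self.write_stream_footer(stream_id, stats)
        self._finalized = True
        self._fh.close()

    def abandon(self) -> None:
        """Close the file handle without footers — models abnormal termination."""
        if not self._fh.closed:
            self._fh.close()

    @property
    def sample_counts(self) -> dict[int, int]:
        return dict(self._sample_counts)


def open_writer(path: str | os.PathLike, version: str = "1.0") -> XdfWriter:
    """Create a new XDF file (refusing to overwrite) and write its file header."""
    return XdfWriter(path, version=version)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _xml_text(root: ET.Element, tag: str, default: str = "") -> str:
    el = root.find(tag)
    return el.text if el is not None and el.text is not None else default


def _parse_stream_header(content: bytes) -> tuple[int, StreamInfo]:
    (stream_id,) = struct.unpack_from("<I", content, 0)
    root = ET.fromstring(content[4:].decode("utf-8"))
    info = StreamInfo(
        name=_xml_text(root, "name"),
        stream_type=_xml_text(root, "type"),
        channel_count=int(_xml_text(root, "channel_count", "1")),
        nominal_srate=float(_xml_text(root, "nominal_srate", "0")),
        channel_format=_xml_text(root, "channel_format", "float32"),
        source_id=_xml_text(root, "source_id"),
        uid=_xml_text(root, "uid"),
    )
    return stream_id, info


def _parse_footer(content: bytes) -> tuple[int, FooterStats]:
    (stream_id,) = struct.unpack_from("<I", content, 0)
    root = ET.fromstring(content[4:].decode("utf-8"))
    offsets = OffsetSeries()
    co = root.find("clock_offsets")
    if co is not None:
        for off in co.findall("offset"):
            offsets.append(
                ClockOffsetRecord(
                    collection_time=float(_xml_text(off, "time")),
                    offset=float(_xml_text(off, "value")),
                )
            )
    stats = FooterStats(
        first_timestamp=float(_xml_text(root, "first_timestamp", "nan")),
        last_timestamp=float(_xml_text(root, "last_timestamp", "nan")),
        sample_count=int(_xml_text(root, "sample_count", "0")),
        measured_srate=float(_xml_text(root, "measured_srate", "nan")),
        offsets=offsets,
    )
    return stream_id, stats


class _StreamAccumulator:
    def __init__(self, stream_id: int, info: StreamInfo) -> None:
        self.stream_id = stream_id
        self.info = info
        self.values: list[tuple] = []
        self.timestamps: list[float] = []
        self.offsets = OffsetSeries(stream_uid=info.uid)
        self.footer: FooterStats | None = None
        self._last_ts: float | None = None

    def add_samples(self, content: bytes, warn: list[str]) -> None:
        off = 4  # stream id already parsed
        nbytes = content[off]
        off += 1
        if nbytes == 1:
            n = content[off]
            off += 1
        elif nbytes == 4:
            (n,) = struct.unpack_from("<I", content, off)
            off += 4
        else:
            (n,) = struct.unpack_from("<Q", content, off)
            off += 8
        fmt = self.info.channel_format
        cc = self.info.channel_count
        unpacker = _FORMAT_STRUCT.get(fmt)
        itemsize = struct.calcsize(unpacker) if unpacker else 0
        for _ in range(n):
            tsbytes = content[off]
            off += 1
            if tsbytes == 8:
                (ts,) = struct.unpack_from("<d", content, off)
                off += 8
            elif tsbytes == 0:
                if self._last_ts is None or self.info.nominal_srate <= 0:
                    warn.append(
                        f"stream {self.stream_id}: deduced timestamp without predecessor"
                    )
                    ts = 0.0 if self._last_ts is None else self._last_ts
                else:
                    ts = self._last_ts + 1.0 / self.info.nominal_srate
            else:
                raise XdfFormatError(f"invalid timestamp-bytes flag {tsbytes}")
            self._last_ts = ts
            if unpacker is not None:
                vals = struct.unpack_from(f"<{cc}{unpacker[-1]}", content, off)
                off += itemsize * cc
            else:
                items = []
                for _c in range(cc):
                    w = content[off]
                    off += 1
                    if w == 1:
                        ln = content[off]
                        off += 1
                    elif w == 4:
                        (ln,) = struct.unpack_from("<I", content, off)
                        off += 4
                    else:
                        (ln,) = struct.unpack_from("<Q", content, off)
                        off += 8
                    items.append(content[off : off + ln].decode("utf-8"))
                    off += ln
                vals = tuple(items)
            self.values.append(vals)
            self.timestamps.append(ts)

    def finish(self) -> StreamRecording:
        fmt = self.info.channel_format
        if fmt in _FORMAT_DTYPE:
            values = np.array(self.values, dtype=_FORMAT_DTYPE[fmt]).reshape(
                len(self.values), self.info.channel_count
            )
        else:
            values = self.values
        return StreamRecording(
            stream_id=self.stream_id,
            info=self.info,
            values=values,
            timestamps=np.asarray(self.timestamps, dtype=np.float64),
            offsets=self.offsets,
            footer=self.footer,
        )


def read_xdf(path: str | os.PathLike) -> XdfRecording:
    """Load an XDF file, tolerating truncation and a missing footer.

    Returns every *complete* chunk in the file. A final chunk cut short by
    an abnormal termination is dropped with a warning; streams whose footer
    is absent come back with ``footer=None`` so callers can flag them as
    unsynchronizable-by-footer.
    """
    warns: list[str] = []
    streams: dict[int, _StreamAccumulator] = {}
    version = ""
    with open(path, "rb") as fh:
        if fh.read(4) != MAGIC:
            raise XdfFormatError(f"{path}: not an XDF file (bad magic)")
        while True:
            nlb = fh.read(1)
            if not nlb:
                break  # clean EOF at a chunk boundary
            width = nlb[0]
            if width not in (1, 4, 8):
                warns.append(f"invalid NumLengthBytes {width}; stopping at byte {fh.tell()}")
                break
            raw_len = fh.read(width)
            if len(raw_len) < width:
                warns.append("truncated chunk length field; trailing chunk discarded")
                break
            length = int.from_bytes(raw_len, "little")
            body = fh.read(length)
            if len(body) < length or length < 2:
                warns.append("truncated final chunk discarded")
                break
            (tag,) = struct.unpack_from("<H", body, 0)
            content = body[2:]
            try:
                if tag == ChunkTag.FILE_HEADER:
                    root = ET.fromstring(content.decode("utf-8"))
                    version = _xml_text(root, "version", "")
                elif tag == ChunkTag.STREAM_HEADER:
                    sid, info = _parse_stream_header(content)
                    streams[sid] = _StreamAccumulator(sid, info)
                elif tag == ChunkTag.SAMPLES:
                    (sid,) = struct.unpack_from("<I", content, 0)
                    if sid not in streams:
                        warns.append(f"samples for unknown stream {sid} skipped")
                    else:
                        streams[sid].add_samples(content, warns)
                elif tag == ChunkTag.CLOCK_OFFSET:
                    sid, ct, off = struct.unpack("<Idd", content)
                    if sid in streams:
                        streams[sid].offsets.append(ClockOffsetRecord(ct, off))
                    else:
                        warns.append(f"clock offset for unknown stream {sid} skipped")
                elif tag == ChunkTag.BOUNDARY:
                    pass
                elif tag == ChunkTag.STREAM_FOOTER:
                    sid, stats = _parse_footer(content)
                    if sid in streams:
                        streams[sid].footer = stats
                    else:
                        warns.append(f"footer for unknown stream {sid} skipped")
                else:
                    warns.append(f"unknown chunk tag {tag} skipped")
            except (struct.error, ET.ParseError, IndexError) as exc:
                warns.append(f"malformed chunk (tag {tag}) skipped: {exc}")
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return XdfRecording(
        version=version,
        streams={sid: acc.finish() for sid, acc in streams.items()},
        warnings=warns,
    )


def validate_file(path: str | os.PathLike) -> XdfRecording:
    """Read and cross-check footer statistics against the loaded data."""
    rec = read_xdf(path)
    for sid, s in rec.streams.items():
        if s.footer is None:
            raise XdfFormatError(f"stream {sid}: footer missing")
        if s.footer.sample_count != s.sample_count:
            raise XdfFormatError(
                f"stream {sid}: footer sample_count {s.footer.sample_count} "
                f"!= {s.sample_count} samples in file"
            )
        if s.sample_count and s.footer.last_timestamp < s.footer.first_timestamp:
            raise XdfFormatError(f"stream {sid}: footer timestamps out of order")
    return rec
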