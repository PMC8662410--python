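"""Independent XDF 1.0 byte-layout oracle for tests.

A deliberately separate, minimal implementation of the public XDF chunk
layout — shared with nothing in the package — used to cross-check that
files the package writes are decodable by an independent reading of the
format, and that files encoded independently load in the package reader.

Layout decoded here, straight from the container rules:
  magic "XDF:", then chunks of
  [1 byte: number of length bytes, 1|4|8][length, little-endian]
  [2-byte tag][content]; stream-scoped content starts with 4-byte id.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET


def decode_file(path):
    """Decode an XDF file into plain dicts, trusting only the byte layout."""
    with open(path, "rb") as fh:
        blob = fh.read()
    assert blob[:4] == b"XDF:", "bad magic"
    pos = 4
    out = {"version": None, "streams": {}}
    while pos < len(blob):
        width = blob[pos]
        pos += 1
        assert width in (1, 4, 8), f"bad width {width}"
        length = int.from_bytes(blob[pos : pos + width], "little")
        pos += width
        body = blob[pos : pos + length]
        assert len(body) == length, "truncated chunk"
        pos += length
        tag = int.from_bytes(body[:2], "little")
        content = body[2:]
        if tag == 1:  # file header
            out["version"] = ET.fromstring(content.decode()).findtext("version")
        elif tag == 2:  # stream header
            sid = int.from_bytes(content[:4], "little")
            root = ET.fromstring(content[4:].decode())
            out["streams"][sid] = {
                "info": {el.tag: el.text for el in root},
                "timestamps": [],
                "values": [],
                "offsets": [],
                "footer": None,
            }
        elif tag == 3:  # samples
            sid = int.from_bytes(content[:4], "little")
            st = out["streams"][sid]
            fmt = st["info"]["channel_format"]
            cc = int(st["info"]["channel_count"])
            srate = float(st["info"]["nominal_srate"])
            o = 4
            nw = content[o]
            o += 1
            n = int.from_bytes(content[o : o + nw], "little")
            o += nw
            for _ in range(n):
                tsb = content[o]
                o += 1
                if tsb == 8:
                    (ts,) = struct.unpack_from("<d", content, o)
                    o += 8
                else:
                    assert tsb == 0
                    ts = st["timestamps"][-1] + 1.0 / srate
                if fmt == "string":
                    vals = []
                    for _c in range(cc):
                        w = content[o]
                        o += 1
                        ln = int.from_bytes(content[o : o + w], "little")
                        o += w
                        vals.append(content[o : o + ln].decode())
                        o += ln
                    vals = tuple(vals)
                else:
                    code = {"float32": "f", "double64": "d", "int32": "i"}[fmt]
                    vals = struct.unpack_from("<" + code * cc, content, o)
                    o += struct.calcsize("<" + code * cc)
                st["timestamps"].append(ts)
                st["values"].append(vals)
            assert o == len(content), "samples chunk length mismatch"
        elif tag == 4:  # clock offset
            sid, t, off = struct.unpack("<Idd", content)
            out["streams"][sid]["offsets"].append((t, off))
        elif tag == 5:  # boundary
            pass
        elif tag == 6:  # stream footer
            sid = int.from_bytes(content[:4], "little")
            root = ET.fromstring(content[4:].decode())
            out["streams"][sid]["footer"] = {
                "first_timestamp": float(root.findtext("first_timestamp")),
                "last_timestamp": float(root.findtext("last_timestamp")),
                "sample_count": int(root.findtext("sample_count")),
                "measured_srate": float(root.findtext("measured_srate")),
                "clock_offsets": [
                    (float(o.findtext("time")), float(o.findtext("value")))
                    for o in root.find("clock_offsets").findall("offset")
                ],
            }
        else:
            raise AssertionError(f"unknown tag {tag}")
    return out


# -- independent encoder (for reverse-direction fixtures) -------------------


def _chunk(tag: int, content: bytes) -> bytes:
    length = 2 + len(content)
    if length <= 0xFF:
        head = b"\x01" + bytes([length])
    else:
        head = b"\x04" + length.to_bytes(4, "little")
    return head + tag.to_bytes(2, "little") + content


def encode_simple_file(
    path,
    stream_id: int,
    info_fields: dict,
    samples: list[tuple[float, tuple]],
    offsets: list[tuple[float, float]] = (),
    footer: dict | None = None,
) -> None:
    """Hand-encode a one-stream float32 XDF file, independently of the package."""
    info = ET.Element("info")
    for k, v in info_fields.items():
        ET.SubElement(info, k).text = str(v)
    cc = int(info_fields["channel_count"])
    parts = [b"XDF:"]
    fh = ET.Element("info")
    ET.SubElement(fh, "version").text = "1.0"
    parts.append(_chunk(1, b'<?xml version="1.0"?>' + ET.tostring(fh)))
    parts.append(
        _chunk(2, stream_id.to_bytes(4, "little") + b'<?xml version="1.0"?>' + ET.tostring(info))
    )
    body = [stream_id.to_bytes(4, "little"), b"\x01", bytes([len(samples)])]
    for ts, vals in samples:
        body.append(b"\x08" + struct.pack("<d", ts))
        body.append(struct.pack("<" + "f" * cc, *vals))
    parts.append(_chunk(3, b"".join(body)))
    for t, off in offsets:
        parts.append(_chunk(4, struct.pack("<Idd", stream_id, t, off)))
    parts.append(_chunk(5, b""))
    if footer is not None:
        root = ET.Element("info")
        for k in ("first_timestamp", "last_timestamp", "sample_count", "measured_srate"):
            ET.SubElement(root, k).text = repr(footer[k])
        co = ET.SubElement(root, "clock_offsets")
        for t, off in footer.get("clock_offsets", []):
            el = ET.SubElement(co, "offset")
            ET.SubElement(el, "time").text = repr(t)
            ET.SubElement(el, "value").text = repr(off)
        parts.append(
            _chunk(6, stream_id.to_bytes(4, "little") + b'<?xml version="1.0"?>' + ET.tostring(root))
        )
    with open(path, "wb") as f:
        f.write(b"".join(parts))
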