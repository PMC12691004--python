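"""Minimal DICOM codec: Explicit VR Little Endian read/write.

Supports the subset of DICOM needed to exchange CT series, RT-DOSE grids
and RT-STRUCT contour sets between the synthetic cohort writer and the
reader in :mod:`dosederm.io_rt` -- single-frame/multi-frame image modules
and nested sequences.  Datasets are plain dicts mapping ``(group, element)``
tags to decoded values; sequences decode to lists of dicts.

Not a general-purpose DICOM implementation: one transfer syntax, no
implicit VR, no compressed pixel data, no character-set handling beyond
ASCII.  Files written here are structurally valid Part-10 files.
"""

from __future__ import annotations

import struct
from io import BytesIO

MAGIC = b"DICM"
TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"

# VRs whose length field is 4 bytes after a 2-byte reserved gap
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}
_TEXT_VRS = {b"UI", b"CS", b"LO", b"SH", b"PN", b"DA", b"TM", b"ST", b"AE"}

ITEM_TAG = (0xFFFE, 0xE000)
ITEM_DELIM_TAG = (0xFFFE, 0xE00D)
SEQ_DELIM_TAG = (0xFFFE, 0xE0DD)

# Tags used by this package, with their VRs (write side).
VR_OF_TAG = {
    (0x0002, 0x0002): b"UI", (0x0002, 0x0003): b"UI", (0x0002, 0x0010): b"UI",
    (0x0008, 0x0016): b"UI", (0x0008, 0x0018): b"UI", (0x0008, 0x0060): b"CS",
    (0x0010, 0x0010): b"PN", (0x0010, 0x0020): b"LO",
    (0x0018, 0x0050): b"DS",
    (0x0020, 0x000D): b"UI", (0x0020, 0x000E): b"UI",
    (0x0020, 0x0032): b"DS", (0x0020, 0x0037): b"DS", (0x0020, 0x0052): b"UI",
    (0x0028, 0x0002): b"US", (0x0028, 0x0008): b"IS",
    (0x0028, 0x0010): b"US", (0x0028, 0x0011): b"US", (0x0028, 0x0030): b"DS",
    (0x0028, 0x0100): b"US", (0x0028, 0x0101): b"US", (0x0028, 0x0102): b"US",
    (0x0028, 0x0103): b"US", (0x0028, 0x1052): b"DS", (0x0028, 0x1053): b"DS",
    (0x3004, 0x0002): b"CS", (0x3004, 0x000C): b"DS", (0x3004, 0x000E): b"DS",
    (0x3006, 0x0002): b"SH", (0x3006, 0x0020): b"SQ", (0x3006, 0x0022): b"IS",
    (0x3006, 0x0024): b"UI", (0x3006, 0x0026): b"LO", (0x3006, 0x0039): b"SQ",
    (0x3006, 0x0040): b"SQ", (0x3006, 0x0042): b"CS", (0x3006, 0x0046): b"IS",
    (0x3006, 0x0050): b"DS", (0x3006, 0x0084): b"IS",
    (0x7FE0, 0x0010): b"OW",
}

# Common tag aliases
TAG = {
    "SOPClassUID": (0x0008, 0x0016),
    "SOPInstanceUID": (0x0008, 0x0018),
    "Modality": (0x0008, 0x0060),
    "PatientName": (0x0010, 0x0010),
    "PatientID": (0x0010, 0x0020),
    "SliceThickness": (0x0018, 0x0050),
    "StudyInstanceUID": (0x0020, 0x000D),
    "SeriesInstanceUID": (0x0020, 0x000E),
    "ImagePositionPatient": (0x0020, 0x0032),
    "ImageOrientationPatient": (0x0020, 0x0037),
    "FrameOfReferenceUID": (0x0020, 0x0052),
    "SamplesPerPixel": (0x0028, 0x0002),
    "NumberOfFrames": (0x0028, 0x0008),
    "Rows": (0x0028, 0x0010),
    "Columns": (0x0028, 0x0011),
    "PixelSpacing": (0x0028, 0x0030),
    "BitsAllocated": (0x0028, 0x0100),
    "BitsStored": (0x0028, 0x0101),
    "HighBit": (0x0028, 0x0102),
    "PixelRepresentation": (0x0028, 0x0103),
    "RescaleIntercept": (0x0028, 0x1052),
    "RescaleSlope": (0x0028, 0x1053),
    "DoseUnits": (0x3004, 0x0002),
    "GridFrameOffsetVector": (0x3004, 0x000C),
    "DoseGridScaling": (0x3004, 0x000E),
    "StructureSetLabel": (0x3006, 0x0002),
    "StructureSetROISequence": (0x3006, 0x0020),
    "ROINumber": (0x3006, 0x0022),
    "ReferencedFrameOfReferenceUID": (0x3006, 0x0024),
    "ROIName": (0x3006, 0x0026),
    "ROIContourSequence": (0x3006, 0x0039),
    "ContourSequence": (0x3006, 0x0040),
    "ContourGeometricType": (0x3006, 0x0042),
    "NumberOfContourPoints": (0x3006, 0x0046),
    "ContourData": (0x3006, 0x0050),
    "ReferencedROINumber": (0x3006, 0x0084),
    "PixelData": (0x7FE0, 0x0010),
}

SOP_CLASS_CT = "1.2.840.10008.5.1.4.1.1.2"
SOP_CLASS_RTDOSE = "1.2.840.10008.5.1.4.1.1.481.2"
SOP_CLASS_RTSTRUCT = "1.2.840.10008.5.1.4.1.1.481.3"

_UID_COUNTER = [0]
_UID_ROOT = "1.2.826.0.1.3680043.10.424"  # generic org root for generated UIDs


def make_uid(suffix: str = "") -> str:
    _UID_COUNTER[0] += 1
    tail = f".{suffix}" if suffix else ""
    return f"{_UID_ROOT}{tail}.{_UID_COUNTER[0]}"


def _format_ds(value) -> str:
    if isinstance(value, (list, tuple)):
        return "\\".join(_format_ds(v) for v in value)
    s = f"{float(value):.10g}"
    return s


def _encode_value(vr: bytes, value) -> bytes:
    if vr == b"DS":
        raw = _format_ds(value).encode("ascii")
    elif vr == b"IS":
        if isinstance(value, (list, tuple)):
            raw = "\\".join(str(int(v)) for v in value).encode("ascii")
        else:
            raw = str(int(value)).encode("ascii")
    elif vr in _TEXT_VRS:
        if isinstance(value, (list, tuple)):
            raw = "\\".join(str(v) for v in value).encode("ascii")
        else:
            raw = str(value).encode("ascii")
    elif vr == b"US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        raw = struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    elif vr == b"UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        raw = struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    elif vr == b"OW":
        raw = bytes(value)
    else:
        raise ValueError(f"unsupported VR for writing: {vr!r}")
    if len(raw) % 2:
        raw += b"\x00" if vr in (b"UI", b"OW") else b" "
    return raw


def _write_element(buf: BytesIO, tag: tuple[int, int], vr: bytes, raw: bytes) -> None:
    buf.write(struct.pack("<HH", *tag))
    buf.write(vr)
    if vr in _LONG_VRS:
        buf.write(struct.pack("<HI", 0, len(raw)))
    else:
        if len(raw) > 0xFFFF:
            raise ValueError("value too long for short VR")
        buf.write(struct.pack("<H", len(raw)))
    buf.write(raw)


def _encode_dataset(ds: dict) -> bytes:
    buf = BytesIO()
    for tag in sorted(ds):
        value = ds[tag]
        vr = VR_OF_TAG.get(tag)
        if vr is None:
            raise ValueError(f"no VR registered for tag {tag}")
        if vr == b"SQ":
            items = BytesIO()
            for item_ds in value:
                raw_item = _encode_dataset(item_ds)
                items.write(struct.pack("<HHI", *ITEM_TAG, len(raw_item)))
                items.write(raw_item)
            _write_element(buf, tag, vr, items.getvalue())
        else:
            _write_element(buf, tag, vr, _encode_value(vr, value))
    return buf.getvalue()


def write_file(path, dataset: dict) -> None:
    """Write a Part-10 file (128-byte preamble, meta group, dataset)."""
    sop_class = dataset.get(TAG["SOPClassUID"], "")
    sop_inst = dataset.get(TAG["SOPInstanceUID"], make_uid())
    meta = {
        (0x0002, 0x0002): sop_class,
        (0x0002, 0x0003): sop_inst,
        (0x0002, 0x0010): TRANSFER_SYNTAX_EXPLICIT_LE,
    }
    meta_raw = _encode_dataset(meta)
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(MAGIC)
        # group length element for group 0002
        gl = BytesIO()
        gl.write(struct.pack("<HH", 0x0002, 0x0000))
        gl.write(b"UL")
        gl.write(struct.pack("<H", 4))
        gl.write(struct.pack("<I", len(meta_raw)))
        fh.write(gl.getvalue())
        fh.write(meta_raw)
        fh.write(_encode_dataset(dataset))


def _decode_value(vr: bytes, raw: bytes):
    if vr == b"DS":
        text = raw.decode("ascii").strip(" \x00")
        if not text:
            return []
        parts = [float(p) for p in text.split("\\")]
        return parts[0] if len(parts) == 1 else parts
    if vr == b"IS":
        text = raw.decode("ascii").strip(" \x00")
        if not text:
            return []
        parts = [int(p) for p in text.split("\\")]
        return parts[0] if len(parts) == 1 else parts
    if vr in _TEXT_VRS:
        text = raw.decode("ascii").strip(" \x00")
        return text
    if vr == b"US":
        vals = list(struct.unpack(f"<{len(raw)//2}H", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == b"UL":
        vals = list(struct.unpack(f"<{len(raw)//4}I", raw))
        return vals[0] if len(vals) == 1 else vals
    return raw  # OW/OB/unknown: raw bytes


def _parse_dataset(buf: memoryview, pos: int, end: int) -> tuple[dict, int]:
    ds: dict = {}
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        tag = (group, elem)
        pos += 4
        if tag in (ITEM_DELIM_TAG, SEQ_DELIM_TAG):
            pos += 4  # zero length
            return ds, pos
        vr = bytes(buf[pos:pos + 2])
        pos += 2
        if vr in _LONG_VRS:
            pos += 2  # reserved
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        else:
            (length,) = struct.unpack_from("<H", buf, pos)
            pos += 2
        if vr == b"SQ":
            items, pos = _parse_sequence(buf, pos, length)
            ds[tag] = items
        else:
            if length == 0xFFFFFFFF:
                raise ValueError("undefined length outside SQ not supported")
            ds[tag] = _decode_value(vr, bytes(buf[pos:pos + length]))
            pos += length
    return ds, pos


def _parse_sequence(buf: memoryview, pos: int, length: int) -> tuple[list, int]:
    items = []
    undefined = length == 0xFFFFFFFF
    end = len(buf) if undefined else pos + length
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        (item_len,) = struct.unpack_from("<I", buf, pos)
        pos += 4
        if (group, elem) == SEQ_DELIM_TAG:
            break
        if (group, elem) != ITEM_TAG:
            raise ValueError("malformed sequence")
        if item_len == 0xFFFFFFFF:
            item, pos = _parse_dataset(buf, pos, len(buf))
        else:
            item, _ = _parse_dataset(buf, pos, pos + item_len)
            pos += item_len
        items.append(item)
    return items, pos


def read_file(path) -> dict:
    """Parse a Part-10 Explicit-VR-LE file into a tag -> value dict."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[128:132] != MAGIC:
        raise ValueError(f"{path}: not a DICOM Part-10 file")
    buf = memoryview(data)
    pos = 132
    # meta group (always explicit LE)
    meta, pos = _parse_meta(buf, pos)
    ts = meta.get((0x0002, 0x0010))
    if ts and ts != TRANSFER_SYNTAX_EXPLICIT_LE:
        raise ValueError(f"unsupported transfer syntax {ts}")
    ds, _ = _parse_dataset(buf, pos, len(buf))
    return ds


def _parse_meta(buf: memoryview, pos: int) -> tuple[dict, int]:
    meta: dict = {}
    # first element must be the group length
    group, elem = struct.unpack_from("<HH", buf, pos)
    if (group, elem) != (0x0002, 0x0000):
        raise ValueError("missing file meta group length")
    pos += 4 + 2  # tag + 'UL'
    (length,) = struct.unpack_from("<H", buf, pos)
    pos += 2
    (meta_len,) = struct.unpack_from("<I", buf, pos)
    pos += length
    meta, pos = _parse_dataset(buf, pos, pos + meta_len)
    return meta, pos
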