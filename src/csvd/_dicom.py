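"""Minimal single-frame grayscale DICOM support.

Covers exactly what the pipeline needs — uncompressed MONOCHROME little-endian
files with 8- or 16-bit unsigned pixels — in both explicit- and implicit-VR
transfer syntaxes.  Anything else (compressed syntaxes, color, multi-frame)
is rejected with a typed error.  The writer emits Explicit VR Little Endian
secondary-capture objects that the reader round-trips bit-identically.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError, UnsupportedInputError

EXPLICIT_LE = "1.2.840.10008.1.2.1"
IMPLICIT_LE = "1.2.840.10008.1.2"
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

# tags the reader interprets
_TAG_SAMPLES = (0x0028, 0x0002)
_TAG_PHOTOMETRIC = (0x0028, 0x0004)
_TAG_FRAMES = (0x0028, 0x0008)
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_SPACING = (0x0028, 0x0030)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REP = (0x0028, 0x0103)
_TAG_INSTANCE = (0x0020, 0x0013)
_TAG_PIXELDATA = (0x7FE0, 0x0010)


def _parse_elements(buf: bytes, pos: int, explicit: bool) -> dict[tuple[int, int], bytes]:
    """Walk data elements sequentially; returns raw value bytes per tag."""
    out: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        # file meta (group 0002) is always explicit VR
        if explicit or group == 0x0002:
            vr = buf[pos : pos + 2]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 4)
                pos += 8
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 2)
                pos += 4
            if vr == b"SQ":
                raise UnsupportedInputError("DICOM sequences are not supported")
        else:
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        if length == 0xFFFFFFFF:
            raise UnsupportedInputError("undefined-length DICOM elements are not supported")
        if pos + length > n:
            raise FormatError("truncated DICOM element")
        out[(group, elem)] = buf[pos : pos + length]
        pos += length
    return out


def _ascii(elems: dict, tag: tuple[int, int]) -> str | None:
    raw = elems.get(tag)
    return None if raw is None else raw.decode("ascii", "replace").strip("\x00 ")


def _ushort(elems: dict, tag: tuple[int, int]) -> int | None:
    raw = elems.get(tag)
    if raw is None or len(raw) < 2:
        return None
    return struct.unpack("<H", raw[:2])[0]


def read(path: str) -> tuple[np.ndarray, float | None, int | None]:
    """Read pixels, in-plane pixel spacing (mm) and instance number.

    Raises :class:`FormatError` for unparsable files and
    :class:`UnsupportedInputError` for multi-frame or non-grayscale data.
    """
    try:
        with open(path, "rb") as fh:
            buf = fh.read()
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM marker")

    # parse file meta first (always explicit) to learn the transfer syntax
    meta: dict[tuple[int, int], bytes] = {}
    pos = 132
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        if group != 0x0002:
            break
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            body = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            body = pos + 8
        meta[(group, elem)] = buf[body : body + length]
        pos = body + length
    ts = _ascii(meta, (0x0002, 0x0010)) or EXPLICIT_LE
    if ts == EXPLICIT_LE:
        explicit = True
    elif ts == IMPLICIT_LE:
        explicit = False
    else:
        raise UnsupportedInputError(f"{path}: transfer syntax {ts} is not supported")

    try:
        elems = _parse_elements(buf, pos, explicit)
    except struct.error as exc:
        raise FormatError(f"{path}: malformed DICOM stream") from exc

    frames = _ascii(elems, _TAG_FRAMES)
    if frames and int(frames) > 1:
        raise UnsupportedInputError(f"{path}: multi-frame DICOM ({frames} frames)")
    samples = _ushort(elems, _TAG_SAMPLES)
    if samples not in (None, 1):
        raise UnsupportedInputError(f"{path}: {samples} samples per pixel (not grayscale)")
    photometric = _ascii(elems, _TAG_PHOTOMETRIC)
    if photometric not in (None, "MONOCHROME1", "MONOCHROME2"):
        raise UnsupportedInputError(f"{path}: photometric {photometric}")

    rows = _ushort(elems, _TAG_ROWS)
    cols = _ushort(elems, _TAG_COLS)
    bits = _ushort(elems, _TAG_BITS_ALLOC) or 16
    signed = _ushort(elems, _TAG_PIXEL_REP) == 1
    pixeldata = elems.get(_TAG_PIXELDATA)
    if rows is None or cols is None or pixeldata is None:
        raise FormatError(f"{path}: missing Rows/Columns/PixelData")
    if bits not in (8, 16):
        raise UnsupportedInputError(f"{path}: {bits}-bit pixels are not supported")
    dtype = {(8, False): np.uint8, (8, True): np.int8, (16, False): np.uint16, (16, True): np.int16}[
        (bits, signed)
    ]
    expected = rows * cols * (bits // 8)
    if len(pixeldata) < expected:
        raise FormatError(f"{path}: pixel data shorter than Rows x Columns")
    pixels = np.frombuffer(pixeldata[:expected], dtype=np.dtype(dtype).newbyteorder("<"))
    pixels = pixels.reshape(rows, cols).astype(dtype)

    spacing = None
    raw_spacing = _ascii(elems, _TAG_SPACING)
    if raw_spacing:
        parts = [p for p in raw_spacing.split("\\") if p]
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"{path}: bad PixelSpacing {raw_spacing!r}") from exc
        if values:
            if len(values) == 2 and abs(values[0] - values[1]) > 1e-9:
                raise UnsupportedInputError(f"{path}: anisotropic pixel spacing {values}")
            spacing = values[0]

    instance = _ascii(elems, _TAG_INSTANCE)
    index = int(instance) if instance else None
    return pixels, spacing, index


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"UI", b"IS", b"DS", b"LO", b"CS") else b"\x00"
    head = struct.pack("<HH", group, elem)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _str_el(group: int, elem: int, vr: bytes, text: str) -> bytes:
    return _element(group, elem, vr, text.encode("ascii"))


def write(
    path: str,
    pixels: np.ndarray,
    pixel_spacing_mm: float | None = None,
    instance_number: int | None = None,
) -> None:
    """Write an Explicit VR Little Endian secondary-capture file."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise UnsupportedInputError("only 2D grids can be written as DICOM")
    if arr.dtype.kind not in "iu" or arr.min(initial=0) < 0:
        raise UnsupportedInputError("DICOM writer requires non-negative integer pixels")
    if arr.max(initial=0) > 0xFFFF:
        raise UnsupportedInputError("pixel values exceed 16-bit range")
    bits = 8 if arr.max(initial=0) <= 0xFF else 16
    payload = arr.astype("<u1" if bits == 8 else "<u2").tobytes()

    body = b"".join(
        [
            _str_el(0x0008, 0x0016, b"UI", _SC_SOP_CLASS),
            _str_el(0x0008, 0x0018, b"UI", "1.2.826.0.1.3680043.8.498.1"),
            *(
                [_str_el(0x0020, 0x0013, b"IS", str(instance_number))]
                if instance_number is not None
                else []
            ),
            _element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _str_el(0x0028, 0x0004, b"CS", "MONOCHROME2"),
            _element(0x0028, 0x0010, b"US", struct.pack("<H", arr.shape[0])),
            _element(0x0028, 0x0011, b"US", struct.pack("<H", arr.shape[1])),
            *(
                [_str_el(0x0028, 0x0030, b"DS", f"{pixel_spacing_mm:g}\\{pixel_spacing_mm:g}")]
                if pixel_spacing_mm is not None
                else []
            ),
            _element(0x0028, 0x0100, b"US", struct.pack("<H", bits)),
            _element(0x0028, 0x0101, b"US", struct.pack("<H", bits)),
            _element(0x0028, 0x0102, b"US", struct.pack("<H", bits - 1)),
            _element(0x0028, 0x0103, b"US", struct.pack("<H", 0)),
            _element(0x7FE0, 0x0010, b"OW", payload),
        ]
    )

    meta_body = b"".join(
        [
            _element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _str_el(0x0002, 0x0002, b"UI", _SC_SOP_CLASS),
            _str_el(0x0002, 0x0003, b"UI", "1.2.826.0.1.3680043.8.498.1"),
            _str_el(0x0002, 0x0010, b"UI", EXPLICIT_LE),
        ]
    )
    meta = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)
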