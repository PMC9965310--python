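"""Minimal DICOM series reader/writer.

Only the subset required for CBCT-style volumes is implemented:
single-frame, monochrome, uncompressed Explicit VR Little Endian
(transfer syntax 1.2.840.10008.1.2.1), 8/16-bit integer pixels. This is
enough to round-trip series written by :func:`write_series` and to read
typical exported CT/CBCT slices.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from .errors import FormatError, InputError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_UID_ROOT = "1.2.826.0.1.3680043.10.1405"  # generic org root for generated UIDs

# VRs with a 2-byte reserved field and 32-bit length
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _read_exact(fh, n, path):
    buf = fh.read(n)
    if len(buf) != n:
        raise FormatError(f"{path}: truncated DICOM stream")
    return buf


def parse_dataset(path):
    """Parse a DICOM file into a {(group, elem): raw bytes or value} dict."""
    try:
        fh = open(path, "rb")
    except OSError as exc:
        raise InputError(f"cannot open DICOM file {path}: {exc}") from exc
    with fh:
        preamble = fh.read(132)
        if len(preamble) < 132 or preamble[128:132] != b"DICM":
            raise FormatError(f"{path}: missing DICM marker (compressed or non-part-10?)")
        elements = {}
        while True:
            head = fh.read(8)
            if len(head) == 0:
                break
            if len(head) < 8:
                raise FormatError(f"{path}: truncated element header")
            group, elem = struct.unpack("<HH", head[:4])
            vr = head[4:6]
            if vr.isalpha() and vr.isupper():
                if vr in _LONG_VRS:
                    (length,) = struct.unpack("<I", _read_exact(fh, 4, path))
                else:
                    (length,) = struct.unpack("<H", head[6:8])
            else:
                # implicit VR fallback (only hit for non-conformant files)
                vr = b"UN"
                (length,) = struct.unpack("<I", head[4:8])
            if length == 0xFFFFFFFF:
                raise FormatError(
                    f"{path}: undefined-length element ({group:04x},{elem:04x}) unsupported"
                )
            value = _read_exact(fh, length, path)
            elements[(group, elem)] = (vr.decode("ascii"), value)
    return elements


def _get_str(ds, tag, default=None):
    if tag not in ds:
        return default
    return ds[tag][1].decode("ascii", "replace").strip("\x00 ")


def _get_floats(ds, tag):
    text = _get_str(ds, tag)
    if text is None:
        return None
    return [float(tok) for tok in text.split("\\") if tok.strip()]


def _get_us(ds, tag):
    if tag not in ds:
        return None
    return struct.unpack("<H", ds[tag][1][:2])[0]


class _Slice:
    __slots__ = ("path", "position", "pixels")

    def __init__(self, path, position, pixels):
        self.path = path
        self.position = position
        self.pixels = pixels


def read_series(directory):
    """Read a single-series DICOM directory into (data, meta).

    Returns the volume indexed ``[column, row, slice]`` so that
    ``world = origin + orientation @ (index * spacing)`` with the
    orientation columns being (row-dir, col-dir, normal) in LPS.

    Raises :class:`FormatError` when inter-slice spacing is inconsistent
    beyond 1%, naming the offending slices.
    """
    if not os.path.isdir(directory):
        raise InputError(f"DICOM series directory not found: {directory}")
    paths = sorted(
        os.path.join(directory, name)
        for name in os.listdir(directory)
        if not name.startswith(".")
    )
    if not paths:
        raise InputError(f"no files in DICOM directory {directory}")

    slices = []
    geom = None
    for path in paths:
        ds = parse_dataset(path)
        rows = _get_us(ds, (0x0028, 0x0010))
        cols = _get_us(ds, (0x0028, 0x0011))
        bits = _get_us(ds, (0x0028, 0x0100)) or 16
        signed = (_get_us(ds, (0x0028, 0x0103)) or 0) == 1
        if rows is None or cols is None or TAG_PIXEL_DATA not in ds:
            raise FormatError(f"{path}: not an image slice")
        iop = _get_floats(ds, (0x0020, 0x0037)) or [1, 0, 0, 0, 1, 0]
        ipp = _get_floats(ds, (0x0020, 0x0032)) or [0, 0, 0]
        ps = _get_floats(ds, (0x0028, 0x0030)) or [1.0, 1.0]
        slope = (_get_floats(ds, (0x0028, 0x1053)) or [1.0])[0]
        intercept = (_get_floats(ds, (0x0028, 0x1052)) or [0.0])[0]
        dtype = np.dtype(f"<i{bits // 8}" if signed else f"<u{bits // 8}")
        raw = ds[TAG_PIXEL_DATA][1]
        expected = rows * cols * dtype.itemsize
        if len(raw) < expected:
            raise FormatError(f"{path}: pixel data truncated")
        pixels = np.frombuffer(raw[:expected], dtype=dtype).reshape(rows, cols)
        pixels = pixels.astype(np.float64) * slope + intercept

        this_geom = (rows, cols, tuple(np.round(iop, 9)), tuple(np.round(ps, 9)))
        if geom is None:
            geom = this_geom
        elif this_geom[:2] != geom[:2] or this_geom[2] != geom[2]:
            raise FormatError(f"{path}: slice geometry differs from first slice")
        slices.append(_Slice(path, np.asarray(ipp, float), pixels))

    row_dir = np.asarray(geom[2][:3], float)
    col_dir = np.asarray(geom[2][3:], float)
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda s: float(np.dot(s.position, normal)))

    if len(slices) > 1:
        offsets = np.array([np.dot(s.position, normal) for s in slices])
        gaps = np.diff(offsets)
        if np.any(gaps <= 0):
            raise FormatError(f"{directory}: duplicate or unordered slice positions")
        ref = np.median(gaps)
        bad = np.nonzero(np.abs(gaps - ref) > 0.01 * ref)[0]
        if bad.size:
            names = ", ".join(
                f"{os.path.basename(slices[i].path)}->"
                f"{os.path.basename(slices[i + 1].path)}" for i in bad
            )
            raise FormatError(
                f"{directory}: inconsistent slice spacing beyond 1% between {names}"
            )
        slice_spacing = float(ref)
    else:
        slice_spacing = float(geom[3][0])

    # pixels[r, c]: world = IPP + c*dc*row_dir + r*dr*col_dir
    stack = np.stack([s.pixels for s in slices], axis=-1)  # (rows, cols, nslices)
    data = np.transpose(stack, (1, 0, 2))  # -> [column, row, slice]
    dr, dc = geom[3][0], geom[3][1]
    meta = {
        "spacing": np.array([dc, dr, slice_spacing]),
        "origin": slices[0].position.copy(),
        "orientation": np.column_stack([row_dir, col_dir, normal]),
    }
    return np.ascontiguousarray(data), meta


def _el(group, elem, vr, value):
    if isinstance(value, str):
        value = value.encode("ascii")
    if len(value) % 2:
        value += b"\x00" if vr in ("UI", "OB") else b" "
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr.encode("ascii") in _LONG_VRS:
        head += b"\x00\x00" + struct.pack("<I", len(value))
    else:
        head += struct.pack("<H", len(value))
    return head + value


def write_series(directory, data, spacing, origin, orientation):
    """Write ``data`` (indexed [column, row, slice]) as a DICOM series.

    Intensities are stored as int16 with rescale slope/intercept 1/0, so
    values must fit in int16 after rounding.
    """
    os.makedirs(directory, exist_ok=True)
    data = np.asarray(data)
    if data.ndim != 3:
        raise InputError("DICOM writer expects a 3-D volume")
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    orientation = np.asarray(orientation, float)
    nx, ny, nz = data.shape
    row_dir, col_dir, normal = orientation.T
    series_uid = f"{_UID_ROOT}.1.1"

    for k in range(nz):
        ipp = origin + orientation @ (spacing * np.array([0.0, 0.0, k]))
        pixels = np.round(data[:, :, k].T).astype("<i2")  # (rows, cols)
        ds = b"".join([
            _el(0x0008, 0x0016, "UI", "1.2.840.10008.5.1.4.1.1.2"),  # CT Image
            _el(0x0008, 0x0018, "UI", f"{series_uid}.{k + 1}"),
            _el(0x0008, 0x0060, "CS", "CT"),
            _el(0x0020, 0x000D, "UI", f"{_UID_ROOT}.1"),
            _el(0x0020, 0x000E, "UI", series_uid),
            _el(0x0020, 0x0013, "IS", str(k + 1)),
            _el(0x0020, 0x0032, "DS", "\\".join(repr(float(v)) for v in ipp)),
            _el(0x0020, 0x0037, "DS",
                "\\".join(repr(float(v)) for v in np.concatenate([row_dir, col_dir]))),
            _el(0x0028, 0x0002, "US", struct.pack("<H", 1)),
            _el(0x0028, 0x0004, "CS", "MONOCHROME2"),
            _el(0x0028, 0x0010, "US", struct.pack("<H", ny)),  # Rows
            _el(0x0028, 0x0011, "US", struct.pack("<H", nx)),  # Columns
            _el(0x0028, 0x0030, "DS", f"{float(spacing[1])!r}\\{float(spacing[0])!r}"),
            _el(0x0028, 0x0100, "US", struct.pack("<H", 16)),
            _el(0x0028, 0x0101, "US", struct.pack("<H", 16)),
            _el(0x0028, 0x0102, "US", struct.pack("<H", 15)),
            _el(0x0028, 0x0103, "US", struct.pack("<H", 1)),  # signed
            _el(0x0028, 0x1052, "DS", "0"),
            _el(0x0028, 0x1053, "DS", "1"),
            _el(0x7FE0, 0x0010, "OW", pixels.tobytes()),
        ])
        meta_body = b"".join([
            _el(0x0002, 0x0001, "OB", b"\x00\x01"),
            _el(0x0002, 0x0002, "UI", "1.2.840.10008.5.1.4.1.1.2"),
            _el(0x0002, 0x0003, "UI", f"{series_uid}.{k + 1}"),
            _el(0x0002, 0x0010, "UI", EXPLICIT_VR_LE),
        ])
        meta = _el(0x0002, 0x0000, "UL", struct.pack("<I", len(meta_body))) + meta_body
        with open(os.path.join(directory, f"slice_{k:04d}.dcm"), "wb") as fh:
            fh.write(b"\x00" * 128 + b"DICM")
            fh.write(meta)
            fh.write(ds)
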