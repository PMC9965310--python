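"""Minimal NRRD reader/writer for 3-D scalar volumes.

Supports the subset of NRRD needed here: attached data, ``raw`` or
``gzip`` encoding, little/big endian scalar types, and the ``space``
fields used to carry LPS geometry. Arrays use Fortran-style axis order
so ``sizes[0]`` is the fastest-varying file axis, matching the common
``arr[x, y, z]`` convention.
"""

from __future__ import annotations

import gzip
import re
import zlib

import numpy as np

from .errors import FormatError, InputError

_TYPE_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "short int": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "long long": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "unsigned long long": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_TYPE = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64", np.dtype(np.uint64): "uint64",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def _parse_vector(text: str) -> np.ndarray:
    text = text.strip()
    if not (text.startswith("(") and text.endswith(")")):
        raise FormatError(f"malformed NRRD vector: {text!r}")
    return np.array([float(v) for v in text[1:-1].split(",")])


def _format_vector(vec) -> str:
    return "(" + ",".join(repr(float(v)) for v in vec) + ")"


def read_nrrd(path):
    """Read an NRRD file.

    Returns ``(data, meta)`` where ``meta`` has keys ``spacing``,
    ``origin`` and ``orientation`` (identity defaults when the file
    carries no space information).
    """
    try:
        fh = open(path, "rb")
    except OSError as exc:
        raise InputError(f"cannot open NRRD file {path}: {exc}") from exc
    with fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise FormatError(f"{path}: not an NRRD file (magic {magic!r})")
        fields = {}
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: unexpected EOF in header")
            line = line.decode("ascii", "replace").rstrip("\r\n")
            if line == "":
                break
            if line.startswith("#"):
                continue
            if ":=" in line:  # key/value pair, not needed
                continue
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        payload = fh.read()

    for required in ("type", "dimension", "sizes", "encoding"):
        if required not in fields:
            raise FormatError(f"{path}: missing NRRD field '{required}'")
    ndim = int(fields["dimension"])
    sizes = [int(v) for v in fields["sizes"].split()]
    if len(sizes) != ndim:
        raise FormatError(f"{path}: sizes/dimension mismatch")
    try:
        dtype = np.dtype(_TYPE_TO_DTYPE[fields["type"].lower()])
    except KeyError:
        raise FormatError(f"{path}: unsupported NRRD type {fields['type']!r}") from None
    if dtype.itemsize > 1:
        endian = fields.get("endian", "little")
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")

    encoding = fields["encoding"].lower()
    if encoding == "raw":
        buf = payload
    elif encoding in ("gzip", "gz"):
        try:
            buf = gzip.decompress(payload)
        except (OSError, zlib.error) as exc:
            raise FormatError(f"{path}: corrupt gzip payload: {exc}") from exc
    else:
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")

    count = int(np.prod(sizes))
    expected = count * dtype.itemsize
    if len(buf) < expected:
        raise FormatError(f"{path}: truncated data ({len(buf)} < {expected} bytes)")
    data = np.frombuffer(buf[:expected], dtype=dtype).reshape(sizes, order="F")

    meta = {
        "spacing": np.ones(ndim),
        "origin": np.zeros(ndim),
        "orientation": np.eye(ndim),
    }
    if "space directions" in fields:
        toks = re.findall(r"\([^)]*\)", fields["space directions"])
        if len(toks) != ndim:
            raise FormatError(f"{path}: expected {ndim} space directions")
        cols = [_parse_vector(tok) for tok in toks]
        mat = np.stack(cols, axis=1)  # columns = per-axis direction * spacing
        spacing = np.linalg.norm(mat, axis=0)
        if np.any(spacing <= 0):
            raise FormatError(f"{path}: degenerate space directions")
        meta["spacing"] = spacing
        meta["orientation"] = mat / spacing
    if "space origin" in fields:
        meta["origin"] = _parse_vector(fields["space origin"])
    meta["space"] = fields.get("space", "left-posterior-superior")
    return np.asarray(data), meta


def write_nrrd(path, data, spacing=None, origin=None, orientation=None,
               encoding="gzip"):
    """Write ``data`` as an attached-data NRRD file (LPS space)."""
    data = np.asarray(data)
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    if data.dtype not in _DTYPE_TO_TYPE:
        data = data.astype(np.float64)
    ndim = data.ndim
    spacing = np.ones(ndim) if spacing is None else np.asarray(spacing, float)
    origin = np.zeros(ndim) if origin is None else np.asarray(origin, float)
    orientation = np.eye(ndim) if orientation is None else np.asarray(orientation, float)

    dirs = orientation * spacing[np.newaxis, :]
    lines = [
        "NRRD0004",
        "# generated by rwnseg",
        f"type: {_DTYPE_TO_TYPE[data.dtype]}",
        f"dimension: {ndim}",
        "space: left-posterior-superior" if ndim == 3 else f"space dimension: {ndim}",
        "sizes: " + " ".join(str(s) for s in data.shape),
        "space directions: " + " ".join(_format_vector(dirs[:, i]) for i in range(ndim)),
        "kinds: " + " ".join(["domain"] * ndim),
        "endian: little",
        f"encoding: {encoding}",
        "space origin: " + _format_vector(origin),
        "",  # blank line terminates the header
        "",
    ]
    raw = np.ascontiguousarray(data.astype(data.dtype.newbyteorder("<"))).tobytes(order="F")
    if encoding == "raw":
        payload = raw
    elif encoding == "gzip":
        # mtime pinned for byte-identical reruns
        payload = gzip.compress(raw, mtime=0)
    else:
        raise FormatError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write("\n".join(lines).encode("ascii"))
        fh.write(payload)
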