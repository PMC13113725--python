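"""Minimal NRRD reader/writer (attached headers, raw or gzip encoding).

Covers the subset of NRRD used for volumetric masks: 3D arrays, scalar
types, `space directions` / `space origin` metadata in LPS or RAS.
Index order follows the NRRD convention (first listed axis fastest),
i.e. arrays are reshaped with Fortran order against the `sizes` field.
"""

from __future__ import annotations

import gzip
import re

import numpy as np

_TYPE_MAP = {
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

_INV_TYPE_MAP = {
    "i1": "int8", "u1": "uint8", "i2": "int16", "u2": "uint16",
    "i4": "int32", "u4": "uint32", "i8": "int64", "u8": "uint64",
    "f4": "float", "f8": "double",
}

_LPS_NAMES = {"left-posterior-superior", "lps"}
_RAS_NAMES = {"right-anterior-superior", "ras"}


def _parse_vector(tok: str) -> np.ndarray:
    tok = tok.strip()
    if tok == "none":
        return None
    nums = tok.strip("()").split(",")
    return np.asarray([float(v) for v in nums], dtype=float)


def read(path):
    """Read an NRRD file.

    Returns ``(data, header)`` where *data* is indexed ``data[i, j, k]``
    with axis order as listed in the file and *header* is a dict with
    parsed ``space directions`` / ``space origin`` when present.
    """
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise IOError(f"not an NRRD file: {path}")
        header: dict = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", errors="replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                key, val = text.split(":=", 1)
                header[key.strip()] = val.strip()
                continue
            key, val = text.split(":", 1)
            header[key.strip().lower()] = val.strip()
        payload = fh.read()

    if "type" not in header or "sizes" not in header:
        raise IOError(f"NRRD header missing required fields in {path}")
    dtype_code = _TYPE_MAP.get(header["type"].lower())
    if dtype_code is None:
        raise IOError(f"unsupported NRRD type {header['type']!r} in {path}")
    endian = header.get("endian", "little")
    prefix = "<" if endian == "little" else ">"
    dtype = np.dtype(prefix + dtype_code) if dtype_code[0] in "iuf" and dtype_code[1] != "1" else np.dtype(dtype_code)
    sizes = [int(v) for v in header["sizes"].split()]

    encoding = header.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise IOError(f"unsupported NRRD encoding {encoding!r} in {path}")

    count = int(np.prod(sizes))
    data = np.frombuffer(payload, dtype=dtype, count=count).reshape(sizes, order="F")

    parsed = {"sizes": sizes, "type": header["type"], "encoding": encoding}
    space = header.get("space", "").lower()
    parsed["space"] = space
    if "space directions" in header:
        toks = re.findall(r"\([^)]*\)|none", header["space directions"])
        dirs = [_parse_vector(t) for t in toks]
        parsed["space directions"] = np.asarray([d for d in dirs if d is not None], dtype=float)
    if "space origin" in header:
        parsed["space origin"] = _parse_vector(header["space origin"])
    return data, parsed


def write(path, data: np.ndarray, *, space_directions=None, space_origin=None,
          space: str = "left-posterior-superior", encoding: str = "gzip") -> None:
    """Write *data* as an attached-header NRRD file (LPS by default)."""
    data = np.ascontiguousarray(data)
    code = data.dtype.str.lstrip("<>=|")
    if code not in _INV_TYPE_MAP:
        raise IOError(f"unsupported dtype {data.dtype} for NRRD")
    lines = [
        "NRRD0004",
        "# generated by aortaquant",
        f"type: {_INV_TYPE_MAP[code]}",
        f"dimension: {data.ndim}",
        f"space: {space}",
        "sizes: " + " ".join(str(s) for s in data.shape),
    ]
    if space_directions is not None:
        sd = np.asarray(space_directions, dtype=float)
        lines.append("space directions: " + " ".join(
            "(" + ",".join(repr(float(v)) for v in col) + ")" for col in sd.T))
    lines.append("kinds: " + " ".join(["domain"] * data.ndim))
    if data.dtype.itemsize > 1:
        lines.append("endian: little")
        data = data.astype(data.dtype.newbyteorder("<"), copy=False)
    lines.append(f"encoding: {encoding}")
    if space_origin is not None:
        so = np.asarray(space_origin, dtype=float)
        lines.append("space origin: (" + ",".join(repr(float(v)) for v in so) + ")")
    header = "\n".join(lines) + "\n\n"

    payload = data.tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise IOError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def space_sign_flips(space: str) -> np.ndarray:
    """Per-axis sign flips converting the named space to LPS."""
    if space in _LPS_NAMES or space == "":
        return np.ones(3)
    if space in _RAS_NAMES:
        return np.asarray([-1.0, -1.0, 1.0])
    raise IOError(f"unsupported NRRD space {space!r}")
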