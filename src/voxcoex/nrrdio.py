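"""Minimal NRRD scalar-volume I/O.

Covers the subset of the NRRD format needed for expression-energy, mask and
annotation volumes: single-scalar N-D grids, attached data, ``raw``, ``gzip``
and ``ascii``/``text`` encodings, little-endian byte order. The first entry of
``sizes`` is the fastest-varying axis, so an array of shape ``(nx, ny, nz)``
is serialized in Fortran order and round-trips bit-exactly for ``raw`` and
``gzip`` encodings.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_MAGIC = "NRRD"

# NRRD type name -> numpy dtype (little-endian where width > 1 byte)
_NRRD_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "<i2", "signed short": "<i2", "int16": "<i2", "int16_t": "<i2",
    "ushort": "<u2", "unsigned short": "<u2", "uint16": "<u2",
    "int": "<i4", "signed int": "<i4", "int32": "<i4", "int32_t": "<i4",
    "uint": "<u4", "unsigned int": "<u4", "uint32": "<u4",
    "long long": "<i8", "int64": "<i8", "int64_t": "<i8",
    "unsigned long long": "<u8", "uint64": "<u8",
    "float": "<f4", "double": "<f8",
}

_DTYPE_TO_NRRD = {
    "int8": "int8", "uint8": "uint8",
    "int16": "int16", "uint16": "uint16",
    "int32": "int32", "uint32": "uint32",
    "int64": "int64", "uint64": "uint64",
    "float32": "float", "float64": "double",
}


class NrrdError(ValueError):
    """Raised on malformed or unsupported NRRD content."""


def read_nrrd(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD volume, returning ``(array, header)``.

    The array has shape ``tuple(sizes)`` with the first axis fastest
    (Fortran storage order on disk).
    """
    path = Path(path)
    raw = path.read_bytes()
    nl = raw.find(b"\n")
    if nl < 0 or not raw[:nl].decode("ascii", "replace").startswith(_MAGIC):
        raise NrrdError(f"{path}: not an NRRD file")
    header: dict = {}
    pos = nl + 1
    while True:
        nl = raw.find(b"\n", pos)
        if nl < 0:
            raise NrrdError(f"{path}: header not terminated by blank line")
        line = raw[pos:nl].decode("ascii", "replace").rstrip("\r")
        pos = nl + 1
        if line == "":
            break
        if line.startswith("#"):
            continue
        if ": " in line:
            key, _, value = line.partition(": ")
        elif ":=" in line:
            key, _, value = line.partition(":=")
        else:
            raise NrrdError(f"{path}: malformed header line {line!r}")
        header[key.strip().lower()] = value.strip()

    for required in ("type", "dimension", "sizes", "encoding"):
        if required not in header:
            raise NrrdError(f"{path}: missing header field '{required}'")
    if "data file" in header or "datafile" in header:
        raise NrrdError(f"{path}: detached data files are not supported")

    sizes = tuple(int(s) for s in header["sizes"].split())
    if len(sizes) != int(header["dimension"]):
        raise NrrdError(f"{path}: sizes/dimension mismatch")
    try:
        dtype = np.dtype(_NRRD_TO_DTYPE[header["type"]])
    except KeyError:
        raise NrrdError(f"{path}: unsupported type {header['type']!r}") from None
    if header.get("endian", "little") == "big" and dtype.itemsize > 1:
        dtype = dtype.newbyteorder(">")

    n = int(np.prod(sizes))
    encoding = header["encoding"].lower()
    body = raw[pos:]
    if encoding == "raw":
        data = np.frombuffer(body[: n * dtype.itemsize], dtype=dtype)
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(body), dtype=dtype, count=n)
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(body.split()[:n], dtype=dtype)
    else:
        raise NrrdError(f"{path}: unsupported encoding {encoding!r}")
    if data.size != n:
        raise NrrdError(f"{path}: expected {n} samples, got {data.size}")
    array = data.astype(dtype.newbyteorder("="), copy=False)
    return array.reshape(sizes, order="F"), header


def write_nrrd(
    path: str | Path,
    array: np.ndarray,
    encoding: str = "gzip",
    extra_fields: dict | None = None,
) -> None:
    """Write ``array`` as an attached-data NRRD volume.

    ``encoding`` is one of ``raw``, ``gzip``, ``ascii``. The first array axis
    is written as the fastest-varying axis.
    """
    path = Path(path)
    array = np.asarray(array)
    try:
        type_name = _DTYPE_TO_NRRD[array.dtype.name]
    except KeyError:
        raise NrrdError(f"unsupported dtype {array.dtype}") from None
    lines = [
        "NRRD0004",
        f"type: {type_name}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        f"encoding: {encoding}",
    ]
    if array.dtype.itemsize > 1 and encoding in ("raw", "gzip"):
        lines.append("endian: little")
    for key, value in (extra_fields or {}).items():
        lines.append(f"{key}: {value}")
    header = ("\n".join(lines) + "\n\n").encode("ascii")

    flat = np.ascontiguousarray(array.ravel(order="F"))
    if flat.dtype.itemsize > 1:
        flat = flat.astype(flat.dtype.newbyteorder("<"), copy=False)
    if encoding == "raw":
        body = flat.tobytes()
    elif encoding == "gzip":
        # mtime=0 keeps output byte-identical across reruns
        body = gzip.compress(flat.tobytes(), mtime=0)
    elif encoding in ("ascii", "text", "txt"):
        if flat.dtype.kind == "f":
            body = "\n".join(repr(float(v)) for v in flat).encode("ascii")
        else:
            body = "\n".join(str(int(v)) for v in flat).encode("ascii")
        body += b"\n"
    else:
        raise NrrdError(f"unsupported encoding {encoding!r}")
    path.write_bytes(header + body)
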