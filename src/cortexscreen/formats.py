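"""Minimal NRRD read/write for the volumes used in this package.

Only the subset of NRRD needed here is supported: raw little-endian
encoding, 3D arrays, detached from any orientation metadata beyond an
isotropic voxel size. Data is laid out in the conventional NRRD fashion
(first axis fastest, i.e. Fortran order on disk).
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np

_NRRD_MAGIC = "NRRD0004"

_TYPE_MAP = {
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
    np.dtype(np.int32): "int",
    np.dtype(np.int64): "longlong",
    np.dtype(np.uint8): "uchar",
    np.dtype(np.uint16): "ushort",
    np.dtype(np.uint32): "uint",
}
_INV_TYPE_MAP = {v: k for k, v in _TYPE_MAP.items()}
# common aliases found in NRRD headers
_INV_TYPE_MAP.update(
    {
        "float32": np.dtype(np.float32),
        "float64": np.dtype(np.float64),
        "double": np.dtype(np.float64),
        "int32": np.dtype(np.int32),
        "int64": np.dtype(np.int64),
        "unsigned char": np.dtype(np.uint8),
    }
)


def write_nrrd(path: str | os.PathLike, array: np.ndarray, voxel_size_um: float | None = None) -> None:
    """Write *array* to *path* as raw little-endian NRRD."""
    array = np.asarray(array)
    dtype = array.dtype
    if dtype == np.bool_:
        array = array.astype(np.uint8)
        dtype = array.dtype
    if dtype not in _TYPE_MAP:
        raise ValueError(f"unsupported dtype for NRRD output: {dtype}")
    lines = [
        _NRRD_MAGIC,
        "# written by cortexscreen",
        f"type: {_TYPE_MAP[dtype]}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        "encoding: raw",
        "endian: little",
    ]
    if voxel_size_um is not None:
        spacings = " ".join(str(float(voxel_size_um)) for _ in range(array.ndim))
        lines.append(f"spacings: {spacings}")
    header = "\n".join(lines) + "\n\n"
    data = array.astype(dtype.newbyteorder("<"), copy=False)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.ravel(order="F").tobytes())


def read_nrrd(path: str | os.PathLike) -> Tuple[np.ndarray, dict]:
    """Read a raw-encoded NRRD file; returns (array, header-fields dict)."""
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii")
            if line in ("\n", "\r\n", ""):
                break
            line = line.strip()
            if line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError(f"{path}: only raw encoding is supported")
        dtype = _INV_TYPE_MAP.get(fields["type"])
        if dtype is None:
            raise ValueError(f"{path}: unsupported type {fields['type']!r}")
        if fields.get("endian", "little") != "little":
            dtype = dtype.newbyteorder(">")
        sizes = tuple(int(s) for s in fields["sizes"].split())
        count = int(np.prod(sizes))
        data = np.frombuffer(fh.read(), dtype=dtype, count=count)
    array = data.reshape(sizes, order="F")
    return np.ascontiguousarray(array), fields
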