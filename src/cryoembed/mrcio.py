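"""Minimal MRC2014 volume / image-stack I/O (mode 2, float32).

Internally volumes are indexed ``data[x, y, z]`` and images ``data[x, y]``;
the MRC convention stores sections as ``[z, y, x]`` (column = x fastest), so
arrays are transposed at this boundary.  Only the fields this package needs
are written: dimensions, mode 2, cell size (voxel size times grid), axis
order 1,2,3, min/max/mean, the 'MAP ' stamp and the little-endian machine
stamp.  Reading accepts any mode-0/1/2/6 little-endian file and converts to
float32.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc", "read_stack", "write_stack"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_BYTES = 1024


def _read_header(fh) -> dict:
    raw = fh.read(_HEADER_BYTES)
    if len(raw) < _HEADER_BYTES:
        raise ValueError("truncated MRC header")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    cella = struct.unpack("<3f", raw[40:52])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    mapstamp = raw[208:212]
    if mapstamp not in (b"MAP ", b"\x00\x00\x00\x00"):
        raise ValueError("not an MRC2014 file (missing MAP stamp)")
    return {"nx": nx, "ny": ny, "nz": nz, "mode": mode, "cella": cella, "nsymbt": nsymbt}


def _read_data(path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        h = _read_header(fh)
        if h["mode"] not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {h['mode']}")
        fh.seek(_HEADER_BYTES + h["nsymbt"])
        count = h["nx"] * h["ny"] * h["nz"]
        data = np.fromfile(fh, dtype=np.dtype(_MODE_DTYPES[h["mode"]]).newbyteorder("<"), count=count)
    if data.size != count:
        raise ValueError("truncated MRC data block")
    data = data.reshape(h["nz"], h["ny"], h["nx"]).astype(np.float32)
    voxel = h["cella"][0] / h["nx"] if h["nx"] else 1.0
    return data, float(voxel)


def _write(path, sections: np.ndarray, voxel_size: float) -> None:
    """``sections`` is (nz, ny, nx) float32."""
    nz, ny, nx = sections.shape
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(sections.min()), float(sections.max()),
                     float(sections.mean()))
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(sections.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        sections.astype("<f4").tofile(fh)


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a volume; returns (data indexed [x, y, z], voxel_size in A)."""
    data, voxel = _read_data(path)
    return np.ascontiguousarray(data.T), voxel


def write_mrc(path, data: np.ndarray, voxel_size: float) -> None:
    """Write a volume given ``data[x, y, z]``."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("volume must be 3D")
    _write(path, np.ascontiguousarray(data.T), float(voxel_size))


def read_stack(path) -> tuple[np.ndarray, float]:
    """Read an image stack; returns (data indexed [i, x, y], pixel_size)."""
    data, voxel = _read_data(path)
    return np.ascontiguousarray(np.transpose(data, (0, 2, 1))), voxel


def write_stack(path, data: np.ndarray, pixel_size: float) -> None:
    """Write an image stack given ``data[i, x, y]``."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("stack must be (n, D, D)")
    _write(path, np.ascontiguousarray(np.transpose(data, (0, 2, 1))), float(pixel_size))
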