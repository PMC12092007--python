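"""Minimal MRC (mode 2, 32-bit float) image I/O.

Covers exactly what this package needs: writing single 2D micrographs and
2D image stacks (class averages), and reading them back.  The MRC2014
1024-byte header is written with the mandatory geometry fields, map stamp
and machine stamp; everything else is zeroed.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


def write_mrc(data: np.ndarray, path: str | Path,
              pixel_size: float = 1.0) -> None:
    """Write a 2D image or a 3D stack as MRC mode 2 (little-endian float32).

    For a 3D array the leading axis is the section (stack) axis.
    ``pixel_size`` is recorded via the cell dimensions in angstrom.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        nz, ny, nx = 1, *data.shape
    elif data.ndim == 3:
        nz, ny, nx = data.shape
    else:
        raise ValueError(f"expected 2D or 3D array, got shape {data.shape}")

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)
    # mx, my, mz grid size == array size
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    # cell dimensions in angstrom; angles 90
    struct.pack_into("<3f", header, 40,
                     nx * pixel_size, ny * pixel_size, nz * pixel_size)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    # axis order mapcrs = 1,2,3
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76,
                     float(data.min()) if data.size else 0.0,
                     float(data.max()) if data.size else 0.0,
                     float(data.mean()) if data.size else 0.0)
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC mode-2 file; returns ``(array, pixel_size)``.

    A single-section file comes back 2D, multi-section files 3D.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode != _MODE_FLOAT32:
            raise ValueError(f"{path}: unsupported MRC mode {mode} "
                             "(only mode 2 float32 is handled)")
        cella_x = struct.unpack_from("<f", header, 40)[0]
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(_HEADER_SIZE + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    pixel_size = cella_x / nx if nx else 1.0
    arr = data.reshape(nz, ny, nx).astype(np.float32)
    return (arr[0] if nz == 1 else arr), float(pixel_size)
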