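"""Minimal C3D (coordinate 3D) point-data reader/writer.

C3D is the interchange format of the optical motion-capture world. This
module implements the subset the package needs: the 512-byte header block,
the POINT parameter group (LABELS, RATE, UNITS, SCALE, FRAMES, USED), and
the 3D point data section in either floating-point or scaled-integer
representation. Analog channels, multiple data formats per file, and
non-Intel processor encodings are out of scope and raise clear errors.

Points with a negative residual are treated as invalid (occluded) and read
back as NaN, per the format's convention.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["C3DError", "read_c3d_points", "write_c3d_points", "C3DPoints"]

_BLOCK = 512
_PROC_INTEL = 84  # 83 + 1


class C3DError(ValueError):
    """Raised for corrupt, truncated or unsupported C3D content."""


@dataclass
class C3DPoints:
    """Raw point payload of a C3D file, in file units."""

    positions: np.ndarray  # (frames, points, 3), NaN for invalid samples
    labels: list[str]
    rate: float
    units: str | None


# --------------------------------------------------------------------------
# reading


def _read_params(raw: bytes, start: int):
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(raw) < start + 4:
        raise C3DError("truncated parameter section")
    proc = raw[start + 3]
    if proc != _PROC_INTEL:
        raise C3DError(f"unsupported processor type {proc} (only Intel/DEC-83+1 handled)")
    groups: dict[int, str] = {}
    params: dict[int, dict[str, tuple]] = {}
    pos = start + 4
    while True:
        if pos + 2 > len(raw):
            break
        nname = struct.unpack_from("b", raw, pos)[0]
        gid = struct.unpack_from("b", raw, pos + 1)[0]
        if gid == 0 or nname == 0:
            break
        nname = abs(nname)
        name = raw[pos + 2 : pos + 2 + nname].decode("ascii", "replace").upper()
        off_pos = pos + 2 + nname
        offset = struct.unpack_from("<h", raw, off_pos)[0]
        next_pos = off_pos + offset
        body = off_pos + 2
        if gid < 0:  # group definition
            groups[-gid] = name
        else:  # parameter
            dtype = struct.unpack_from("b", raw, body)[0]
            ndims = raw[body + 1]
            dims = list(raw[body + 2 : body + 2 + ndims])
            data_pos = body + 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            itemsize = {-1: 1, 1: 1, 2: 2, 4: 4}.get(dtype)
            if itemsize is None:
                raise C3DError(f"unknown parameter type {dtype} for {name}")
            payload = raw[data_pos : data_pos + count * itemsize]
            params.setdefault(gid, {})[name] = (dtype, dims, payload)
        if offset == 0:
            break
        pos = next_pos
    out: dict[str, dict[str, tuple]] = {}
    for gid, ps in params.items():
        gname = groups.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {}).update(ps)
    return out


def _param_scalar(entry, kind: str):
    dtype, dims, payload = entry
    if kind == "float":
        if dtype == 4:
            return struct.unpack_from("<f", payload)[0]
        if dtype == 2:
            return float(struct.unpack_from("<h", payload)[0])
    if kind == "int":
        if dtype == 2:
            return struct.unpack_from("<h", payload)[0]
        if dtype == 4:
            return int(struct.unpack_from("<f", payload)[0])
    raise C3DError(f"parameter has unexpected type {dtype}")


def _param_strings(entry) -> list[str]:
    dtype, dims, payload = entry
    if dtype != -1:
        raise C3DError("expected a character parameter")
    if len(dims) == 1:
        return [payload.decode("ascii", "replace").strip()]
    width, count = dims[0], int(np.prod(dims[1:]))
    return [
        payload[i * width : (i + 1) * width].decode("ascii", "replace").strip()
        for i in range(count)
    ]


def read_c3d_points(path) -> C3DPoints:
    """Read the point section of a C3D file (positions left in file units)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _BLOCK:
        raise C3DError("file shorter than one C3D block")
    param_block, magic = raw[0], raw[1]
    if magic != 0x50:
        raise C3DError("not a C3D file (bad magic byte)")
    npoints = struct.unpack_from("<H", raw, 2)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_block = struct.unpack_from("<H", raw, 16)[0]
    rate = struct.unpack_from("<f", raw, 20)[0]

    params = _read_params(raw, (param_block - 1) * _BLOCK)
    point = params.get("POINT", {})
    if "RATE" in point:
        rate = _param_scalar(point["RATE"], "float")
    if "SCALE" in point:
        scale = _param_scalar(point["SCALE"], "float")
    if "USED" in point:
        npoints = _param_scalar(point["USED"], "int")
    nframes = last_frame - first_frame + 1
    if "FRAMES" in point:
        nframes = _param_scalar(point["FRAMES"], "int")
    labels = _param_strings(point["LABELS"]) if "LABELS" in point else [
        f"M{i + 1}" for i in range(npoints)
    ]
    labels = labels[:npoints]
    units = _param_strings(point["UNITS"])[0] if "UNITS" in point else None

    if npoints < 1 or nframes < 1:
        raise C3DError("no point data declared")
    offset = (data_block - 1) * _BLOCK
    count = nframes * npoints * 4
    if scale < 0:  # floating-point representation
        flat = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
        data = flat.reshape(nframes, npoints, 4).astype(float)
        xyz = data[:, :, :3].copy()
        residual = data[:, :, 3]
    else:  # scaled 16-bit integers
        flat = np.frombuffer(raw, dtype="<i2", count=count, offset=offset)
        data = flat.reshape(nframes, npoints, 4)
        xyz = data[:, :, :3].astype(float) * scale
        residual = data[:, :, 3].astype(float)
    xyz[residual < 0] = np.nan
    return C3DPoints(positions=xyz, labels=labels, rate=float(rate), units=units)


# --------------------------------------------------------------------------
# writing


def _char_param(name: str, gid: int, strings: list[str]) -> bytes:
    width = max(max((len(s) for s in strings), default=1), 1)
    payload = b"".join(s.ljust(width).encode("ascii") for s in strings)
    dims = bytes([width, len(strings)]) if len(strings) > 1 else bytes([width])
    return _param_entry(name, gid, -1, dims, payload)


def _param_entry(name: str, gid: int, dtype: int, dims: bytes, payload: bytes) -> bytes:
    head = struct.pack("bb", len(name), gid) + name.encode("ascii")
    body = struct.pack("b", dtype) + bytes([len(dims)]) + dims + payload + b"\x00"
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def _group_entry(name: str, gid: int) -> bytes:
    head = struct.pack("bb", len(name), -gid) + name.encode("ascii")
    body = b"\x00"
    return head + struct.pack("<h", 2 + len(body)) + body


def write_c3d_points(path, positions: np.ndarray, labels: list[str], rate: float,
                     units: str = "mm") -> None:
    """Write (frames, points, 3) positions as a floating-point C3D file.

    NaN samples are written as zero coordinates with residual -1 (the
    format's invalid-point convention) and round-trip back to NaN.
    """
    positions = np.asarray(positions, dtype=float)
    nframes, npoints, _ = positions.shape
    if len(labels) != npoints:
        raise ValueError("one label per point required")
    if nframes > 65535:
        raise C3DError("writer limited to 65535 frames")

    gid = 1
    ptable = b"\x01\x50\x00" + bytes([_PROC_INTEL])
    ptable += _group_entry("POINT", gid)
    ptable += _param_entry("USED", gid, 2, b"", struct.pack("<h", npoints))
    ptable += _param_entry("FRAMES", gid, 2, b"", struct.pack("<h", nframes))
    ptable += _param_entry("RATE", gid, 4, b"", struct.pack("<f", rate))
    ptable += _param_entry("SCALE", gid, 4, b"", struct.pack("<f", -1.0))
    ptable += _char_param("UNITS", gid, [units])
    ptable += _char_param("LABELS", gid, [str(l) for l in labels])
    ptable += b"\x00\x00"  # terminator
    nparam_blocks = -(-len(ptable) // _BLOCK)
    ptable = bytearray(ptable.ljust(nparam_blocks * _BLOCK, b"\x00"))
    ptable[2] = nparam_blocks

    data_block = 2 + nparam_blocks
    header = bytearray(_BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<H", header, 2, npoints)
    struct.pack_into("<H", header, 4, 0)  # no analog
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, nframes)
    struct.pack_into("<f", header, 12, -1.0)  # float representation
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<f", header, 20, rate)

    invalid = np.isnan(positions).any(axis=2)
    data = np.zeros((nframes, npoints, 4), dtype="<f4")
    data[:, :, :3] = np.where(invalid[:, :, None], 0.0, positions)
    data[:, :, 3] = np.where(invalid, -1.0, 0.0)
    payload = data.tobytes()
    payload += b"\x00" * (-len(payload) % _BLOCK)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(bytes(ptable))
        fh.write(payload)
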