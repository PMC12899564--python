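"""Readers and writers for XYZ text, PLY, and uncompressed LAS 1.2 clouds.

These are deliberately small, dependency-free implementations of the subsets
the pipeline needs: ASCII / binary-little-endian PLY with ``x y z`` (plus an
optional per-vertex ``label`` byte), whitespace XYZ with an optional fourth
label column, and LAS 1.2 point-format-0 with labels stored in the
classification byte. LAZ requires a decompressor and is rejected explicitly.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .pointcloud import PointCloud

__all__ = ["read_point_cloud", "write_point_cloud"]

_FORMATS = ("xyz", "ply", "las", "laz")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown point-cloud format {fmt!r} (expected one of {_FORMATS})")
    return fmt


def read_point_cloud(path, fmt: Optional[str] = None) -> PointCloud:
    """Read a point cloud; format inferred from the extension unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "las":
        return _read_las(path)
    raise ValueError("LAZ (compressed LAS) is not supported; decompress to .las first")


def write_point_cloud(cloud: PointCloud, path, fmt: Optional[str] = None) -> None:
    """Write a cloud; labels, when present, are emitted as a per-point field."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "las":
        _write_las(cloud, path)
    else:
        raise ValueError("LAZ writing is not supported; write .las instead")


# ---------------------------------------------------------------- XYZ text

def _read_xyz(path: Path) -> PointCloud:
    pts, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            try:
                xyz = [float(v) for v in fields[:3]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from None
            if not all(np.isfinite(xyz)):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            pts.append(xyz)
            if len(fields) >= 4:
                labels.append(int(float(fields[3])))
    lab = np.array(labels, dtype=np.int8) if len(labels) == len(pts) and labels else None
    return PointCloud(np.array(pts, dtype=float), lab)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(cloud.points):
            line = f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
            if cloud.labels is not None:
                line += f" {int(cloud.labels[i])}"
            fh.write(line + "\n")


# ---------------------------------------------------------------- PLY

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "short": ("<i2", 2), "ushort": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties on vertices unsupported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: vertex element lacks {axis!r} property")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                fields = fh.readline().split()
                if len(fields) < len(props):
                    raise ValueError(f"{path}: truncated vertex data")
                rows.append([float(v) for v in fields[: len(props)]])
            data = {name: np.array([r[i] for r in rows]) for i, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, _PLY_TYPES[typ][0]) for name, typ in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise ValueError(f"{path}: truncated vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            data = {name: rec[name].astype(float) for name, _ in props}
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    if not np.all(np.isfinite(pts)):
        bad = int(np.flatnonzero(~np.isfinite(pts).all(axis=1))[0])
        raise ValueError(f"{path}: non-finite coordinate at vertex {bad}")
    labels = data["label"].astype(np.int8) if "label" in data else None
    return PointCloud(pts, labels)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True,
               scalar: Optional[np.ndarray] = None, scalar_name: str = "wss") -> None:
    n = len(cloud)
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    if cloud.labels is not None:
        header.append("property uchar label")
        fields.append(("label", "<u1"))
    if scalar is not None:
        header.append(f"property double {scalar_name}")
        fields.append((scalar_name, "<f8"))
    header.append("end_header")
    rec = np.empty(n, dtype=np.dtype(fields))
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    if cloud.labels is not None:
        rec["label"] = cloud.labels.astype(np.uint8)
    if scalar is not None:
        rec[scalar_name] = scalar
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                fh.write((" ".join(f"{float(v):.17g}" if isinstance(v, float) else str(v)
                                   for v in row.tolist()) + "\n").encode("ascii"))


def write_ply_with_scalar(cloud: PointCloud, path, scalar: np.ndarray,
                          scalar_name: str = "wss", binary: bool = True) -> None:
    """Write a PLY with one extra per-vertex double field (e.g. WSS values)."""
    _write_ply(cloud, Path(path), binary=binary, scalar=np.asarray(scalar, float),
               scalar_name=scalar_name)


# ---------------------------------------------------------------- LAS 1.2

_LAS_HEADER_SIZE = 227
_LAS_SCALE = 0.001  # 1 mm quantum


def _write_las(cloud: PointCloud, path: Path) -> None:
    pts = cloud.points
    n = len(pts)
    offset = pts.min(axis=0)
    ixyz = np.round((pts - offset) / _LAS_SCALE).astype(np.int64)
    if np.abs(ixyz).max() > 2**31 - 1:
        raise ValueError("cloud extent exceeds LAS int32 range at 1 mm scale")
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # number of VLRs
    header[104] = 0  # point data format 0
    struct.pack_into("<H", header, 105, 20)  # point record length
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, _LAS_SCALE, _LAS_SCALE, _LAS_SCALE)
    struct.pack_into("<3d", header, 155, *offset)
    mx, mn = pts.max(axis=0), pts.min(axis=0)
    struct.pack_into("<6d", header, 179, mx[0], mn[0], mx[1], mn[1], mx[2], mn[2])
    rec = np.zeros(n, dtype=np.dtype([("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
                                      ("intensity", "<u2"), ("flags", "<u1"),
                                      ("classification", "<u1"), ("scan_angle", "<i1"),
                                      ("user_data", "<u1"), ("point_source", "<u2")]))
    rec["X"], rec["Y"], rec["Z"] = ixyz.T.astype(np.int32)
    if cloud.labels is not None:
        rec["classification"] = cloud.labels.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if raw[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    point_offset = struct.unpack_from("<I", raw, 96)[0]
    point_format = raw[104]
    rec_len = struct.unpack_from("<H", raw, 105)[0]
    n = struct.unpack_from("<I", raw, 107)[0]
    if point_format & 0x80:
        raise ValueError(f"{path}: LAZ-compressed point format; decompress to .las first")
    scale = np.array(struct.unpack_from("<3d", raw, 131))
    offset = np.array(struct.unpack_from("<3d", raw, 155))
    body = raw[point_offset:point_offset + rec_len * n]
    if len(body) < rec_len * n:
        raise ValueError(f"{path}: truncated point data")
    base = np.dtype([("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
                     ("flags", "<u1"), ("classification", "<u1"), ("scan_angle", "<i1"),
                     ("user_data", "<u1"), ("point_source", "<u2")])
    dtype = base if rec_len == base.itemsize else np.dtype(
        base.descr + [("extra", f"V{rec_len - base.itemsize}")])
    rec = np.frombuffer(body, dtype=dtype, count=n)
    pts = np.column_stack([rec["X"], rec["Y"], rec["Z"]]).astype(float) * scale + offset
    cls = rec["classification"]
    # all-zero classification is read as "no labels stored" (LAS default fill)
    labels = cls.astype(np.int8) if np.any(cls != 0) else None
    return PointCloud(pts, labels)
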