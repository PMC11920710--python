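"""Minimal binary little-endian PLY I/O for labeled surface point clouds.

One vertex element per surface point with properties
``x, y, z`` (double, mm), ``vessel`` (uchar code), ``station`` (ushort row
index), ``angle`` (double, rad) and optionally ``tawss`` (double, Pa).
Doubles keep write -> read round trips bitwise lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import SurfacePointCloud

__all__ = ["write_cloud_ply", "read_cloud_ply"]

_PROPS = [
    ("x", "<f8", "double"),
    ("y", "<f8", "double"),
    ("z", "<f8", "double"),
    ("vessel", "u1", "uchar"),
    ("station", "<u2", "ushort"),
    ("angle", "<f8", "double"),
]
_TAWSS_PROP = ("tawss", "<f8", "double")


def write_cloud_ply(
    path: str | Path,
    cloud: SurfacePointCloud,
    tawss: np.ndarray | None = None,
) -> None:
    props = list(_PROPS) + ([_TAWSS_PROP] if tawss is not None else [])
    n = cloud.n_points
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    header += [f"property {ply_t} {name}" for name, _, ply_t in props]
    header += [
        f"comment model_id {cloud.model_id}",
        f"comment grid {cloud.rows} {cloud.cols}",
        "end_header",
    ]
    rec = np.empty(n, dtype=[(name, np_t) for name, np_t, _ in props])
    rec["x"], rec["y"], rec["z"] = cloud.coords.T
    rec["vessel"] = cloud.vessel_label
    rec["station"] = cloud.station_index
    rec["angle"] = cloud.circ_angle
    if tawss is not None:
        if len(tawss) != n:
            raise ValueError(f"tawss length {len(tawss)} != point count {n}")
        rec["tawss"] = tawss
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_cloud_ply(path: str | Path) -> tuple[SurfacePointCloud, np.ndarray | None]:
    """Read a cloud written by :func:`write_cloud_ply`.

    Returns the cloud and its TAWSS labels (``None`` if the file has no
    ``tawss`` property).
    """
    raw = Path(path).read_bytes()
    end = raw.index(b"end_header\n") + len(b"end_header\n")
    lines = raw[:end].decode("ascii").splitlines()
    if lines[0] != "ply" or "format binary_little_endian 1.0" not in lines[1]:
        raise ValueError(f"{path}: not a binary little-endian PLY file")
    n = 0
    names: list[str] = []
    types: list[str] = []
    model_id, rows, cols = "", 0, 0
    ply_np = {"double": "<f8", "float": "<f4", "uchar": "u1", "ushort": "<u2", "uint": "<u4", "int": "<i4"}
    for ln in lines:
        parts = ln.split()
        if parts[0] == "element" and parts[1] == "vertex":
            n = int(parts[2])
        elif parts[0] == "property":
            types.append(parts[1])
            names.append(parts[2])
        elif parts[0] == "comment" and len(parts) >= 3 and parts[1] == "model_id":
            model_id = parts[2]
        elif parts[0] == "comment" and parts[1] == "grid":
            rows, cols = int(parts[2]), int(parts[3])
    dtype = np.dtype([(nm, ply_np[t]) for nm, t in zip(names, types)])
    rec = np.frombuffer(raw[end:], dtype=dtype, count=n)
    cloud = SurfacePointCloud(
        coords=np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float),
        vessel_label=rec["vessel"].astype(int),
        station_index=rec["station"].astype(int),
        circ_angle=rec["angle"].astype(float),
        model_id=model_id,
        rows=rows,
        cols=cols,
    )
    tawss = rec["tawss"].astype(float) if "tawss" in names else None
    return cloud, tawss
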