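"""Minimal ImageJ ROI archive support: polygon/freehand ROIs in ``.roi``
binary records and ``.zip`` archives, plus rasterization to boolean masks.

Only the subset needed for hand-drawn cortical region outlines is
implemented (polygon and freehand vertex lists; big-endian ImageJ header,
version 227). Vertices use ImageJ's convention: x grows rightwards (columns),
y grows downwards (rows), integer coordinates sit on pixel corners.

Rasterization includes a pixel when its center lies inside the polygon under
the even-odd rule; centers exactly on the boundary are included.
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path
from typing import Dict, Sequence

import numpy as np

_MAGIC = b"Iout"
_VERSION = 227
_TYPE_POLYGON = 0
_TYPE_FREEHAND = 7
_HEADER_SIZE = 64


def write_roi_bytes(vertices: Sequence[tuple[float, float]]) -> bytes:
    """Encode a polygon ROI as an ImageJ ``.roi`` binary record."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    xs = np.round(verts[:, 0]).astype(int)
    ys = np.round(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(verts)
    header = bytearray(_HEADER_SIZE)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _TYPE_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(header) + body


def read_roi_bytes(data: bytes) -> np.ndarray:
    """Decode a polygon/freehand ``.roi`` record to an (n, 2) xy array."""
    if data[0:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI record (bad magic)")
    roi_type = data[6]
    if roi_type not in (_TYPE_POLYGON, _TYPE_FREEHAND):
        raise ValueError(f"unsupported ROI type {roi_type}; "
                         "only polygon/freehand outlines are supported")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    if n < 3:
        raise ValueError(f"ROI has {n} vertices; need >= 3")
    off = _HEADER_SIZE
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=off).astype(float)
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=off + 2 * n).astype(float)
    return np.column_stack([xs + left, ys + top])


def write_roi_zip(path: str | Path,
                  rois: Dict[str, Sequence[tuple[float, float]]]) -> None:
    """Write named polygons to an ImageJ ROI zip archive."""
    if not rois:
        raise ValueError("refusing to write an empty ROI archive")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, verts in rois.items():
            zf.writestr(f"{name}.roi", write_roi_bytes(verts))


def read_roi_zip(path: str | Path) -> Dict[str, np.ndarray]:
    """Read every polygon/freehand ROI in an archive, keyed by entry name."""
    out: Dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path, "r") as zf:
        names = [n for n in zf.namelist() if n.lower().endswith(".roi")]
        if not names:
            raise ValueError(f"{path}: archive contains no .roi entries")
        for entry in names:
            out[entry[:-4]] = read_roi_bytes(zf.read(entry))
    return out


def rasterize_polygon(vertices: np.ndarray,
                      grid: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a polygon on an (H, W) grid.

    A pixel (row r, column c) has its center at (c + 0.5, r + 0.5) in
    ImageJ coordinates and is included when that center is inside the
    polygon (even-odd rule) or exactly on an edge.
    """
    verts = np.asarray(vertices, dtype=float)
    h, w = grid
    if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
            or verts[:, 0].max() > w or verts[:, 1].max() > h):
        raise ValueError("ROI extends outside the image grid")
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    px = cols.ravel() + 0.5
    py = rows.ravel() + 0.5
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    x1s, y1s = verts[:, 0], verts[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    eps = 1e-9
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        straddles = (y1 > py) != (y2 > py)
        if y2 != y1:
            xcross = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= straddles & (px < xcross)
        # boundary-tie inclusion: point collinear with and within the segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 > 0:
            t = ((px - x1) * dx + (py - y1) * dy) / seg2
            t = np.clip(t, 0.0, 1.0)
            d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
            on_edge |= d2 < eps
    return (inside | on_edge).reshape(h, w)
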