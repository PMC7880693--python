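"""Image, calibration and polygon-ROI input/output.

Coordinate conventions used throughout the package:

* pixels are indexed 0-based; the pixel with array index ``[row, col]`` has
  its *center* at the point ``(x, y) = (col, row)``;
* all geometry (ROI vertices, centroids, axes) lives in pixel units with
  ``x`` running along columns and ``y`` along rows (y pointing down);
* physical calibration (``pixel_size_um`` / ``voxel_size_um``) is applied
  only when a physical quantity (a volume in µm³) is produced, never to the
  geometry itself.

Images travel as plain TIFF arrays with canonical axis order ``(C, Y, X)``
for 2D multichannel images and ``(C, Z, Y, X)`` for stacks; calibration and
channel names live in a JSON sidecar, not in TIFF tags.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "PolygonROI",
    "read_image",
    "write_image",
    "read_roi",
    "write_roi",
    "rasterize",
    "points_in_polygon",
]


@dataclass
class CalibratedImage:
    """A multichannel image or z-stack with physical calibration.

    ``data`` has shape ``(C, Y, X)`` or ``(C, Z, Y, X)``; ``pixel_size_um``
    is ``(dy, dx)`` for 2D data and ``(dz, dy, dx)`` for stacks.
    """

    data: np.ndarray
    pixel_size_um: tuple[float, ...]
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"canonical image arrays have 3 or 4 axes, got {self.data.ndim}"
            )
        if any(s <= 0 for s in self.pixel_size_um):
            raise ValueError("pixel sizes must be positive")
        expected = self.data.ndim - 1
        if len(self.pixel_size_um) != expected:
            raise ValueError(
                f"{expected} pixel sizes required for {self.data.ndim}-axis data, "
                f"got {len(self.pixel_size_um)}"
            )
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels in array but "
                f"{len(self.channels)} channel names"
            )

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 4

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's array ``(Y, X)`` or ``(Z, Y, X)`` by name."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None
        return self.data[idx]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.pixel_size_um))


@dataclass
class PolygonROI:
    """An ordered vertex list delineating a gland or gland compartment.

    Vertices are ``(x, y)`` pairs in pixel units.  ``anchor``, when present,
    marks the proximal tip of the gland (near the duct) and fixes the
    orientation of axial profiles.
    """

    vertices: np.ndarray
    label: str | None = None
    anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) pairs")
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        if not self.shapely.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        """Shoelace area in px²."""
        return float(self.shapely.area)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex list."""
        xmin, ymin = self.vertices.min(axis=0)
        xmax, ymax = self.vertices.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        return points_in_polygon(points, self.vertices)


# ---------------------------------------------------------------------------
# point-in-polygon and rasterization


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test.

    Uses the half-open edge rule ``(y1 <= y) != (y2 <= y)`` with a strict
    ``x < x_intersection`` comparison, so two polygons sharing an edge
    partition the points on that edge consistently: each such point counts
    as inside exactly one of them.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    vx = np.asarray(vertices, dtype=float)[:, 0]
    vy = np.asarray(vertices, dtype=float)[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(vx)
    for i in range(n):
        x1, y1 = vx[i], vy[i]
        x2, y2 = vx[(i + 1) % n], vy[(i + 1) % n]
        if y1 == y2:  # horizontal edge never crosses a half-open scanline
            continue
        crosses = (y1 <= y) != (y2 <= y)
        if not crosses.any():
            continue
        xint = x1 + (y[crosses] - y1) * (x2 - x1) / (y2 - y1)
        hit = np.zeros(len(pts), dtype=bool)
        hit[crosses] = x[crosses] < xint
        inside ^= hit
    return inside


def rasterize(roi: PolygonROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Binary mask: True iff the pixel center lies inside the polygon.

    The pixel at ``[row, col]`` is tested at the point ``(col, row)``.
    """
    rows, cols = image_shape
    xmin, ymin, xmax, ymax = roi.bounds()
    c0 = max(int(np.floor(xmin)), 0)
    c1 = min(int(np.ceil(xmax)) + 1, cols)
    r0 = max(int(np.floor(ymin)), 0)
    r1 = min(int(np.ceil(ymax)) + 1, rows)
    mask = np.zeros((rows, cols), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    inside = points_in_polygon(pts, roi.vertices)
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


# ---------------------------------------------------------------------------
# file I/O


def write_image(
    path: str | Path, image: CalibratedImage, sidecar_path: str | Path | None = None
) -> None:
    """Write a TIFF plus JSON sidecar with calibration and channel names."""
    path = Path(path)
    tifffile.imwrite(path, image.data, photometric="minisblack")
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    sidecar = {
        "pixel_size_um": list(image.pixel_size_um),
        "channels": list(image.channels),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_image(
    path: str | Path, sidecar_path: str | Path | None = None
) -> CalibratedImage:
    """Read a TIFF and its calibration sidecar into canonical axis order.

    Axis conventions on read: 2 axes → a single-channel 2D image reshaped to
    ``(1, Y, X)``; 3 axes → ``(C, Y, X)``; 4 axes → ``(C, Z, Y, X)``.  A
    missing sidecar yields calibration 1.0 per axis and generic channel
    names, with a logged warning.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise ValueError(f"unsupported axis count {data.ndim} in {path}")
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    n_spatial = data.ndim - 1
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pixel_size = tuple(float(v) for v in meta["pixel_size_um"])
        channels = [str(c) for c in meta.get("channels", [])]
        if not channels:
            channels = [f"ch{i}" for i in range(data.shape[0])]
    else:
        logger.warning(
            "no calibration sidecar for %s; assuming 1.0 per axis", path
        )
        pixel_size = (1.0,) * n_spatial
        channels = [f"ch{i}" for i in range(data.shape[0])]
    return CalibratedImage(data=data, pixel_size_um=pixel_size, channels=channels)


def write_roi(path: str | Path, roi: PolygonROI) -> None:
    payload = {
        "label": roi.label,
        "vertices": [[float(x), float(y)] for x, y in roi.vertices],
        "anchor": list(map(float, roi.anchor)) if roi.anchor is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi(path: str | Path) -> PolygonROI:
    """Read a polygon ROI from JSON (or a two-column x,y CSV fallback)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and not _is_number(rows[0][0]):
            rows = rows[1:]
        vertices = [[float(r[0]), float(r[1])] for r in rows if r]
        return PolygonROI(vertices=np.asarray(vertices))
    payload = json.loads(path.read_text())
    anchor = payload.get("anchor")
    return PolygonROI(
        vertices=np.asarray(payload["vertices"], dtype=float),
        label=payload.get("label"),
        anchor=tuple(anchor) if anchor is not None else None,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
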