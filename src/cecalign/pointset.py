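"""Centroid point sets and their CSV interchange format.

A :class:`CentroidSet` is an ordered collection of sub-pixel cell-centroid
coordinates together with the dimensions of the frame they were extracted
from. Points use 0-based pixel coordinates, x = column, y = row, origin at
the top-left. The on-disk format is a plain CSV with an ``x,y`` header and a
``# frame <width> <height>`` comment line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError


@dataclass
class CentroidSet:
    points: np.ndarray  # (N, 2) float array of (x, y)
    frame_width: int
    frame_height: int
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError(f"points must be (N, 2), got {pts.shape}")
        self.points = pts
        if self.frame_width < 1 or self.frame_height < 1:
            raise InvalidInputError("frame dimensions must be >= 1 px")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def in_frame_mask(self) -> np.ndarray:
        """True for points inside [0, width) x [0, height).

        Transformed sets may carry points outside the frame; they stay in the
        set (flagged here) so exports remain lossless, while scoring ignores
        the flag.
        """
        return (
            (self.x >= 0)
            & (self.x < self.frame_width)
            & (self.y >= 0)
            & (self.y < self.frame_height)
        )

    def validate(self, min_separation: float = 2.0) -> None:
        """Enforce the frame-bounds and minimum-separation invariants."""
        if not np.all(self.in_frame_mask):
            raise InvalidInputError("points outside the frame bounds")
        if len(self) >= 2 and min_separation > 0:
            d, _ = cKDTree(self.points).query(self.points, k=2)
            if np.min(d[:, 1]) < min_separation:
                raise InvalidInputError(
                    f"points closer than min separation {min_separation} px"
                )

    def sorted_by_yx(self) -> "CentroidSet":
        order = np.lexsort((self.points[:, 0], self.points[:, 1]))
        return CentroidSet(
            self.points[order], self.frame_width, self.frame_height, self.source_id
        )


def mean_nn_spacing(cs: CentroidSet) -> float:
    """Mean nearest-neighbour distance of the set (requires >= 2 points)."""
    if len(cs) < 2:
        raise InvalidInputError("need at least 2 points for nearest-neighbour spacing")
    d, _ = cKDTree(cs.points).query(cs.points, k=2)
    return float(np.mean(d[:, 1]))


def write_csv(cs: CentroidSet, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# frame {cs.frame_width} {cs.frame_height}", "x,y"]
    lines += [f"{p[0]:.4f},{p[1]:.4f}" for p in cs.points]
    path.write_text("\n".join(lines) + "\n")


def read_csv(path: str | Path, source_id: str | None = None) -> CentroidSet:
    path = Path(path)
    width = height = None
    xs: list[float] = []
    ys: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["frame"] and len(parts) >= 3:
                width, height = int(parts[1]), int(parts[2])
            continue
        if line.lower().replace(" ", "") == "x,y":
            continue
        sx, sy = line.split(",")[:2]
        xs.append(float(sx))
        ys.append(float(sy))
    pts = np.column_stack([xs, ys]) if xs else np.empty((0, 2))
    if width is None or height is None:
        # no frame comment: fall back to the tight integer bounding box
        width = int(np.ceil(pts[:, 0].max())) + 1 if len(pts) else 1
        height = int(np.ceil(pts[:, 1].max())) + 1 if len(pts) else 1
    return CentroidSet(pts, width, height, source_id or path.stem)
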