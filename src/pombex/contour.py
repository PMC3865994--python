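"""Closed contour geometry: the SnakeContour container and polygon helpers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import draw

MIN_VERTICES = 8


@dataclass
class SnakeContour:
    """Closed ordered polygon of one candidate cell.

    ``vertices`` is an (n, 2) float array of ``(x, y)`` pixel coordinates;
    the contour is implicitly closed (no duplicated endpoint).  The arc
    parameterisation ``s`` in [0, 1] is implicit in the vertex ordering.
    """

    vertices: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < MIN_VERTICES and not self.degenerate:
            raise ValueError(
                f"closed contour needs >= {MIN_VERTICES} vertices, "
                f"got {len(self.vertices)}"
            )

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    def area(self) -> float:
        return polygon_area(self.vertices)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def rasterize(self, shape: Tuple[int, int]) -> np.ndarray:
        """Boolean mask of the enclosed pixels (vertices at pixel centers)."""
        mask = np.zeros(shape, dtype=bool)
        if len(self.vertices) < 3:
            return mask
        rr, cc = draw.polygon(self.y, self.x, shape=shape)
        mask[rr, cc] = True
        return mask

    def clamped(self, shape: Tuple[int, int]) -> "SnakeContour":
        v = self.vertices.copy()
        v[:, 0] = np.clip(v[:, 0], 0.0, shape[1] - 1.0)
        v[:, 1] = np.clip(v[:, 1], 0.0, shape[0] - 1.0)
        return SnakeContour(v, degenerate=self.degenerate)


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def mask_to_contour(mask: np.ndarray, spacing: float = 2.0) -> "SnakeContour":
    """Trace the boundary of a binary mask into a closed SnakeContour.

    The longest 0.5-level curve is used; the mask is padded so
    components touching the frame still yield closed curves.
    """
    from skimage import measure

    padded = np.pad(np.asarray(mask, dtype=float), 1)
    traces = measure.find_contours(padded, 0.5)
    if not traces:
        raise ValueError("mask is empty; no contour to trace")
    trace = max(traces, key=len)
    xy = np.column_stack([trace[:, 1] - 1, trace[:, 0] - 1])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return SnakeContour(resample_closed(xy, spacing=spacing))


def resample_closed(vertices: np.ndarray, spacing: float = 2.0,
                    min_vertices: int = MIN_VERTICES) -> np.ndarray:
    """Resample a closed polygon to (approximately) equal arc-length
    spacing, preserving orientation.

    The number of output vertices is ``max(min_vertices,
    round(perimeter / spacing))``.
    """
    v = np.asarray(vertices, dtype=np.float64)
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        return np.repeat(v[:1], min_vertices, axis=0)
    n_out = max(int(min_vertices), int(round(total / spacing)))
    targets = np.linspace(0.0, total, n_out, endpoint=False)
    x = np.interp(targets, arclen, closed[:, 0])
    y = np.interp(targets, arclen, closed[:, 1])
    return np.column_stack([x, y])
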