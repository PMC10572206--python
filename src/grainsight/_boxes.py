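"""Shared vectorized box arithmetic (internal).

Boxes are ``(N, 4)`` float arrays ``[xmin, ymin, xmax, ymax]`` in the half-open
pixel convention, so widths are ``xmax - xmin`` with no +1 correction.
"""

from __future__ import annotations

import numpy as np


def box_areas(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64)
    return (boxes[..., 2] - boxes[..., 0]) * (boxes[..., 3] - boxes[..., 1])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, shape ``(len(a), len(b))``. Disjoint pairs give 0."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0.0, None) * np.clip(y1 - y0, 0.0, None)
    union = box_areas(a)[:, None] + box_areas(b)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0.0, inter / union, 0.0)
    return out


def centers_sizes(boxes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (cx, cy, w, h) column views of an ``(N, 4)`` box array."""
    boxes = np.asarray(boxes, dtype=np.float64)
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    cx = boxes[:, 0] + 0.5 * w
    cy = boxes[:, 1] + 0.5 * h
    return cx, cy, w, h


def from_centers_sizes(cx, cy, w, h) -> np.ndarray:
    return np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h], axis=-1)
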