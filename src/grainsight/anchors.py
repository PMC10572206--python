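"""Anchor generation, ground-truth matching, and box delta encoding.

Anchors are reference rectangles tiled over a strided feature grid. For a grid
of ``feat_w x feat_h`` cells and ``k = len(scales) * len(ratios)`` shapes per
cell there are exactly ``feat_w * feat_h * k`` anchors. An anchor of scale ``s``
and height:width ratio ``r`` has area exactly ``s**2`` (``w = s/sqrt(r)``,
``h = s*sqrt(r)``) and is centered at ``((x + 0.5) * stride, (y + 0.5) * stride)``.

During training, anchors crossing the image boundary are flagged invalid and
excluded from loss computation; at test time all anchors are used and decoded
boxes are clipped to the image instead.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from ._boxes import centers_sizes, from_centers_sizes, iou_matrix

__all__ = [
    "AnchorConfig",
    "MatchResult",
    "generate_anchors",
    "match_anchors",
    "encode_box",
    "decode_box",
    "clip_boxes",
    "POSITIVE",
    "NEGATIVE",
    "IGNORE",
]

# anchor labels
POSITIVE = 1
NEGATIVE = 0
IGNORE = -1

#: default scales tuned for small grain insects (label areas 8^2..48^2 px)
DEFAULT_SCALES = (8.0, 16.0, 24.0, 32.0, 48.0)
#: height:width ratios 1:1, 1:2, 2:1
DEFAULT_RATIOS = (1.0, 0.5, 2.0)


@dataclass(frozen=True)
class AnchorConfig:
    scales: tuple[float, ...] = DEFAULT_SCALES
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    stride: int = 16

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or len(self.ratios) == 0:
            raise ValueError("anchor scales and ratios must be non-empty")
        s = tuple(float(v) for v in self.scales)
        if any(v <= 0 for v in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError(f"scales must be positive and strictly increasing: {s}")
        if any(float(r) <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def k(self) -> int:
        """Anchors per feature-map location."""
        return len(self.scales) * len(self.ratios)

    def cell_anchors(self) -> np.ndarray:
        """(k, 4) anchor shapes centered at the origin; scale-major ordering."""
        out = []
        for s in self.scales:
            for r in self.ratios:
                w = s / np.sqrt(r)
                h = s * np.sqrt(r)
                out.append([-0.5 * w, -0.5 * h, 0.5 * w, 0.5 * h])
        return np.asarray(out, dtype=np.float64)


@dataclass
class MatchResult:
    """Per-anchor training labels against one image's ground truth."""

    labels: np.ndarray  # int8, POSITIVE / NEGATIVE / IGNORE
    gt_index: np.ndarray  # int64, matched gt for positives, -1 otherwise
    max_iou: np.ndarray  # float64 best IoU per anchor (0 when no gt)

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == POSITIVE)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NEGATIVE)


def generate_anchors(
    config: AnchorConfig,
    feat_w: int,
    feat_h: int,
    image_w: int,
    image_h: int,
    mode: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """Tile anchors over a ``feat_w x feat_h`` grid.

    Returns ``(anchors, valid)`` where ``anchors`` has shape
    ``(feat_h * feat_w * k, 4)`` flattened row-major over (y, x, shape) and
    ``valid`` marks anchors fully inside the image (all True in test mode).
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    if feat_w < 1 or feat_h < 1:
        raise ValueError("feature-map dimensions must be >= 1")
    cell = config.cell_anchors()  # (k, 4)
    xs = (np.arange(feat_w, dtype=np.float64) + 0.5) * config.stride
    ys = (np.arange(feat_h, dtype=np.float64) + 0.5) * config.stride
    cx, cy = np.meshgrid(xs, ys)  # (feat_h, feat_w)
    shifts = np.stack([cx, cy, cx, cy], axis=-1).reshape(-1, 1, 4)
    anchors = (shifts + cell[None, :, :]).reshape(-1, 4)
    if mode == "train":
        valid = (
            (anchors[:, 0] >= 0.0)
            & (anchors[:, 1] >= 0.0)
            & (anchors[:, 2] <= image_w)
            & (anchors[:, 3] <= image_h)
        )
    else:
        valid = np.ones(len(anchors), dtype=bool)
    return anchors, valid


def match_anchors(
    anchors: np.ndarray,
    valid_mask: np.ndarray,
    gts: np.ndarray,
    pos_iou: float = 0.7,
    neg_iou: float = 0.3,
) -> MatchResult:
    """Label anchors positive/negative/ignore against ground-truth boxes.

    An anchor is positive when (i) it attains the maximum IoU over valid anchors
    for some gt (provided that IoU > 0), or (ii) its IoU with any gt exceeds
    ``pos_iou``. It is negative when valid and its best IoU is below ``neg_iou``.
    Everything else — including every invalid anchor — is ignored. Ties in the
    per-gt argmax break to the lowest anchor index; ties across gts to the lowest
    gt index (both are what NumPy's argmax yields).
    """
    if pos_iou <= neg_iou:
        raise ValueError(f"pos_iou ({pos_iou}) must exceed neg_iou ({neg_iou})")
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
    n = len(anchors)
    labels = np.full(n, IGNORE, dtype=np.int8)
    gt_index = np.full(n, -1, dtype=np.int64)
    max_iou = np.zeros(n, dtype=np.float64)

    if len(gts) == 0:
        labels[valid_mask] = NEGATIVE
        return MatchResult(labels, gt_index, max_iou)

    ious = iou_matrix(anchors, gts)  # (n, m)
    ious[~valid_mask] = 0.0
    max_iou = ious.max(axis=1)
    best_gt = ious.argmax(axis=1)  # lowest gt index on ties

    labels[valid_mask & (max_iou < neg_iou)] = NEGATIVE

    pos = valid_mask & (max_iou > pos_iou)
    # rule (i): per-gt argmax over valid anchors, when any overlap exists
    per_gt_best = ious.argmax(axis=0)  # lowest anchor index on ties
    per_gt_max = ious.max(axis=0)
    for g in range(len(gts)):
        if per_gt_max[g] > 0.0:
            pos[per_gt_best[g]] = True

    labels[pos] = POSITIVE
    gt_index[pos] = best_gt[pos]
    return MatchResult(labels, gt_index, max_iou)


def encode_box(gt: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Encode gt boxes as deltas ``(tx, ty, tw, th)`` relative to anchors.

    ``tx = (gx - ax) / aw``, ``ty = (gy - ay) / ah``, ``tw = ln(gw / aw)``,
    ``th = ln(gh / ah)`` with ``(gx, gy)``/``(ax, ay)`` the box centers.
    Accepts single boxes or ``(N, 4)`` arrays.
    """
    gt = np.asarray(gt, dtype=np.float64)
    anchor = np.asarray(anchor, dtype=np.float64)
    squeeze = gt.ndim == 1
    gx, gy, gw, gh = centers_sizes(gt.reshape(-1, 4))
    ax, ay, aw, ah = centers_sizes(anchor.reshape(-1, 4))
    if np.any(gw <= 0) or np.any(gh <= 0) or np.any(aw <= 0) or np.any(ah <= 0):
        raise ValueError("encode_box requires positive widths and heights")
    t = np.stack([(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=-1)
    return t[0] if squeeze else t


def decode_box(delta: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_box`: apply deltas to anchors, returning boxes."""
    delta = np.asarray(delta, dtype=np.float64)
    anchor = np.asarray(anchor, dtype=np.float64)
    squeeze = delta.ndim == 1
    d = delta.reshape(-1, 4)
    ax, ay, aw, ah = centers_sizes(anchor.reshape(-1, 4))
    if np.any(aw <= 0) or np.any(ah <= 0):
        raise ValueError("decode_box requires positive anchor sizes")
    cx = d[:, 0] * aw + ax
    cy = d[:, 1] * ah + ay
    w = np.exp(d[:, 2]) * aw
    h = np.exp(d[:, 3]) * ah
    boxes = from_centers_sizes(cx, cy, w, h)
    return boxes[0] if squeeze else boxes


def clip_boxes(boxes: np.ndarray, image_w: int, image_h: int) -> tuple[np.ndarray, np.ndarray]:
    """Clamp boxes to ``[0, W] x [0, H]``.

    Returns ``(clipped, degenerate)`` where ``degenerate`` flags boxes with zero
    area after clipping (fully outside the image or collapsed to a line).
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    out = boxes.copy()
    out[:, [0, 2]] = np.clip(out[:, [0, 2]], 0.0, float(image_w))
    out[:, [1, 3]] = np.clip(out[:, [1, 3]], 0.0, float(image_h))
    degenerate = (out[:, 2] - out[:, 0] <= 0.0) | (out[:, 3] - out[:, 1] <= 0.0)
    return out, degenerate
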