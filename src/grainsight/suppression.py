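"""Non-maximum suppression: hard NMS and Soft-NMS (linear / Gaussian decay).

Hard NMS deletes every box overlapping the current maximum by more than ``Nt``.
Soft-NMS instead decays scores: in *linear* mode a neighbor with
``IoU(M, b) >= Nt`` is rescaled by ``(1 - IoU)``; in *gaussian* mode every
remaining neighbor is rescaled by ``exp(-IoU^2 / sigma)`` (a continuous penalty
with no overlap gate). Boxes whose running score drops below ``score_floor``
are pruned. Equal scores break ties toward the lower input index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BoundingBox

__all__ = ["Detection", "SuppressionConfig", "hard_nms", "soft_nms", "suppress_per_class"]


@dataclass(frozen=True)
class Detection:
    """A scored, class-labeled box emitted by the detector."""

    box: BoundingBox
    label: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

_MODES = ("hard", "linear", "gaussian")


@dataclass(frozen=True)
class SuppressionConfig:
    mode: str = "gaussian"
    nt: float = 0.3
    sigma: float = 0.5
    score_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown suppression mode {self.mode!r}; expected {_MODES}")
        if not (0.0 < self.nt < 1.0):
            raise ValueError("Nt must lie in (0, 1)")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.score_floor < 1.0):
            raise ValueError("score_floor must lie in [0, 1)")


def _iou_one(box: np.ndarray, boxes: np.ndarray, areas: np.ndarray, area: float) -> np.ndarray:
    """IoU of one box against many (fast path for the NMS inner loop)."""
    x0 = np.maximum(box[0], boxes[:, 0])
    y0 = np.maximum(box[1], boxes[:, 1])
    x1 = np.minimum(box[2], boxes[:, 2])
    y1 = np.minimum(box[3], boxes[:, 3])
    inter = np.clip(x1 - x0, 0.0, None) * np.clip(y1 - y0, 0.0, None)
    union = area + areas - inter
    return np.where(union > 0.0, inter / union, 0.0)


def hard_nms(boxes: np.ndarray, scores: np.ndarray, nt: float = 0.3) -> np.ndarray:
    """Classical iterative NMS on a single-class set.

    Returns indices into the input, in selection (descending score) order.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores length mismatch")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(boxes) == 0:
        return np.zeros(0, dtype=np.int64)

    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    alive = np.ones(len(boxes), dtype=bool)
    keep: list[int] = []
    while True:
        cand = np.flatnonzero(alive)
        if cand.size == 0:
            break
        m = int(cand[np.argmax(scores[cand])])  # first max -> lowest index tie rule
        alive[m] = False
        keep.append(m)
        cand = np.flatnonzero(alive)
        if cand.size == 0:
            break
        ious = _iou_one(boxes[m], boxes[cand], areas[cand], areas[m])
        alive[cand[ious > nt]] = False
    return np.asarray(keep, dtype=np.int64)


def soft_nms(
    boxes: np.ndarray,
    scores: np.ndarray,
    config: SuppressionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-NMS on a single-class set.

    Returns ``(indices, final_scores)`` in selection order: at each step the
    current maximum keeps its running score and the remaining scores decay by
    the configured penalty; boxes falling below ``config.score_floor`` are
    pruned. ``mode='hard'`` reproduces :func:`hard_nms` with threshold ``nt``.
    """
    config = config or SuppressionConfig()
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    s = np.asarray(scores, dtype=np.float64).ravel().copy()
    if len(boxes) != len(s):
        raise ValueError("boxes and scores length mismatch")
    if len(boxes) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.float64)

    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    alive = np.ones(len(boxes), dtype=bool)
    keep: list[int] = []
    kept_scores: list[float] = []
    while True:
        cand = np.flatnonzero(alive)
        if cand.size == 0:
            break
        m = int(cand[np.argmax(s[cand])])
        alive[m] = False
        keep.append(m)
        kept_scores.append(float(s[m]))
        cand = np.flatnonzero(alive)
        if cand.size == 0:
            break
        ious = _iou_one(boxes[m], boxes[cand], areas[cand], areas[m])
        if config.mode == "linear":
            decay = np.where(ious >= config.nt, 1.0 - ious, 1.0)
        elif config.mode == "gaussian":
            decay = np.exp(-(ious**2) / config.sigma)
        else:  # hard: delete over-threshold neighbors outright
            decay = np.where(ious > config.nt, 0.0, 1.0)
        s[cand] *= decay
        alive[cand[s[cand] < config.score_floor]] = False
    return np.asarray(keep, dtype=np.int64), np.asarray(kept_scores, dtype=np.float64)


def suppress_per_class(
    boxes: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    config: SuppressionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured suppression independently within each class.

    ``labels`` may be any array of hashable class identifiers. Cross-class
    pairs never suppress each other. Returns ``(indices, final_scores)`` with
    indices into the input, concatenated over classes in sorted class order.
    """
    config = config or SuppressionConfig()
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels)
    keep_all: list[np.ndarray] = []
    score_all: list[np.ndarray] = []
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        if config.mode == "hard":
            kept = hard_nms(boxes[idx], scores[idx], config.nt)
            keep_all.append(idx[kept])
            score_all.append(scores[idx][kept])
        else:
            kept, new_scores = soft_nms(boxes[idx], scores[idx], config)
            keep_all.append(idx[kept])
            score_all.append(new_scores)
    if not keep_all:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.float64)
    return np.concatenate(keep_all), np.concatenate(score_all)
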