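"""Detection evaluation: IoU, greedy matching, AP/mAP, confusion matrix, k-fold.

True positives are detections whose IoU with an unmatched non-difficult ground
truth meets the threshold (default 0.5); each ground truth can absorb one
detection, so duplicates count as false positives. Difficult ground truths are
excluded from both matching targets and recall denominators (detections whose
only over-threshold overlap is with a difficult ground truth are ignored).
AP is the area under the precision envelope of the recall-sorted PR curve
(all-point interpolation); mAP averages APs over classes present in the ground
truth. The confusion matrix matches boxes class-agnostically first
(localization), then compares labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._boxes import iou_matrix
from .data_io import BoundingBox, ImageRecord
from .suppression import Detection

__all__ = [
    "iou",
    "match_detections",
    "average_precision",
    "mean_ap",
    "EvalReport",
    "evaluate_detections",
    "ConfusionMatrix",
    "confusion_matrix",
    "FoldSplit",
    "make_folds",
    "cross_validate",
]

TP, FP, IGNORED = 1, 0, -1


def iou(p, g) -> float:
    """Intersection-over-union of two boxes (scalar form of Jaccard index)."""
    pa = p.to_array() if isinstance(p, BoundingBox) else np.asarray(p, dtype=np.float64)
    ga = g.to_array() if isinstance(g, BoundingBox) else np.asarray(g, dtype=np.float64)
    for name, b in (("p", pa), ("g", ga)):
        if (b[2] - b[0]) * (b[3] - b[1]) <= 0:
            raise ValueError(f"box {name} has non-positive area: {b.tolist()}")
    return float(iou_matrix(pa, ga)[0, 0])


def match_detections(
    det_boxes: np.ndarray,
    det_scores: np.ndarray,
    gt_boxes: np.ndarray,
    gt_difficult: np.ndarray | None = None,
    iou_thresh: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Greedy score-ordered matching for one image and one class slice.

    Returns ``(flags, n_fn)``: per-detection flags in *input order* (1 = TP,
    0 = FP, -1 = ignored by a difficult ground truth) and the count of
    non-difficult ground truths left unmatched (false negatives).
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    det_scores = np.asarray(det_scores, dtype=np.float64).ravel()
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if gt_difficult is None:
        gt_difficult = np.zeros(len(gt_boxes), dtype=bool)
    gt_difficult = np.asarray(gt_difficult, dtype=bool)

    flags = np.zeros(len(det_boxes), dtype=np.int8)
    easy = np.flatnonzero(~gt_difficult)
    hard = np.flatnonzero(gt_difficult)
    matched = np.zeros(len(gt_boxes), dtype=bool)
    if len(det_boxes) == 0:
        return flags, len(easy)
    order = np.argsort(-det_scores, kind="stable")
    ious = iou_matrix(det_boxes, gt_boxes) if len(gt_boxes) else np.zeros((len(det_boxes), 0))
    for d in order:
        best_gt, best_iou = -1, 0.0
        for g in easy:
            if not matched[g] and ious[d, g] > best_iou:
                best_gt, best_iou = g, ious[d, g]
        if best_gt >= 0 and best_iou >= iou_thresh:
            matched[best_gt] = True
            flags[d] = TP
        elif len(hard) and ious[d, hard].max(initial=0.0) >= iou_thresh:
            flags[d] = IGNORED
        else:
            flags[d] = FP
    n_fn = int(np.sum(~matched[easy]))
    return flags, n_fn


def average_precision(scores: np.ndarray, tp_flags: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from dataset-pooled, scored TP/FP flags.

    ``tp_flags`` holds 1 for true positives and 0 for false positives (ignored
    detections must be removed beforehand). Ties in score keep input order,
    so callers should pool detections in (image, detection) order.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    tp_flags = np.asarray(tp_flags, dtype=np.float64).ravel()
    if n_gt <= 0:
        raise ValueError("average_precision requires n_gt > 0")
    if len(scores) == 0 or tp_flags.sum() == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp_flags[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: monotone non-increasing from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_ap(per_class_ap: dict[str, float]) -> float:
    """Mean of per-class APs (classes with ground truth only)."""
    if not per_class_ap:
        raise ValueError("no classes with ground truth")
    return float(np.mean(list(per_class_ap.values())))


@dataclass
class EvalReport:
    iou_thresh: float
    per_class: dict[str, dict[str, float]]  # precision, recall, ap, tp, fp, fn, n_gt
    map: float
    n_gt_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class).T
        df.index.name = "class"
        return df

    def summary(self) -> str:
        df = self.to_frame()
        cols = ["precision", "recall", "ap"]
        lines = [f"{'class':<12}" + "".join(f"{c:>12}" for c in cols)]
        for cls, row in df.iterrows():
            lines.append(f"{cls:<12}" + "".join(f"{row[c]:>12.4f}" for c in cols))
        lines.append(f"mAP@{self.iou_thresh:.2f} = {self.map:.4f}  (n_gt = {self.n_gt_total})")
        return "\n".join(lines)


def evaluate_detections(
    detections: Sequence[Sequence[Detection]],
    records: Sequence[ImageRecord],
    iou_thresh: float = 0.5,
    classes: Sequence[str] | None = None,
) -> EvalReport:
    """Score per-image detection lists against annotated records.

    Detections are pooled over the whole dataset per class; precision/recall
    are taken at the end of the ranked list and AP integrates the PR curve.
    Classes without ground truth are excluded from mAP with a warning.
    """
    if len(detections) != len(records):
        raise ValueError("detections and records length mismatch")
    if classes is None:
        classes = sorted({a.label for rec in records for a in rec.annotations})
    per_class: dict[str, dict[str, float]] = {}
    aps: dict[str, float] = {}
    n_gt_total = 0
    for cls in classes:
        scores, flags = [], []
        n_gt = n_fn_nodet = 0
        tp_count = fp_count = fn_count = 0
        for dets, rec in zip(detections, records):
            cls_dets = [d for d in dets if d.label == cls]
            det_boxes = (
                np.stack([d.box.to_array() for d in cls_dets])
                if cls_dets
                else np.zeros((0, 4))
            )
            det_scores = np.array([d.score for d in cls_dets])
            anns = [a for a in rec.annotations if a.label == cls]
            gt_boxes = (
                np.stack([a.box.to_array() for a in anns]) if anns else np.zeros((0, 4))
            )
            gt_diff = np.array([a.difficult for a in anns], dtype=bool)
            f, n_fn = match_detections(det_boxes, det_scores, gt_boxes, gt_diff, iou_thresh)
            keep = f != IGNORED
            scores.extend(det_scores[keep].tolist())
            flags.extend(f[keep].tolist())
            n_gt += int((~gt_diff).sum())
            fn_count += n_fn
        tp_count = int(sum(flags))
        fp_count = int(len(flags) - sum(flags))
        n_gt_total += n_gt
        if n_gt == 0:
            warnings.warn(f"class {cls!r} has no ground truth; excluded from mAP")
            continue
        ap = average_precision(np.array(scores), np.array(flags), n_gt) if flags else 0.0
        precision = tp_count / (tp_count + fp_count) if (tp_count + fp_count) else 0.0
        recall = tp_count / n_gt
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "ap": ap,
            "tp": tp_count,
            "fp": fp_count,
            "fn": fn_count,
            "n_gt": n_gt,
        }
        aps[cls] = ap
    return EvalReport(iou_thresh, per_class, mean_ap(aps), n_gt_total)


@dataclass
class ConfusionMatrix:
    """Rows are actual classes, columns predicted classes (matched pairs only)."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (C, C) int
    n_unmatched_gt: int
    n_unmatched_det: int
    n_gt_total: int  # non-difficult ground truths (percentage denominator)

    @property
    def percent(self) -> np.ndarray:
        if self.n_gt_total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return 100.0 * self.counts / self.n_gt_total

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(
    detections: Sequence[Sequence[Detection]],
    records: Sequence[ImageRecord],
    iou_thresh: float = 0.5,
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Localize first (class-agnostic greedy match), then compare labels."""
    if classes is None:
        classes = sorted({a.label for rec in records for a in rec.annotations})
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    n_unmatched_gt = n_unmatched_det = n_gt_total = 0
    for dets, rec in zip(detections, records):
        anns = [a for a in rec.annotations if not a.difficult]
        n_gt_total += len(anns)
        if not anns:
            n_unmatched_det += len(dets)
            continue
        gt_boxes = np.stack([a.box.to_array() for a in anns])
        matched = np.zeros(len(anns), dtype=bool)
        for d in sorted(dets, key=lambda d: -d.score):
            if d.label not in idx:
                continue
            ious = iou_matrix(d.box.to_array(), gt_boxes)[0]
            ious[matched] = -1.0
            g = int(np.argmax(ious))
            if ious[g] >= iou_thresh:
                matched[g] = True
                counts[idx[anns[g].label], idx[d.label]] += 1
            else:
                n_unmatched_det += 1
        n_unmatched_gt += int((~matched).sum())
    return ConfusionMatrix(classes, counts, n_unmatched_gt, n_unmatched_det, n_gt_total)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """k disjoint index subsets partitioning a dataset; sizes differ by <= 1."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        all_idx = sorted(i for fold in self.folds for i in fold)
        if all_idx != list(range(len(all_idx))):
            raise ValueError("folds must partition 0..n-1")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")


def make_folds(n_items: int, k: int = 10, seed: int = 0) -> FoldSplit:
    if n_items < k:
        raise ValueError(f"dataset size {n_items} smaller than k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    folds = tuple(tuple(int(i) for i in fold) for fold in np.array_split(perm, k))
    return FoldSplit(folds, seed)


def cross_validate(
    dataset: Sequence[ImageRecord],
    train_config,
    k: int = 10,
    seed: int = 0,
    train_fn: Callable | None = None,
    predict_fn: Callable | None = None,
    iou_thresh: float = 0.5,
) -> pd.DataFrame:
    """k-fold cross-validation: train on k-1 folds, evaluate on the held-out one.

    Returns a table of per-fold metrics plus ``mean`` and ``std`` rows (sample
    standard deviation, n-1 normalization). ``train_fn(records, train_config)``
    and ``predict_fn(model, record)`` default to the package detector and can
    be swapped for lightweight models in experiments.
    """
    if train_fn is None or predict_fn is None:
        from .detector import train_detector

        train_fn = train_fn or (lambda recs, cfg: train_detector(list(recs), cfg))
        predict_fn = predict_fn or (lambda model, rec: model.detect(rec.pixels))
    split = make_folds(len(dataset), k=k, seed=seed)
    rows = []
    for fi, fold in enumerate(split.folds):
        test_idx = set(fold)
        train_recs = [rec for i, rec in enumerate(dataset) if i not in test_idx]
        test_recs = [dataset[i] for i in fold]
        model = train_fn(train_recs, train_config)
        dets = [predict_fn(model, rec) for rec in test_recs]
        report = evaluate_detections(dets, test_recs, iou_thresh=iou_thresh)
        row = {"fold": fi, "map": report.map}
        for cls, m in report.per_class.items():
            row[f"ap_{cls}"] = m["ap"]
            row[f"precision_{cls}"] = m["precision"]
            row[f"recall_{cls}"] = m["recall"]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("fold")
    summary = pd.DataFrame(
        {"mean": df.mean(axis=0), "std": df.std(axis=0, ddof=1)}
    ).T
    return pd.concat([df, summary])
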