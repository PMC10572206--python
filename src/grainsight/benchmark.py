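"""Desk-scale end-to-end benchmark: train, detect, evaluate on synthetic scenes.

This is the package's reference experiment: a tiny stride-4 backbone trained
with the published optimizer settings (Adam, lr 5e-4, first-moment 0.9, weight
decay 5e-4) on 100 synthetic 160x160 grain scenes with 3-8 insects of two
classes, then evaluated on 30 held-out scenes at IoU 0.5, plus a clustered-
scene comparison of Gaussian Soft-NMS against hard NMS at the detection stage.
Problem sizes are chosen so the whole run completes in minutes on one CPU
while still exercising every stage of the pipeline.

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from .detector import MCSDetector, TrainConfig
from .evaluation import evaluate_detections
from .suppression import SuppressionConfig
from .synthetic import generate_records, small_scene_config

__all__ = ["run_end_to_end", "BENCHMARK_TRAIN_CONFIG"]

#: training schedule for the desk-scale benchmark: 36 epochs alternating
#: RPN/head every epoch (18 alternation cycles), published optimizer settings
BENCHMARK_TRAIN_CONFIG = TrainConfig(epochs=36, cycles=18)

N_TRAIN = 100
N_TEST = 30
N_CLUSTERED = 20


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_end_to_end(seed: int = 0, verbose: bool = False) -> dict:
    """Run the full benchmark; returns the measured quantities.

    Keys: ``map50`` (held-out mAP at IoU 0.5), per-class ``ap_<class>``,
    ``precision``/``recall`` (pooled over classes), ``soft_nms_recall`` and
    ``hard_nms_recall`` on aggregation-heavy scenes, counts and timings.
    """
    s_train, s_test, s_cluster, s_model = _sub_seeds(seed, 4)
    train_recs = generate_records(N_TRAIN, small_scene_config(seed=s_train))
    test_recs = generate_records(N_TEST, small_scene_config(seed=s_test))
    clustered = generate_records(
        N_CLUSTERED,
        small_scene_config(seed=s_cluster, cluster_prob=0.8, count_range=(5, 8)),
    )

    model = MCSDetector(classes=("Cfb", "Rfb"), arch="tiny", seed=s_model)
    config = replace(BENCHMARK_TRAIN_CONFIG, seed=s_model)
    t0 = time.time()
    model.fit(train_recs, config, verbose=verbose)
    train_time = time.time() - t0

    dets = [model.detect(rec.pixels, score_thresh=0.05) for rec in test_recs]
    report = evaluate_detections(dets, test_recs, iou_thresh=0.5)

    result: dict[str, float] = {"map50": report.map}
    tp = fp = n_gt = 0
    for cls, metrics in report.per_class.items():
        result[f"ap_{cls}"] = metrics["ap"]
        tp += metrics["tp"]
        fp += metrics["fp"]
        n_gt += metrics["n_gt"]
    result["precision"] = tp / (tp + fp) if tp + fp else 0.0
    result["recall"] = tp / n_gt if n_gt else 0.0
    result["n_gt_test"] = n_gt

    for mode, key in (("gaussian", "soft_nms_recall"), ("hard", "hard_nms_recall")):
        cfg = SuppressionConfig(mode=mode)
        cdets = [model.detect(r.pixels, score_thresh=0.05, suppression=cfg) for r in clustered]
        crep = evaluate_detections(cdets, clustered, iou_thresh=0.5)
        ctp = sum(v["tp"] for v in crep.per_class.values())
        cgt = sum(v["n_gt"] for v in crep.per_class.values())
        result[key] = ctp / cgt if cgt else 0.0
        result["n_gt_clustered"] = cgt
    result["train_seconds"] = train_time
    return result
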