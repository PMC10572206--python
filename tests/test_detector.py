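"""Backbone shapes, proposal contracts, losses, training behavior, serialization."""

import numpy as np
import pytest

import grainsight.nn as nn
from grainsight.anchors import AnchorConfig, MatchResult, generate_anchors, match_anchors
from grainsight.detector import (
    MCSDetector,
    TrainConfig,
    build_backbone,
    compute_losses,
    propose_rois,
    train_detector,
)
from grainsight.data_io import Annotation, BoundingBox
from grainsight.evaluation import evaluate_detections
from grainsight.suppression import SuppressionConfig
from grainsight.synthetic import SceneConfig, generate_records, small_scene_config


def tiny_scene():
    return SceneConfig(
        width=64, height=64, count_range=(1, 3), size_range=(8.0, 20.0),
        aspect_range=(0.5, 2.0), cluster_prob=0.2, seed=0,
    )


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def test_mcs_backbone_640x480_gives_40x30_features():
    bb = build_backbone("mcs", 0)
    x = np.zeros((3, 480, 640), dtype=np.float32)
    feat = bb.forward(x, train=False)
    assert feat.shape == (256, 30, 40)
    assert bb.stride == 16


def test_tiny_backbone_64x64_gives_16x16():
    bb = build_backbone("tiny", 0)
    feat = bb.forward(np.zeros((3, 64, 64), dtype=np.float32), train=False)
    assert feat.shape == (32, 16, 16)
    assert bb.stride == 4


def test_mcs_has_twelve_conv_layers_plus_fusion():
    bb = build_backbone("mcs", 0)
    conv_params = [p for p in bb.params() if p.name.endswith("weight")]
    assert len(conv_params) == 13  # 12 group convs + 1 fusion projection
    assert bb.fusion_conv is not None


def test_fusion_changes_values_but_not_shapes():
    bb = build_backbone("mcs", 0)
    x = np.random.default_rng(0).normal(size=(3, 64, 64)).astype(np.float32)
    with_fusion = bb.forward(x, train=False)
    fusion_conv = bb.fusion_conv
    bb.fusion_conv = None
    without = bb.forward(x, train=False)
    bb.fusion_conv = fusion_conv
    assert with_fusion.shape == without.shape
    assert not np.allclose(with_fusion, without)


def test_unknown_arch_rejected():
    with pytest.raises(ValueError):
        build_backbone("resnet", 0)


def test_backbone_commutes_with_horizontal_flip_under_symmetric_kernels():
    """With left-right symmetric kernels the conv stack must be covariant with
    mirroring: feature(hflip(x)) == hflip(feature(x))."""
    bb = build_backbone("tiny", 0)
    for p in bb.params():
        if p.name.endswith("weight") and p.value.shape[1] % 9 == 0:
            w = p.value.reshape(p.value.shape[0], -1, 3, 3)
            p.value = (0.5 * (w + w[..., ::-1])).reshape(p.value.shape).astype(np.float32)
    x = np.random.default_rng(1).normal(size=(3, 32, 32)).astype(np.float32)
    f1 = bb.forward(x[:, :, ::-1].copy(), train=False)
    f2 = bb.forward(x, train=False)[:, :, ::-1]
    np.testing.assert_allclose(f1, f2, atol=1e-4)


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def _disjoint_anchors(n, size=10.0, gap=30.0):
    out = []
    for i in range(n):
        x = (i % 10) * gap
        y = (i // 10) * gap
        out.append([x, y, x + size, y + size])
    return np.array(out)


def test_equal_scores_zero_deltas_return_first_n_by_tie_rule():
    anchors = _disjoint_anchors(40)
    obj = np.zeros(40)
    deltas = np.zeros((40, 4))
    boxes, scores = propose_rois(
        anchors=anchors, obj_logits=obj, deltas=deltas, image_w=400, image_h=400,
        suppression=SuppressionConfig(mode="gaussian"), pre_nms=40, post_nms=10,
    )
    np.testing.assert_allclose(boxes, anchors[:10])


def test_proposals_clipped_within_image():
    rng = np.random.default_rng(3)
    anchors = _disjoint_anchors(40) - 15.0  # push some outside
    obj = rng.normal(size=40)
    deltas = rng.normal(scale=0.2, size=(40, 4))
    boxes, _ = propose_rois(
        anchors=anchors, obj_logits=obj, deltas=deltas, image_w=200, image_h=200,
        suppression=SuppressionConfig(mode="gaussian"),
    )
    assert np.all(boxes[:, 0] >= 0) and np.all(boxes[:, 1] >= 0)
    assert np.all(boxes[:, 2] <= 200) and np.all(boxes[:, 3] <= 200)


def test_proposal_count_never_exceeds_n():
    rng = np.random.default_rng(4)
    cfg = AnchorConfig(scales=(8, 16, 24, 32, 48), stride=4)
    anchors, _ = generate_anchors(cfg, 40, 40, 160, 160, mode="test")
    obj = rng.normal(size=len(anchors))
    deltas = rng.normal(scale=0.1, size=(len(anchors), 4))
    boxes, scores = propose_rois(
        anchors=anchors, obj_logits=obj, deltas=deltas, image_w=160, image_h=160,
        suppression=SuppressionConfig(mode="gaussian"),
    )
    assert len(boxes) <= 600
    assert np.all(np.diff(scores) <= 1e-12)  # sorted by score descending


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_compute_losses_closed_forms():
    anchors = np.array([[0, 0, 10, 10], [20, 20, 30, 30.0]])
    gts = np.array([[0, 0, 10, 10.0]])
    match = match_anchors(anchors, np.ones(2, bool), gts)
    # perfect rpn predictions: +inf-ish logit for positive, -inf-ish for negative
    obj = np.array([50.0, -50.0])
    deltas = np.zeros((2, 4))
    # head: uniform 3-way prediction -> roi_cls = ln 3
    roi_logits = np.zeros((4, 3))
    roi_labels = np.array([0, 1, 2, 2])
    out = compute_losses(
        obj, deltas, anchors, match, gts,
        roi_cls_logits=roi_logits, roi_labels=roi_labels,
        roi_pred_deltas=np.zeros((4, 4)), roi_target_deltas=np.zeros((4, 4)),
    )
    assert out["rpn_cls"] < 1e-12
    assert out["rpn_loc"] == 0.0  # target delta is exactly zero
    np.testing.assert_allclose(out["roi_cls"], np.log(3.0))
    assert out["roi_loc"] == 0.0
    np.testing.assert_allclose(out["total"], sum(v for k, v in out.items() if k != "total"))


def test_compute_losses_requires_some_anchor_samples():
    anchors = np.array([[0, 0, 10, 10.0]])
    match = MatchResult(
        labels=np.array([-1], dtype=np.int8),
        gt_index=np.array([-1]),
        max_iou=np.zeros(1),
    )
    with pytest.raises(ValueError, match="rpn_cls"):
        compute_losses(np.zeros(1), np.zeros((1, 4)), anchors, match, np.zeros((0, 4)))


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

def _model(seed=0):
    return MCSDetector(
        classes=("Cfb", "Rfb"), arch="tiny",
        anchor_config=AnchorConfig(scales=(8.0, 16.0, 24.0), stride=4),
        seed=seed,
    )


def test_training_reduces_losses_per_phase():
    recs = generate_records(8, tiny_scene())
    tc = TrainConfig(epochs=8, cycles=4, seed=0, augment=False)
    model = _model()
    hist = model.fit(recs, tc)
    rpn_cls = [h["rpn_cls"] for h in hist if "rpn_cls" in h]
    roi_cls = [h["roi_cls"] for h in hist if "roi_cls" in h]
    assert rpn_cls[-1] < rpn_cls[0]
    assert roi_cls[-1] < roi_cls[0]


def test_empty_dataset_rejected():
    with pytest.raises(ValueError, match="empty"):
        _model().fit([], TrainConfig(epochs=1))


def test_all_difficult_annotations_rejected():
    recs = generate_records(2, tiny_scene())
    for rec in recs:
        rec.annotations = [
            Annotation(a.label, a.box, True) for a in rec.annotations
        ]
    with pytest.raises(ValueError, match="difficult"):
        _model().fit(recs, TrainConfig(epochs=1))


def test_untrained_model_with_threshold_one_detects_nothing():
    rec = generate_records(1, tiny_scene())[0]
    dets = _model().detect(rec.pixels, score_thresh=1.0)
    assert dets == []


def test_detect_rejects_images_smaller_than_stride():
    with pytest.raises(ValueError, match="stride"):
        _model().detect(np.zeros((2, 2, 3), dtype=np.uint8))


def test_detection_output_contract():
    rec = generate_records(1, tiny_scene())[0]
    dets = _model().detect(rec.pixels, score_thresh=0.2)
    for d in dets:
        assert d.score >= 0.2
        assert d.label in ("Cfb", "Rfb")
        assert 0 <= d.box.xmin < d.box.xmax <= rec.width
        assert 0 <= d.box.ymin < d.box.ymax <= rec.height


def test_no_trainable_parameters_after_roi_stage():
    """Everything trainable lives in convolutions before/beside the RoI stage;
    pooling and voting are parameter-free."""
    model = _model()
    names = {p.name for p in model.params()}
    assert all(("weight" in n) or ("bias" in n) for n in names)
    expected = (
        len(model.backbone.params())
        + len(model.rpn.params())
        + len(model.head.params())
    )
    assert len(model.params()) == expected  # nothing else owns parameters


def test_save_load_bit_exact_detections(tmp_path):
    rec = generate_records(1, tiny_scene())[0]
    model = _model(seed=3)
    path = model.save(tmp_path / "model.npz")
    clone = MCSDetector.load(path)
    d1 = model.detect(rec.pixels, score_thresh=0.1)
    d2 = clone.detect(rec.pixels, score_thresh=0.1)
    assert len(d1) == len(d2)
    for a, b in zip(d1, d2):
        assert a.label == b.label and a.score == b.score
        assert np.array_equal(a.box.to_array(), b.box.to_array())
    assert clone.anchor_config == model.anchor_config
    assert clone.detection_suppression == model.detection_suppression


def test_overfit_single_image_recovers_ground_truth():
    """Trained to overfit one scene, the detector must recover every insect at
    IoU >= 0.5 within a bounded step budget."""
    recs = generate_records(1, SceneConfig(
        width=96, height=96, count_range=(3, 3), size_range=(12.0, 24.0),
        aspect_range=(0.5, 2.0), cluster_prob=0.0, seed=5,
    ))
    rec = recs[0]
    model = _model(seed=1)
    tc = TrainConfig(epochs=1, cycles=1, seed=0, augment=False)
    opt_r = nn.Adam(model.backbone.params() + model.rpn.params())
    opt_h = nn.Adam(model.backbone.params() + model.head.params())
    rng = np.random.default_rng(0)
    for _ in range(220):
        model._train_step(rec, "rpn", opt_r, opt_h, rng, tc)
        model._train_step(rec, "head", opt_r, opt_h, rng, tc)
    dets = model.detect(rec.pixels, score_thresh=0.1)
    report = evaluate_detections([dets], [rec])
    recalls = [m["recall"] for m in report.per_class.values()]
    assert min(recalls) == 1.0  # every gt matched at IoU >= 0.5


def test_train_detector_wrapper_infers_classes():
    recs = generate_records(3, tiny_scene())
    tc = TrainConfig(epochs=2, cycles=1, seed=0, augment=False)
    model = train_detector(
        recs, tc, anchor_config=AnchorConfig(scales=(8.0, 16.0), stride=4)
    )
    assert set(model.classes) <= {"Cfb", "Rfb"}
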