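"""Two-stage dense small-object detector.

A fully convolutional backbone feeds two sibling heads sharing its feature map:
a Region Proposal Network (RPN) scoring/regressing anchors into candidate
regions, and a position-sensitive prediction head (PSPM) that classifies and
refines each candidate through parameter-free score-map pooling. Training
alternates RPN and head phases over a shared backbone with Adam (first-moment
coefficient 0.9), learning rate 5e-4 and weight decay 5e-4; proposals are
pruned with (Soft-)NMS, keeping the top N = 600.

Two backbones are provided: ``"mcs"`` — four groups of three 3x3 convolutions
(12 conv layers, four max-pools, total stride 16, 256 output channels) with a
feature-fusion pathway that adds a projected shallow-group map back onto the
final map to preserve microstructural detail — and ``"tiny"``, a two-group,
stride-4 variant for desk-scale experiments and tests.
"""

from __future__ import annotations


import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._boxes import iou_matrix
from .anchors import (
    AnchorConfig,
    MatchResult,
    clip_boxes,
    decode_box,
    encode_box,
    generate_anchors,
    match_anchors,
)
from .data_io import AUGMENT_OPS, BoundingBox, ImageRecord, augment_record
from .pspm import (
    RoI,
    pool_regression,
    pool_regression_grad,
    ps_roi_pool,
    ps_roi_pool_grad,
)
from .suppression import (
    Detection,
    SuppressionConfig,
    hard_nms,
    soft_nms,
    suppress_per_class,
)

# regression targets are normalized by these per-component stds (head only)
_DELTA_STD = np.array([0.1, 0.1, 0.2, 0.2])

__all__ = [
    "TrainConfig",
    "ArchSpec",
    "build_backbone",
    "MCSDetector",
    "train_detector",
    "detect",
    "propose_rois",
    "compute_losses",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published training recipe)."""

    lr: float = 5e-4
    epochs: int = 100
    lr_decay: float = 0.1
    lr_decay_at: float = 2.0 / 3.0  # fraction of epochs after which lr decays once
    weight_decay: float = 5e-4
    beta1: float = 0.9  # Adam first-moment coefficient ("momentum")
    pre_nms: int = 2000  # proposals kept before suppression
    post_nms: int = 600  # N: proposals kept after suppression
    roi_pos_iou: float = 0.5
    rois_per_image: int = 128
    roi_pos_fraction: float = 0.25  # 1:3 positive:negative
    rpn_samples: int = 256
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    cycles: int = 2  # alternating (RPN block, head block) repetitions
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.lr_decay) <= 0:
            raise ValueError("rates must be positive")
        if self.post_nms > self.pre_nms:
            raise ValueError("post_nms (N) must not exceed pre_nms")
        if self.epochs < 1 or self.cycles < 1:
            raise ValueError("epochs and cycles must be >= 1")


@dataclass(frozen=True)
class ArchSpec:
    """Backbone layout: channels per group, convs per group, fusion pathway."""

    name: str
    group_channels: tuple[int, ...]
    convs_per_group: int
    fusion: bool
    head_channels: int  # 1x1 expansion width feeding the PSPM heads

    @property
    def stride(self) -> int:
        return 2 ** len(self.group_channels)

    @property
    def out_channels(self) -> int:
        return self.group_channels[-1]


_ARCHS = {
    # 4 groups x 3 convs = 12 conv layers, stride 16, 256-d output, fusion on
    "mcs": ArchSpec("mcs", (32, 64, 128, 256), 3, True, 512),
    # desk-scale: 2 groups x 2 convs, stride 4
    "tiny": ArchSpec("tiny", (16, 32), 2, False, 64),
}


class Backbone:
    """Grouped 3x3-conv feature extractor with optional shallow-feature fusion.

    The fusion pathway projects the first group's post-pool map (stride 2 for
    "tiny", stride 2 of 4 groups -> uses the stride-4 map for "mcs") through a
    1x1 convolution and average-downsamples it onto the final map, adding the
    two — countering the loss of microstructural detail through repeated
    pooling. Output spatial size is input/stride (inputs are padded to a
    multiple of the stride beforehand).
    """

    def __init__(self, spec: ArchSpec, rng: np.random.Generator):
        self.spec = spec
        self.groups: list[nn.Sequential] = []
        cin = 3
        for gi, cout in enumerate(spec.group_channels):
            layers = []
            for ci in range(spec.convs_per_group):
                layers.append(nn.Conv2d(cin, cout, 3, rng, f"g{gi}c{ci}"))
                layers.append(nn.ReLU())
                cin = cout
            layers.append(nn.MaxPool2())
            self.groups.append(nn.Sequential(*layers))
        self.fusion_conv: nn.Conv2d | None = None
        self._fusion_group = 1  # fuse the output of the second group
        if spec.fusion:
            self.fusion_conv = nn.Conv2d(
                spec.group_channels[self._fusion_group], spec.out_channels, 1, rng, "fusion"
            )
        self._fusion_factor: int | None = None

    @property
    def stride(self) -> int:
        return self.spec.stride

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    def params(self) -> list[nn.Param]:
        ps = [p for g in self.groups for p in g.params()]
        if self.fusion_conv is not None:
            ps += self.fusion_conv.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        shallow = None
        for gi, g in enumerate(self.groups):
            x = g.forward(x, train=train)
            if self.fusion_conv is not None and gi == self._fusion_group:
                shallow = x
        if self.fusion_conv is not None and shallow is not None:
            fused = self.fusion_conv.forward(shallow, train=train)
            factor = shallow.shape[1] // x.shape[1]
            self._fusion_factor = factor
            c, fh, fw = fused.shape
            pooled = fused.reshape(c, fh // factor, factor, fw // factor, factor).mean(
                axis=(2, 4)
            )
            x = x + pooled.astype(np.float32)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gbranch = None
        if self.fusion_conv is not None:
            factor = self._fusion_factor
            gup = np.repeat(np.repeat(gout, factor, axis=1), factor, axis=2) / (factor**2)
            gbranch = self.fusion_conv.backward(np.ascontiguousarray(gup, dtype=np.float32))
        g = np.asarray(gout, dtype=np.float32)
        for gi in range(len(self.groups) - 1, -1, -1):
            if gbranch is not None and gi == self._fusion_group:
                g = g + gbranch  # fusion tap: branch gradient rejoins the trunk
            g = self.groups[gi].backward(g)
        return g


def build_backbone(arch: str, rng: np.random.Generator | int = 0) -> Backbone:
    """Construct a backbone by name: ``"mcs"`` (stride 16) or ``"tiny"`` (stride 4)."""
    if arch not in _ARCHS:
        raise ValueError(f"unknown backbone arch {arch!r}; expected one of {sorted(_ARCHS)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Backbone(_ARCHS[arch], rng)


class RPNHead:
    """3x3 conv + ReLU trunk with 1x1 objectness (k) and delta (4k) branches.

    Outputs are flattened to anchor order — row-major over (y, x, shape index)
    — matching :func:`grainsight.anchors.generate_anchors`.
    """

    def __init__(self, cin: int, k: int, rng: np.random.Generator):
        self.k = k
        self.conv = nn.Conv2d(cin, cin, 3, rng, "rpn.conv")
        self.relu = nn.ReLU()
        self.obj = nn.Conv2d(cin, k, 1, rng, "rpn.obj")
        self.loc = nn.Conv2d(cin, 4 * k, 1, rng, "rpn.loc")
        self._shape: tuple[int, int] | None = None

    def params(self) -> list[nn.Param]:
        return self.conv.params() + self.obj.params() + self.loc.params()

    def forward(self, feat: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        t = self.relu.forward(self.conv.forward(feat, train=train), train=train)
        obj = self.obj.forward(t, train=train)  # (k, fh, fw)
        loc = self.loc.forward(t, train=train)  # (4k, fh, fw)
        _, fh, fw = obj.shape
        self._shape = (fh, fw)
        obj_flat = obj.transpose(1, 2, 0).reshape(-1)
        loc_flat = loc.transpose(1, 2, 0).reshape(-1, 4)
        return obj_flat, loc_flat

    def backward(self, gobj_flat: np.ndarray, gloc_flat: np.ndarray) -> np.ndarray:
        fh, fw = self._shape
        gobj = gobj_flat.reshape(fh, fw, self.k).transpose(2, 0, 1).astype(np.float32)
        gloc = gloc_flat.reshape(fh, fw, 4 * self.k).transpose(2, 0, 1).astype(np.float32)
        gt = self.obj.backward(np.ascontiguousarray(gobj)) + self.loc.backward(
            np.ascontiguousarray(gloc)
        )
        return self.conv.backward(self.relu.backward(gt))


class PSPMHead:
    """1x1 expansion + 1x1 heads emitting k^2(C+1) class and 4k^2 regression maps."""

    def __init__(self, cin: int, cmid: int, k: int, n_classes: int, rng: np.random.Generator):
        self.k = k
        self.n_classes = n_classes  # foreground classes C
        self.expand = nn.Conv2d(cin, cmid, 1, rng, "pspm.expand")
        self.relu = nn.ReLU()
        self.cls = nn.Conv2d(cmid, k * k * (n_classes + 1), 1, rng, "pspm.cls")
        self.reg = nn.Conv2d(cmid, 4 * k * k, 1, rng, "pspm.reg")

    def params(self) -> list[nn.Param]:
        return self.expand.params() + self.cls.params() + self.reg.params()

    def forward(self, feat: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        t = self.relu.forward(self.expand.forward(feat, train=train), train=train)
        return self.cls.forward(t, train=train), self.reg.forward(t, train=train)

    def backward(self, gcls: np.ndarray, greg: np.ndarray) -> np.ndarray:
        gt = self.cls.backward(np.ascontiguousarray(gcls, dtype=np.float32)) + self.reg.backward(
            np.ascontiguousarray(greg, dtype=np.float32)
        )
        return self.expand.backward(self.relu.backward(gt))


# ---------------------------------------------------------------------------
# proposals and losses
# ---------------------------------------------------------------------------

def propose_rois(
    obj_logits: np.ndarray,
    deltas: np.ndarray,
    anchors: np.ndarray,
    image_w: int,
    image_h: int,
    suppression: SuppressionConfig,
    pre_nms: int = 2000,
    post_nms: int = 600,
    min_size: float = 2.0,
    delta_std: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Turn RPN outputs into at most ``post_nms`` scored candidate boxes.

    Decodes deltas onto anchors, clips to the image, drops degenerate boxes
    (zero area, or thinner than ``min_size`` pixels on either side after
    clipping), keeps the top ``pre_nms`` by objectness (ties to the lower
    anchor index), applies the configured suppression, and returns the top
    ``post_nms`` ``(boxes, scores)`` in image pixel coordinates sorted by
    score descending.
    """
    scores = nn.sigmoid(np.asarray(obj_logits, dtype=np.float64))
    deltas = np.asarray(deltas, dtype=np.float64)
    if delta_std is not None:
        deltas = deltas * delta_std
    boxes = decode_box(deltas, anchors)
    boxes, degenerate = clip_boxes(boxes, image_w, image_h)
    too_thin = ((boxes[:, 2] - boxes[:, 0]) < min_size) | (
        (boxes[:, 3] - boxes[:, 1]) < min_size
    )
    ok = ~degenerate & ~too_thin
    boxes, scores = boxes[ok], scores[ok]
    if len(boxes) == 0:
        return np.zeros((0, 4)), np.zeros(0)
    order = np.argsort(-scores, kind="stable")[:pre_nms]
    boxes, scores = boxes[order], scores[order]
    if suppression is None:
        keep, new_scores = np.arange(len(boxes)), scores
    elif suppression.mode == "hard":
        keep = hard_nms(boxes, scores, suppression.nt)
        new_scores = scores[keep]
    else:
        keep, new_scores = soft_nms(boxes, scores, suppression)
    keep = keep[:post_nms]
    new_scores = new_scores[:post_nms]
    return boxes[keep], new_scores


def _sample_balanced(
    rng: np.random.Generator,
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    total: int,
    pos_fraction: float,
    keep_ratio: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample positives/negatives for a loss batch.

    With ``keep_ratio`` the negative count is capped at
    ``pos/pos_fraction - pos`` (e.g. 1:3 when ``pos_fraction=0.25``) so scarce
    positives are not swamped; otherwise negatives fill the remaining budget.
    """
    n_pos = min(len(pos_idx), int(round(total * pos_fraction)))
    if len(pos_idx) > n_pos:
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False)
    if keep_ratio:
        per_pos = 1.0 / pos_fraction - 1.0
        budget = int(round(per_pos * max(len(pos_idx), 1)))
        n_neg = min(len(neg_idx), min(budget, total - len(pos_idx)))
    else:
        n_neg = min(len(neg_idx), total - len(pos_idx))
    if len(neg_idx) > n_neg:
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    return np.sort(pos_idx), np.sort(neg_idx)


def compute_losses(
    rpn_obj_logits: np.ndarray,
    rpn_deltas: np.ndarray,
    anchors: np.ndarray,
    match: MatchResult,
    gts: np.ndarray,
    roi_cls_logits: np.ndarray | None = None,
    roi_labels: np.ndarray | None = None,
    roi_pred_deltas: np.ndarray | None = None,
    roi_target_deltas: np.ndarray | None = None,
) -> dict[str, float]:
    """Named loss components: rpn_cls, rpn_loc, roi_cls, roi_loc, total.

    Classification terms are cross-entropies; localization terms are smooth-L1
    on encoded deltas of positive samples only. Raises when the RPN sample set
    is empty (no positive and no negative anchors).
    """
    pos = match.positive_indices
    neg = match.negative_indices
    if len(pos) == 0 and len(neg) == 0:
        raise ValueError("rpn_cls undefined: no positive and no negative anchors")
    sample = np.concatenate([pos, neg])
    targets = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    rpn_cls, _ = nn.sigmoid_bce_with_logits(np.asarray(rpn_obj_logits)[sample], targets)
    if len(pos):
        t_star = encode_box(gts[match.gt_index[pos]], anchors[pos])
        rpn_loc, _ = nn.smooth_l1(np.asarray(rpn_deltas)[pos], t_star)
    else:
        rpn_loc = 0.0
    roi_cls = roi_loc = 0.0
    if roi_cls_logits is not None and len(roi_cls_logits):
        roi_cls, _ = nn.softmax_cross_entropy(roi_cls_logits, roi_labels)
        fg = np.flatnonzero(np.asarray(roi_labels) < roi_cls_logits.shape[1] - 1)
        if len(fg):
            roi_loc, _ = nn.smooth_l1(
                np.asarray(roi_pred_deltas)[fg], np.asarray(roi_target_deltas)[fg]
            )
    out = {
        "rpn_cls": float(rpn_cls),
        "rpn_loc": float(rpn_loc),
        "roi_cls": float(roi_cls),
        "roi_loc": float(roi_loc),
    }
    out["total"] = sum(out.values())
    return out


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class MCSDetector:
    """Backbone + RPN + position-sensitive head with serializable parameters.

    The anchor, suppression and pooling configurations are captured at
    construction and embedded in saved models so inference cannot silently
    mismatch training.
    """

    def __init__(
        self,
        classes: tuple[str, ...],
        arch: str = "tiny",
        anchor_config: AnchorConfig | None = None,
        pspm_k: int = 3,
        proposal_suppression: SuppressionConfig | None = None,
        detection_suppression: SuppressionConfig | None = None,
        seed: int = 0,
    ):
        if len(classes) < 1:
            raise ValueError("at least one foreground class required")
        self.classes = tuple(classes)
        self.arch = arch
        self.pspm_k = int(pspm_k)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.backbone = build_backbone(arch, rng)
        if anchor_config is None:
            anchor_config = AnchorConfig(stride=self.backbone.stride)
        if anchor_config.stride != self.backbone.stride:
            raise ValueError(
                f"anchor stride {anchor_config.stride} != backbone stride "
                f"{self.backbone.stride}"
            )
        self.anchor_config = anchor_config
        self.proposal_suppression = proposal_suppression or SuppressionConfig(mode="gaussian")
        self.detection_suppression = detection_suppression or SuppressionConfig(mode="gaussian")
        self.rpn = RPNHead(self.backbone.out_channels, anchor_config.k, rng)
        self.head = PSPMHead(
            self.backbone.out_channels,
            _ARCHS[arch].head_channels,
            self.pspm_k,
            len(self.classes),
            rng,
        )
        self._anchor_cache: dict[tuple[int, int, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[nn.Param]:
        return self.backbone.params() + self.rpn.params() + self.head.params()

    def _prepare(self, pixels: np.ndarray) -> np.ndarray:
        """uint8 HWC -> normalized float32 CHW padded to a stride multiple."""
        if pixels is None:
            raise ValueError("record has no pixel data")
        h, w = pixels.shape[:2]
        s = self.backbone.stride
        if h < s or w < s:
            raise ValueError(f"image {w}x{h} smaller than backbone stride {s}")
        ph = (s - h % s) % s
        pw = (s - w % s) % s
        if ph or pw:
            pixels = np.pad(pixels, ((0, ph), (0, pw), (0, 0)), mode="edge")
        x = pixels.astype(np.float32) / 255.0 - 0.5
        return np.ascontiguousarray(x.transpose(2, 0, 1))

    def _anchors_for(self, img_w: int, img_h: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
        s = self.backbone.stride
        fw = -(-img_w // s)
        fh = -(-img_h // s)
        key = (fw, fh, mode)
        if key not in self._anchor_cache:
            self._anchor_cache[key] = generate_anchors(
                self.anchor_config, fw, fh, img_w, img_h, mode=mode
            )
        return self._anchor_cache[key]

    def _pooled_window_box(self, roi: RoI) -> np.ndarray:
        """Image-coordinate box of the cell-quantized window actually pooled.

        Regression deltas are encoded/decoded against this box rather than the
        continuous proposal: the pooled features cannot observe the sub-cell
        offset, so targets must be expressed relative to the pooled window.
        """
        x0, y0, w, h = roi.quantize()
        s = self.backbone.stride
        return np.array([x0 * s, y0 * s, (x0 + w) * s, (y0 + h) * s], dtype=np.float64)

    def _roi_from_box(self, box: np.ndarray, feat_h: int, feat_w: int) -> RoI:
        s = self.backbone.stride
        x0 = min(max(box[0] / s, 0.0), feat_w - 1.0)
        y0 = min(max(box[1] / s, 0.0), feat_h - 1.0)
        w = max((box[2] - box[0]) / s, 1.0)
        h = max((box[3] - box[1]) / s, 1.0)
        w = min(w, feat_w - math.floor(x0))
        h = min(h, feat_h - math.floor(y0))
        return RoI(x0, y0, w, h)

    # -- training -----------------------------------------------------------

    def fit(self, dataset: list[ImageRecord], config: TrainConfig, verbose: bool = False):
        """Alternating RPN/head training; returns the per-epoch loss history."""
        if not dataset:
            raise ValueError("empty dataset")
        if not any(not a.difficult for rec in dataset for a in rec.annotations):
            raise ValueError("no trainable targets: every annotation is difficult")
        rng = np.random.default_rng(config.seed)
        opt_rpn = nn.Adam(
            self.backbone.params() + self.rpn.params(),
            lr=config.lr,
            beta1=config.beta1,
            weight_decay=config.weight_decay,
        )
        opt_head = nn.Adam(
            self.backbone.params() + self.head.params(),
            lr=config.lr,
            beta1=config.beta1,
            weight_decay=config.weight_decay,
        )
        block = max(1, int(round(config.epochs / (2 * config.cycles))))
        decay_epoch = int(config.epochs * config.lr_decay_at)
        history: list[dict[str, float]] = []
        for epoch in range(config.epochs):
            if epoch == decay_epoch and epoch > 0:
                opt_rpn.lr *= config.lr_decay
                opt_head.lr *= config.lr_decay
            phase = "rpn" if (epoch // block) % 2 == 0 else "head"
            order = rng.permutation(len(dataset))
            sums: dict[str, float] = {}
            n_steps = 0
            for idx in order:
                rec = dataset[idx]
                if config.augment:
                    choice = rng.integers(0, len(AUGMENT_OPS) + 1)
                    if choice > 0:
                        rec = augment_record(rec, AUGMENT_OPS[choice - 1])
                losses = self._train_step(rec, phase, opt_rpn, opt_head, rng, config)
                if losses is None:
                    continue
                for k, v in losses.items():
                    sums[k] = sums.get(k, 0.0) + v
                n_steps += 1
            entry = {"epoch": float(epoch), "phase": 0.0 if phase == "rpn" else 1.0}
            entry.update({k: v / max(n_steps, 1) for k, v in sums.items()})
            history.append(entry)
            if verbose:
                parts = " ".join(f"{k}={v:.4f}" for k, v in entry.items() if k not in ("epoch", "phase"))
                print(f"epoch {epoch:3d} [{phase}] {parts}")
        return history

    def _train_step(self, rec, phase, opt_rpn, opt_head, rng, config):
        gts = rec.gt_boxes(include_difficult=False)
        labels = [a.label for a in rec.annotations if not a.difficult]
        x = self._prepare(rec.pixels)
        feat = self.backbone.forward(x, train=True)
        _, fh, fw = feat.shape
        if phase == "rpn":
            anchors, valid = self._anchors_for(rec.width, rec.height, "train")
            match = match_anchors(
                anchors, valid, gts, pos_iou=config.rpn_pos_iou, neg_iou=config.rpn_neg_iou
            )
            pos, neg = _sample_balanced(
                rng, match.positive_indices, match.negative_indices,
                config.rpn_samples, 0.5,
            )
            if len(pos) == 0 and len(neg) == 0:
                return None
            obj_flat, loc_flat = self.rpn.forward(feat, train=True)
            sample = np.concatenate([pos, neg]).astype(np.int64)
            targets = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            cls_loss, gcls = nn.sigmoid_bce_with_logits(obj_flat[sample], targets)
            gobj = np.zeros_like(obj_flat)
            gobj[sample] = gcls
            gloc = np.zeros_like(loc_flat)
            loc_loss = 0.0
            if len(pos):
                t_star = encode_box(gts[match.gt_index[pos]], anchors[pos]) / _DELTA_STD
                loc_loss, gl = nn.smooth_l1(loc_flat[pos], t_star)
                gloc[pos] = gl
            gfeat = self.rpn.backward(gobj, gloc)
            self.backbone.backward(gfeat)
            opt_rpn.step()
            opt_rpn.zero_grad()
            opt_head.zero_grad()
            return {"rpn_cls": cls_loss, "rpn_loc": loc_loss}

        # head phase: proposals from the frozen forward pass, gt boxes appended
        anchors, _ = self._anchors_for(rec.width, rec.height, "test")
        obj_flat, loc_flat = self.rpn.forward(feat, train=False)
        props, _ = propose_rois(
            obj_flat, loc_flat, anchors, rec.width, rec.height,
            self.proposal_suppression, config.pre_nms, config.post_nms,
            delta_std=_DELTA_STD,
        )
        if len(gts):
            # gt boxes plus jittered copies guarantee positive RoIs (and
            # regression targets) even while the RPN is immature
            jitters = [gts]
            for _ in range(5):
                cx, cy, w, h = (gts[:, 0] + gts[:, 2]) / 2, (gts[:, 1] + gts[:, 3]) / 2, \
                    gts[:, 2] - gts[:, 0], gts[:, 3] - gts[:, 1]
                cx = cx + rng.uniform(-0.18, 0.18, len(gts)) * w
                cy = cy + rng.uniform(-0.18, 0.18, len(gts)) * h
                w = w * rng.uniform(0.75, 1.3, len(gts))
                h = h * rng.uniform(0.75, 1.3, len(gts))
                jit = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
                jit, degen = clip_boxes(jit, rec.width, rec.height)
                jitters.append(jit[~degen])
            extra = np.concatenate(jitters)
            props = np.concatenate([props, extra]) if len(props) else extra
        if len(props) == 0:
            return None
        ious = iou_matrix(props, gts) if len(gts) else np.zeros((len(props), 1))
        max_iou = ious.max(axis=1) if len(gts) else np.zeros(len(props))
        best_gt = ious.argmax(axis=1) if len(gts) else np.zeros(len(props), dtype=int)
        pos_idx = np.flatnonzero(max_iou >= config.roi_pos_iou)
        neg_idx = np.flatnonzero(max_iou < config.roi_pos_iou)
        pos_idx, neg_idx = _sample_balanced(
            rng, pos_idx, neg_idx, config.rois_per_image, config.roi_pos_fraction,
            keep_ratio=True,
        )
        sel = np.concatenate([pos_idx, neg_idx]).astype(np.int64)
        if len(sel) == 0:
            return None
        bg = len(self.classes)
        cls_index = {c: i for i, c in enumerate(self.classes)}
        roi_labels = np.full(len(sel), bg, dtype=np.int64)
        for out_i, p in enumerate(sel[: len(pos_idx)]):
            roi_labels[out_i] = cls_index[labels[best_gt[p]]]
        cls_maps, reg_maps = self.head.forward(feat, train=True)
        k, C = self.pspm_k, len(self.classes)
        rois = [self._roi_from_box(props[p], fh, fw) for p in sel]
        logits = np.stack([ps_roi_pool(cls_maps, r, k, C).mean(axis=(0, 1)) for r in rois])
        cls_loss, gl = nn.softmax_cross_entropy(logits, roi_labels)
        gcls_maps = np.zeros_like(cls_maps, dtype=np.float64)
        for gi, r in zip(gl, rois):
            gcls_maps += ps_roi_pool_grad(
                np.broadcast_to(gi / (k * k), (k, k, C + 1)), r, k, C, cls_maps.shape
            )
        greg_maps = np.zeros_like(reg_maps, dtype=np.float64)
        loc_loss = 0.0
        n_fg = len(pos_idx)
        if n_fg:
            fg_rois = rois[:n_fg]
            pred = np.stack(
                [pool_regression(reg_maps, r, k) for r in fg_rois]
            )
            roi_boxes = np.stack([self._pooled_window_box(r) for r in fg_rois])
            t_star = encode_box(gts[best_gt[sel[:n_fg]]], roi_boxes) / _DELTA_STD
            loc_loss, gd = nn.smooth_l1(pred, t_star)
            for gi, r in zip(gd, fg_rois):
                greg_maps += pool_regression_grad(gi, r, k, reg_maps.shape)
        gfeat = self.head.backward(gcls_maps, greg_maps)
        self.backbone.backward(gfeat)
        opt_head.step()
        opt_head.zero_grad()
        opt_rpn.zero_grad()
        return {"roi_cls": cls_loss, "roi_loc": loc_loss}

    # -- inference ----------------------------------------------------------

    def detect(
        self,
        pixels: np.ndarray,
        score_thresh: float = 0.05,
        suppression: SuppressionConfig | None = None,
        post_nms: int = 600,
        pre_nms: int = 2000,
    ) -> list[Detection]:
        """Run the full pipeline on one image; background is never emitted."""
        h, w = pixels.shape[:2]
        x = self._prepare(pixels)
        feat = self.backbone.forward(x, train=False)
        _, fh, fw = feat.shape
        anchors, _ = self._anchors_for(w, h, "test")
        obj_flat, loc_flat = self.rpn.forward(feat, train=False)
        props, _ = propose_rois(
            obj_flat, loc_flat, anchors, w, h, self.proposal_suppression, pre_nms,
            post_nms, delta_std=_DELTA_STD,
        )
        if len(props) == 0:
            return []
        cls_maps, reg_maps = self.head.forward(feat, train=False)
        k, C = self.pspm_k, len(self.classes)
        boxes, scores, labels = [], [], []
        for p in props:
            roi = self._roi_from_box(p, fh, fw)
            r = ps_roi_pool(cls_maps, roi, k, C).mean(axis=(0, 1))
            z = r - r.max()
            probs = np.exp(z) / np.exp(z).sum()
            c = int(np.argmax(probs))
            if c == C or probs[c] < score_thresh:
                continue  # background RoIs are never emitted
            delta = pool_regression(reg_maps, roi, k) * _DELTA_STD
            refined = decode_box(delta, self._pooled_window_box(roi))
            refined, degen = clip_boxes(refined, w, h)
            if degen[0] or refined[0, 2] - refined[0, 0] < 2 or refined[0, 3] - refined[0, 1] < 2:
                continue
            boxes.append(refined[0])
            scores.append(float(probs[c]))
            labels.append(self.classes[c])
        if not boxes:
            return []
        boxes = np.stack(boxes)
        scores = np.asarray(scores)
        labels_arr = np.asarray(labels)
        cfg = suppression or self.detection_suppression
        keep, final_scores = suppress_per_class(boxes, scores, labels_arr, cfg)
        out = [
            Detection(BoundingBox(*boxes[i]), str(labels_arr[i]), float(min(s, 1.0)))
            for i, s in zip(keep, final_scores)
            if s >= score_thresh
        ]
        out.sort(key=lambda d: -d.score)
        return out

    # -- serialization ------------------------------------------------------

    def save(self, path) -> Path:
        """Serialize parameters and all captured configs (bit-exact reload)."""
        path = Path(path)
        meta = {
            "classes": list(self.classes),
            "arch": self.arch,
            "pspm_k": self.pspm_k,
            "seed": self.seed,
            "anchor_config": {
                "scales": list(self.anchor_config.scales),
                "ratios": list(self.anchor_config.ratios),
                "stride": self.anchor_config.stride,
            },
            "proposal_suppression": asdict(self.proposal_suppression),
            "detection_suppression": asdict(self.detection_suppression),
        }
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)
        return path

    @classmethod
    def load(cls, path) -> "MCSDetector":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            model = cls(
                classes=tuple(meta["classes"]),
                arch=meta["arch"],
                anchor_config=AnchorConfig(
                    scales=tuple(meta["anchor_config"]["scales"]),
                    ratios=tuple(meta["anchor_config"]["ratios"]),
                    stride=meta["anchor_config"]["stride"],
                ),
                pspm_k=meta["pspm_k"],
                proposal_suppression=SuppressionConfig(**meta["proposal_suppression"]),
                detection_suppression=SuppressionConfig(**meta["detection_suppression"]),
                seed=meta["seed"],
            )
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
        return model


def train_detector(
    dataset: list[ImageRecord],
    train_config: TrainConfig | None = None,
    classes: tuple[str, ...] | None = None,
    **detector_kwargs,
) -> MCSDetector:
    """Build and train a detector on annotated records; returns the model."""
    if not dataset:
        raise ValueError("empty dataset")
    train_config = train_config or TrainConfig()
    if classes is None:
        classes = tuple(sorted({a.label for rec in dataset for a in rec.annotations}))
    model = MCSDetector(classes=classes, seed=train_config.seed, **detector_kwargs)
    model.fit(dataset, train_config)
    return model


def detect(
    pixels: np.ndarray,
    model: MCSDetector,
    suppression: SuppressionConfig | None = None,
    score_thresh: float = 0.05,
) -> list[Detection]:
    """Functional wrapper over :meth:`MCSDetector.detect`."""
    return model.detect(pixels, score_thresh=score_thresh, suppression=suppression)

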