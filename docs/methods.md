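# Methods

## Problem and model

`grainsight` detects and classifies small, densely aggregated insects
(body areas roughly 8²–48² px in a 640×480 frame) on cluttered grain-surface
backgrounds. It implements a two-stage, fully convolutional detector:

1. **Backbone.** Grouped 3×3 convolutions with ReLU and 2×2 max pooling.
   The `mcs` variant has four groups of three convolutions (12 conv layers,
   stride 16, 256 output channels) plus a *feature fusion channel*: the
   second group's stride-4 map is projected by a 1×1 convolution and
   average-downsampled onto the final map, preserving microstructural detail
   that repeated pooling would otherwise erase. The `tiny` variant (two
   groups, stride 4, 32 channels) is the desk-scale configuration used by the
   tests and benchmark; all contracts are identical.
2. **Region Proposal Network.** At each feature cell, `k = |scales|·|ratios|`
   anchors (default scales 8, 16, 24, 32, 48 px; height:width ratios 1:1,
   1:2, 2:1; area exactly `s²`) centred at `(cell + 0.5)·stride`. A 3×3 conv
   trunk feeds 1×1 objectness and 4k-delta heads. Anchors crossing the image
   boundary are excluded from training losses; at test time all anchors are
   decoded and the boxes clipped. Proposals are pruned with Soft-NMS and the
   top N = 600 kept.
3. **Position-sensitive prediction (PSPM).** 1×1 convolutions emit
   `k²(C+1)` class score maps and `4k²` class-agnostic regression maps
   (k = 3). Each RoI is split into k×k bins with cell-quantized edges
   `⌊i·w/k⌋ ≤ x < ⌈(i+1)·w/k⌉`; bin (i, j) average-pools only its own channel
   group. Class scores are voted (bin mean) and softmaxed; regression bins
   are averaged into a single (tx, ty, tw, th). Nothing after the RoI stage
   has trainable parameters.
4. **Suppression.** Hard NMS deletes neighbours above `Nt` (default 0.3).
   Soft-NMS decays scores instead: linear `s·(1−IoU)` for `IoU ≥ Nt`, or
   Gaussian `s·exp(−IoU²/σ)` with σ = 0.5 applied to every remaining box, with
   pruning below a floor of 0.001. The Gaussian decay uses a negative
   exponent: a positive exponent would inflate overlapping scores, the
   opposite of a penalty. Suppression is always per class.

### Box conventions

Internal boxes are 0-based half-open `[xmin, xmax) × [ymin, ymax)`;
VOC/labelImg files store 1-based inclusive integers, converted losslessly on
read/write (`xmin → xmin − 1`, `xmax` unchanged). Deltas follow the standard
parameterisation `tx = (gx − ax)/aw`, `tw = ln(gw/aw)`; encode/decode invert
to < 1e−6 px.

### Regression-target normalization and the pooled window

Head regression targets are divided component-wise by (0.1, 0.1, 0.2, 0.2)
before the smooth-L1 loss (predictions are re-scaled at decode time). This is
a numerical conditioning choice: unnormalized targets are small and make
gradients too weak to converge within a short schedule.

Targets are encoded against the **cell-quantized pooled window** (the RoI
after snapping to feature cells, mapped back to pixels) rather than the
continuous proposal box. The pooled features cannot observe the sub-cell
offset of the proposal; encoding against the continuous box would leave an
irreducible error of up to half a stride per edge, which is material for
insects only a few cells wide.

## Training procedure

Losses: binary cross-entropy on sampled anchor objectness (256 anchors per
image, at most half positive); softmax cross-entropy on sampled RoIs (up to
128, positives : negatives held at 1:3 so scarce positives are not swamped —
filling the budget with negatives collapses the head to "background");
smooth-L1 on deltas of positive samples only.

Anchor labels: positive iff argmax-IoU for some ground truth (when overlap
exists) or IoU > 0.7; negative iff best IoU < 0.3; RoI positives at IoU ≥ 0.5.
DIFFICULT annotations are never training targets.

Optimizer: Adam with first-moment coefficient 0.9 ("momentum"), learning rate
5e-4, weight decay 5e-4 (L2 added to gradients), one ×0.1 decay at ⅔ of the
epochs (the decay factor is part of the recipe; its placement is ours).

Training alternates epochs between an RPN phase and a head phase, both
updating the shared backbone; `cycles` controls the block length (default 2
cycles over the epoch budget; the benchmark alternates every epoch). During
head phases, proposals come from the current RPN (no gradient through
proposal coordinates), and ground-truth boxes plus five jittered copies
(centre shift ±0.18·size, scale 0.75–1.3) are appended to the RoI pool so the
head always sees positives — and diverse regression targets — even while the
RPN is immature. Augmentation draws uniformly from {identity, rot±90, hflip,
vflip} per image per epoch.

Degenerate proposals (zero area or thinner than 2 px after clipping) are
dropped: boundary anchors are untrained by design, and their decoded slivers
would otherwise flood the proposal ranking.

## Synthetic scenes

The generator emulates the statistics of stored-grain pest imagery, not its
photometry: a field of overlapping grain-coloured ellipses with an
illumination ramp and pixel noise; each insect is a dark rotated ellipse with
a front pronotum patch whose corner sharpness differs between the two classes
(sharp-cornered for "Cfb", rounded for "Rfb") along with a hue offset
(grey-brown vs reddish-brown), making the classes separable in principle.
Boxes are the tight pixel bounds of the rendered body; placement rejects
samples whose rendered size (√area, configured 8–48 px at 640×480) or aspect
ratio (0.3–2.2) leaves the configured ranges, so annotation statistics respect
the configuration with probability 1. Lab-like scenes hold 1–7 insects per
640×480 frame; field-like scenes 20–50. With `cluster_prob > 0`, groups of
3–5 insects are placed within a fraction of a body length of each other and
may overlap heavily — the regime score-decay suppression exists for.

What passing on these scenes does **not** show: robustness to real-world
posture variation, motion blur, specular grain highlights, occlusion by
kernels, or the subtle morphology that separates sibling species in real
imagery. The toolkit's geometry, suppression, pooling and evaluation logic is
exercised fully; the learned weights are not transferable.

Determinism: one integer seed drives everything; per-image seeds derive via
`numpy.random.SeedSequence((master_seed, index))`, so datasets of any size
are bit-reproducible.

## Evaluation protocol

Greedy score-descending matching to unmatched non-difficult ground truths at
IoU ≥ threshold (default 0.5); duplicates are false positives; detections
whose only over-threshold match is a DIFFICULT annotation are ignored, and
DIFFICULT ground truths never enter recall denominators. AP is the area under
the precision envelope over recall (all-point interpolation); mAP averages
over classes present in the ground truth. The confusion matrix localizes
class-agnostically first, then compares labels; percentages are relative to
the non-difficult ground-truth count, with unmatched detections and ground
truths reported separately. Cross-validation splits into k shuffled folds
whose sizes differ by at most one and reports mean ± sample (n−1) standard
deviation.

## Benchmark problem sizes

`grainsight.benchmark.run_end_to_end` trains the `tiny` detector on 100
synthetic 160×160 scenes (two classes, 3–8 insects of 10–32 px, aspect
0.5–2.0 — the small-object regime scaled to the smaller frame) for 36 epochs
alternating every epoch, then evaluates 30 held-out scenes at IoU 0.5 and
compares Gaussian Soft-NMS with hard NMS on 20 aggregation-heavy scenes
(`cluster_prob = 0.8`). These sizes keep the run in the minutes range on one
CPU while exercising every pipeline stage end to end.

## Known limitations

- The NumPy engine trains single-image batches with stride-1 convolutions
  only; it is a faithful but slow substitute for a GPU framework, so the
  full `mcs` backbone at 640×480 is supported for inference-scale use but not
  exercised by long training runs.
- Greedy matching is not an optimal assignment; on adversarial overlaps it
  can under-count TPs (tests verify optimality in the regimes where greedy is
  provably optimal).
- Soft-NMS ranking interacts with the score floor: in dense duplicate stacks
  a well-localized but lower-scored box can be pruned; the head's re-scoring
  and regression mitigate this, as designed.
- The two synthetic classes are separable by construction; real sibling
  species are not, and no claim about real-world class separability follows
  from these tests.
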