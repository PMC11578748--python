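# Methods

`sproutnet` detects and counts crop seedlings (class `Seedling`) and
look-alike weeds (class `Weed`) in overhead RGB imagery of the kind a
low-altitude UAV produces, and is organised around three modifications
of a nano-scale anchor-free one-stage detector: a multi-scale adaptive
stage block in the backbone, a bidirectional weighted feature-pyramid
neck that adds the fine P2 level, and the minimum-point-distance IoU
(MPDIoU) box-regression loss. Everything — forward pass, training,
evaluation, tracking, data synthesis — runs on CPU through a small
numpy reverse-mode autodiff core (`sproutnet.nn`) written for this
package.

## Baseline detector

The baseline replicates the public nano one-stage topology: a stride-2
stem, four backbone stages of (stride-2 conv, C2f stage block) with
widths 16/32/64/128/256 and stage depths 1/2/2/1, SPPF (three chained
5×5 stride-1 max pools) on the last stage, a PAN neck over P3/P4/P5,
and a decoupled head per scale whose box branch emits a 16-bin discrete
distribution per box side (decoded by expectation) and whose class
branch emits per-class logits. All convolutions are conv–batchnorm–SiLU
triplets. With two classes this model has 3,011,222 learnable scalars
(3.0 M), which anchors all architecture-fidelity checks below.

## Multi-scale adaptive block

`MultiScaleConv` splits its C input channels into four contiguous
groups A–D of C/4. A, B, C pass through 1×1, 3×3 and 5×5
conv-norm-SiLU branches (C/4 → C/4, stride 1, 'same' padding), giving
three receptive-field scales at a quarter of the width each. Each
processed group is reweighted by a channel attention: the per-channel
spatial mean (global average pooling) is passed through a softmax
*within that group*, so each group carries its own simplex of C/4
weights. Group D is concatenated untouched; a final 1×1 conv-norm-SiLU
mixes the C channels.

Design points that were genuinely open:

* **Attention descriptor.** The softmax needs a scalar per channel;
  global average pooling is the standard channel descriptor and is used
  here. The softmax is applied per group rather than across all 3C/4
  processed channels, so each scale competes only internally — this
  matches the block's purpose of letting every group emphasise its own
  informative channels.
* **What "the original feature map" means in the concat.** The block
  concatenates the three processed groups with the untouched D group
  (pre-mix width C). The alternative — concatenating with the full
  input, pre-mix width 7C/4 — is available as
  `MultiScaleConv(c, concat_full_input=True)`; the default is the
  variant whose assembled parameter count reproduces the published
  ablation sizes (see below).
* **Normalisation/activation on the branches.** All branches and the
  mixing conv carry batchnorm + SiLU; purely linear branches would
  destabilise training and do not match how such blocks are drawn in
  this detector family.
* Channel counts not divisible by 4 are a hard error — every stage
  width used here is a multiple of 8.

`MultiScaleBottleneck` is `x + MultiScaleConv(Conv3×3(x))`;
`MultiScaleC2f` is the C2f topology with every inner bottleneck
replaced by it. Because the grouped branches
((1+9+25)(C/4)² ≈ 2.2 C² weights plus a C² mix) replace one dense 3×3
convolution (9 C²), the stage block gets strictly lighter at equal
width and depth.

**Which C2f blocks the multi-scale flag converts.** The flag replaces
the bottleneck in *every* C2f of the network — the four backbone stages
and the neck's stage blocks. Converting the backbone alone yields
2.9 M for the backbone-only ablation variant, which does not reproduce
the published 2.7 M; converting all C2f positions yields 2,707,118
(2.7 M) exactly. Inside the BiFPN neck (below) only the P4
intermediate node uses the multi-scale block, which is both the neck's
stated design and the only choice that reproduces the published 1.9 M
full-model size *and* the 1.1 M reduction simultaneously.

## Bidirectional weighted P2 neck

Four backbone levels enter the neck: the outputs of the four C2f
stages, P2–P5, with strides 4/8/16/32 and channels 32/64/128/256 at
nano scale. Each passes a 1×1 lateral conv to a common width of 64.
One top-down sweep then one bottom-up sweep fuse them:

    td(i)  = Node( w1·in(i) + w2·up2(next-coarser) )
    out(i) = Node( w1'·in(i) + w2'·td(i) + w3'·down2(next-finer out) )

with six fusion nodes total (td at P4 and P3; outputs at P2, P3, P4,
P5 — the edge levels have no separate intermediate). Fusion weights are
one learned scalar per input, clamped at zero, normalised by their sum
plus β = 1e-4 (the fast-normalised-fusion convention; the coefficients
are nonnegative and sum to just under one). `up2` is nearest-neighbour
upsampling; `down2` is a stride-2 3×3 conv block. Each node's
post-fusion transform is a shallow C2f (n = 1, no shortcut) at neck
width — the idiomatic stage block for this detector family; a single
plain 3×3 conv per node was rejected because the assembled neck then
rounds to 2.1 M instead of the published 2.0 M. P2 takes part in
fusion only; the heads read the fused P3/P4/P5, so head strides stay
8/16/32 while small-object detail enters through the P2→P3 bottom-up
edge. Neck width 64 (nano) is the value pinned by the 2.0 M target.

## MPDIoU loss

For corner-form boxes inside a w×h canvas:

    MPDIoU = IoU − d1²/(w²+h²) − d2²/(w²+h²),   L = 1 − MPDIoU

where d1, d2 are the distances between the two top-left and the two
bottom-right corners respectively. The two corners determine a box
completely, so the penalty optimises location, size and aspect ratio
jointly and stays informative when the boxes share an aspect ratio at
different sizes — the failure mode of the centre-distance +
aspect-term losses. (w, h) are the *network-input* dimensions, since
the loss is evaluated in letterboxed input space during training.
Properties maintained and tested: symmetry in the two boxes, MPDIoU ≤
IoU with equality iff both corner pairs coincide, range [−2, 1] for
boxes inside the image (loss in [0, 3]), and invariance to joint
rescaling of boxes and image. The degenerate 0/0 IoU of two zero-area
boxes is defined as 0. The baseline CIoU loss is implemented with the
standard aspect term v = (4/π²)(arctan(w_g/h_g) − arctan(w_p/h_p))²
and α = v/((1−IoU)+v) held constant under differentiation.

## Variant table and parameter accounting

Eight variants toggle the three modifications independently
(`model0` … `model6`, `ms` = all three). The box-loss switch is
parameter-free, so the eight variants produce four distinct counts:

| configuration | exact | M |
|---|---|---|
| baseline | 3,011,222 | 3.0 |
| + multi-scale blocks | 2,707,118 | 2.7 |
| + weighted-fusion P2 neck | 2,045,988 | 2.0 |
| + both (full model) | 1,884,348 | 1.9 |

Counts include conv kernels, head biases and batchnorm affine pairs;
the fixed expectation projection of the box decoder has no learnable
weights. `scripts/acceptance.py` recomputes this table from fresh
assembly.

## Training

The loss is the stock composite of this detector family:
7.5·box + 0.5·cls + 1.5·dfl. A task-aligned assigner picks positives
per ground-truth box: candidate anchors must have their centre inside
the box, are ranked by score^0.5 · IoU^6, the top 10 are kept, and an
anchor claimed by several boxes goes to the highest-IoU one.
Classification is BCE against soft targets (the per-box normalised
alignment metric scaled by the best IoU); the box term is the
configured IoU-family loss on decoded boxes weighted by those targets;
the distribution-focal term pushes the two bins bracketing each true
side distance. The tensor-graph loss implementations are tested to
agree with the plain numpy reference implementations to float32
precision.

Two profiles exist. The **field profile** (image 1280, batch 32, 300
epochs, SGD momentum 0.937 with warmup + cosine decay) mirrors how the
full-scale model would be trained on real UAV data; it is emitted for
configuration completeness and not exercised by the test suite. The
**desk profile** (image 160, batch 8, ≤ 30 epochs, 200 synthetic
scenes, a width-0.125 "tiny" variant of ~0.6 M parameters) is what the
package actually runs end-to-end on one CPU. The desk profile uses
Adam (lr 2e-3, 2 warmup epochs, cosine decay): with only ~750
optimiser steps available, SGD at this scale was either unstable or
far from convergence in side-by-side runs, while Adam reliably reaches
mAP50 ≥ 0.8 on held-out scenes; SGD remains the field-profile default
and is available everywhere via `optimizer="sgd"`.

**Batchnorm recalibration.** After short runs the exponentially
decayed running statistics still sit far from the activation
distribution, and eval-mode outputs collapse towards the bias priors
even though train-mode behaviour is good. `train_model` therefore ends
with one calibration sweep that replaces the running statistics with
exact cumulative averages over the training batches. This is a
deterministic post-processing step, not extra training.

Determinism: a single seed fixes weight init, shuffling and the
synthetic data; two runs with the same seed produce bit-identical loss
histories on one thread.

## Synthetic field scenes

The generator emulates the *structure* of early-season field imagery,
not its appearance: noise-textured brown soil; seedlings as clustered
lobed green blobs with 3–5 lobes and radius 6–13 px at 160 px scale
(size jitter stands in for stunted growth and uneven branching); weeds
as thin crossed green blades 10–22 px long (deliberately confusable
with seedling leaves); optional pale translucent horizontal strips at
45% opacity emulating plastic-film glare that partially occludes
plants; and a 4:1 seedling:weed imbalance reflecting how scarce weed
instances are in such datasets. Placement respects a maximum-overlap
constraint; objects that cannot be placed are reported, not silently
dropped. Labels are tight boxes around the drawn pixels in YOLO
normalized format. The fly-over video renders a wide strip and slides
a square window across it at constant speed, which yields exact
per-frame ground-truth tracks and an exact count of objects whose
centres cross the frame-centre line — objects are placed so that every
one crosses during the sweep.

What passing on this data does and does not show: it validates the
geometry, losses, assignment, decoding, metrics and counting end to
end, and that the architecture can be optimised; it does not establish
detection quality on real UAV imagery (no perspective, blur, lighting
variation, plant overlap across rows, or real film texture).

## Evaluation and counting conventions

Matching is greedy per class in descending score order at IoU ≥ 0.5
(ties broken by ground-truth index), one detection per ground truth.
AP integrates the monotone precision envelope over recall
(all-points); a 101-point interpolation is available behind a flag for
ecosystem comparability. mAP averages classes unweighted; the
0.50:0.05:0.95 sweep gives mAP50-95. All zero-denominator ratios are 0
so sparse scenes evaluate cleanly. The confusion matrix is
(classes+background)²: geometry-matched pairs land in (true,
predicted), unmatched ground truths in the background column,
unmatched detections in the background row. FPS is
1000/(t_pre+t_inf+t_pos) on measured milliseconds — reported but never
asserted against, being hardware-dependent.

Counting uses the box centre. A track is tallied the first time its
centre's side of the reference line flips (zero offsets carry no side,
so a centre sitting exactly on the line defers the decision); each
track id counts at most once ever, which makes the tally immune to
oscillation across the line; a track first seen beyond the line is
never counted. The bundled tracker is a greedy nearest-centroid,
same-class, distance-gated matcher with a short dropout patience — a
deliberately simple component so the counting logic can be verified
without a heavy appearance/motion tracker; any source of per-frame
(id, class, box) records can replace it.

## Numerical choices

float32 storage throughout the tensor core; sigmoid/SiLU via the tanh
form to avoid exp overflow; softmax max-shifted; BCE in the
log1p(exp(−|z|)) form; convolution evaluated as k² shifted
channel-matmuls (fast on CPU, exact); batchnorm ε = 1e-3, momentum
0.03; fusion-weight clamp at 0; IoU denominators guarded at 1e-9.
Checkpoints are single `.npz` files carrying the variant config and a
config hash that the loader verifies.

## Known limitations

* Appearance realism of the synthetic scenes is out of scope by
  design; no augmentation is implemented.
* The field profile (1280/32/300) is configuration only — CPU training
  at that scale is impractical here.
* Video I/O is PNG frame folders; container formats (MP4/AVI) are not
  read or written.
* The tracker is not an identity-preserving tracker under occlusion or
  dense crossing traffic; it is adequate for sparse overhead sweeps.
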