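# Methods

`shrapod` couples four components: a synthetic ultrasound-phantom
generator, a single-stage anchor-based object detector, a detection
evaluation protocol, and a shrapnel-proximity triage metric. This note
records the models behind each, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Synthetic phantom generator

The generator emulates transverse (out-of-plane) B-mode views of a
gelatin thigh phantom: a subcutaneous fat layer over a muscle layer, a
bone deep in the frame, and a neurovascular bundle of an oval vein, a
circular artery and a nerve lateral to the artery, with an optional
metallic shrapnel rod embedded in the muscle.

**Geometry.** All feature sizes are physical and converted through one
pixel scale `px_per_mm`. Defaults: artery diameter 8 mm, vein minor
axis 6.5 mm (major axis 1.25–1.65× the minor, drawn per image), nerve
diameter 6.5 mm, shrapnel a 2.5 mm-wide rod of length 2–10 mm at a
uniform random angle, bone diameter 26 mm. The probe field of view is
not physically determined, so the pixel scale is pinned by one anchor:
at the default 9.4 px/mm the artery's ground-truth box averages ≈75 px,
the reference size the triage gate is expressed in. A `desk()` profile
(256 px frame, 4.7 px/mm) halves everything for CPU-scale runs; the
relative geometry is unchanged.

**Image formation.** No wave propagation is simulated. A mean
echogenicity map assigns each tissue a linear echo amplitude (fat 0.55,
muscle 0.38 plus a few smooth bright/dark inclusions, anechoic vessel
lumina 0.03 with bright arterial rim, hypoechoic nerve 0.33 with a
bright stipple texture, bone rim 0.95 with a dark acoustic shadow
below, shrapnel 1.5). The map is multiplied by Rayleigh-distributed
speckle normalised to unit mean, smeared with an anisotropic Gaussian
point-spread blur (σ = 0.7 px axial, 1.4 px lateral), log-compressed
(`log(1 + g·A)/log(1 + 1.5 g)`, gain g = 60) and quantised to 8 bits,
replicated across three identical channels to match the detector's
512×512×3 input contract.

**Ground truth.** Each feature's box is the tightest axis-aligned
rectangle around its rendered support mask, so the boxes are tight by
construction and the tests can assert it against the masks directly.
Shrapnel placement resamples its position until the rod clears a
dilated union of the vessel/nerve masks; if a bounded number of retries
(default 50) fails, or the bundle itself cannot fit the frame, the
generator raises `PlacementError` rather than emitting an overlapping
configuration.

**Shrapnel prevalence** defaults to 0.6 — in the imaging campaign the
generator emulates, roughly 60% of frames contained shrapnel.

**What the generator does not reproduce:** probe-dependent beam
artefacts, refraction and reverberation, depth-dependent attenuation
and focal zones, tissue deformation, video temporal correlation, and
the label noise of human annotators. Detection scores on this data
therefore say the pipeline is correct and has capacity, not that the
trained weights would transfer to clinical images.

## Augmentation

Training-time augmentation applies, independently per sample: X and Y
reflections (p = 0.5 each), uniform scaling in [0.8, 1.2], and rotation
uniform in ±360°, composed as one similarity transform about the frame
centre. Rasters are warped bilinearly. Boxes are transformed by mapping
their four corners and taking the enclosing axis-aligned rectangle —
the standard convention; for rotations this enclosing box necessarily
contains (and overestimates) the tight box of the rotated feature.
Transformed boxes are clipped to the frame and zero-area remnants
dropped; if any box would leave the frame entirely the whole parameter
draw is resampled (up to 25 times, then the identity is used) so that
per-class box counts are conserved. Box corners are mapped in
continuous coordinates (pixel *i* spans [i, i+1), pivot at S/2) while
rasters are warped in pixel-index coordinates (pivot (S−1)/2); the two
matrices are conjugates by the half-pixel shift, which keeps flips
exact on both rasters and boxes. Validation and test images are never
augmented.

## Detector

**Architecture.** A SqueezeNet-style backbone: a stem convolution
(3×3, stride 2, ReLU, 2×2 max pool), four shared Fire modules, then
five more Fire modules on the classification pathway. Each Fire module
is a 1×1 squeeze convolution (ReLU) feeding parallel 1×1 and 3×3 expand
convolutions (ReLU) whose outputs concatenate in depth. Max pools place
Fire 8 at stride 16 and Fire 9 at stride 32. Two YOLO-style heads: the
coarse head reads Fire 9 through a conv + batch-norm + ReLU block and a
1×1 output convolution; the fine head passes Fire 9 through a 1×1
feature-resizing conv block, upsamples ×2 (nearest), concatenates with
Fire 8, and applies a final conv block and 1×1 output convolution. Each
head emits `A_h × (5 + C)` channels per cell: sigmoid centre offsets,
log size ratios against the anchor, objectness, and per-class scores.
Channel widths follow SqueezeNet v1.1 scaled by a width multiplier;
strides 16/32 give 32×32 and 16×16 grids at the 512 px input. The
network is implemented directly in numpy (im2col convolution with BLAS
matmuls, explicit backward passes); gradients are verified against
finite differences in the test suite.

**Anchors.** k-means over training-box (w, h) with 1 − IoU of
centre-aligned rectangles as the distance, k-means++ seeding, mean
centroid update, and an objective guard that stops the iteration if the
mean 1 − IoU would increase — making the objective non-increasing by
construction. The reference configuration uses 23 anchors; sorted by
area, the larger 12 go to the stride-32 head and the remaining 11 to
the stride-16 head (the partition generalises to ⌈k/2⌉ coarse).

**Loss.** Each ground truth is assigned to its best-shape anchor
(plus any anchor whose centred shape IoU clears the assignment bar —
0.5 in the reference configuration, 0.3 in the desk profile, where the
denser supervision stabilises the short schedule). Assigned
predictors take squared-error penalties on sigmoid centre offsets and
raw log-size terms (weight 5), binary cross-entropy objectness toward
1, and per-class binary cross-entropy. All other predictors take a
no-object objectness penalty (weight 0.5) — *unless* their decoded box
overlaps some ground truth at IoU ≥ 0.5, the penalty threshold, in
which case they are excused. Loss is averaged over the batch; gradients
are clipped to a global norm of 10.

**Optimisation.** SGD with momentum 0.9 and L2 regularisation 5·10⁻⁴.
When a validation set is supplied, the trainer can retain the
parameters from the iteration with the lowest validation loss instead
of the final iterate (`keep_best_val`, on in the desk profile) — with
short schedules the last iterations are noisy and checkpoint selection
on validation loss removes that tail risk.
The learning rate follows a quartic warmup,
`base_lr × (iteration / warmup)⁴`, reaching the base rate 10⁻³ exactly
at the end of the 1000-iteration warmup. The source description of
what follows warmup is ambiguous between "constant" and "slowdown";
the default keeps the rate constant and a `post_warmup_decay` switch
enables the mirrored quartic decay `base_lr × (warmup / iteration)⁴`.
Reference configuration: 125 epochs, batch 16, validation loss every
79 iterations.

**Desk-scale profile.** The reference configuration is impractical for
a quick CPU run, so `ArchSpec.desk()` / `TrainConfig.desk()` define the
profile used by the test-suite and the worked examples: 256 px input,
width multiplier 0.25 (memorisation checks) to 0.75 (held-out runs),
6 anchors, batch 8, ≤20 epochs, warmup 100 iterations, base rate
4·10⁻³ (the shorter schedule needs a higher plateau to converge in few
iterations). At this frame size almost every box is 15–50 px, so the
anchor partition is shifted toward the fine head (2 coarse / 4 fine)
instead of the even split used with 23 anchors at full scale. Dataset
sizes in the end-to-end checks are ~200 generated images split
75/10/15, and evaluation predictions use a low confidence threshold
(0.05) so the precision-recall curve is explored to high recall. The
full-size configuration remains available and is what the defaults of
`PhantomConfig`, `ArchSpec` and `TrainConfig` describe.

**Inference.** Decoded boxes are scored `σ(objectness) × σ(class)`,
thresholded (default 0.5; evaluation runs use a lower threshold so the
precision-recall curve is explored), cleaned by per-class greedy NMS at
IoU 0.5, and clipped to the frame.

## Evaluation protocol

**IoU** is intersection area over union area on half-open boxes; it is
undefined (an error, not 0) when both boxes are degenerate.

**Matching** is per image and per class, greedy in descending
confidence (ties: larger box first): a prediction claims the unmatched
ground truth of highest IoU if that IoU ≥ 0.5 and becomes a TP. Every
unmatched prediction is an FP — this covers both spurious detections
and surplus duplicates on an already-claimed ground truth — and every
unclaimed ground truth an FN. Consequently TP + FP = #predictions and
TP + FN = #ground truths, which the property tests assert.

**mIoU** averages an image-level IoU sample over images where the
class is present in truth or prediction: the mean over ground truths
of their best prediction IoU (regardless of the 0.5 bar), 0 for a
missed ground truth or a prediction with no ground truth. Images where
the class is absent from both contribute nothing.

**AP** pools detections over images, ranks by confidence, computes
cumulative precision/recall, and integrates with the all-point
precision-envelope rule (a raw trapezoid option exists). The test
suite checks the implementation against an oracle that re-matches
every confidence prefix from scratch.

**Summary percentages** report TP, FP and FN as shares of all decision
events (TP + FP + FN) per class, so a class row sums to ~100%.
Ratios that are undefined on the data (0/0) are reported as missing,
not as 0, and are excluded from cross-class averages. The all-class
row is the unweighted column mean (mAP = mean AP, etc.).

## Triage metric

For each test image whose detections include all four classes, the
single highest-confidence detection per class is kept (ties: larger
box, then first seen). The box midpoint is `(x + w/2, y + h/2)`;
distances from the shrapnel midpoint to the vein, artery and nerve
midpoints are Euclidean, in pixels; the minimum of the three is the
image's triage distance and the arg-min its closest feature (exact
distance ties resolve artery → nerve → vein, most critical first).
Images missing any class are excluded from the triage population
entirely. The gate flags an image at multiplier m when its triage
distance is strictly below m × a reference diameter — the mean over
artery ground-truth boxes of (w + h)/2, ≈75 px at the default scale.
The flagged fraction is non-decreasing in m by construction, and
closest-feature frequencies sum to exactly 100% of kept records.
Distances stay float; rounding happens only in report formatting. An
optional px-per-mm factor converts reports to millimetres.

## Numerical and degenerate-input choices

- All randomness flows from explicit integer seeds; the pipeline
  derives per-stage substreams from one global seed via CRC-tagged
  `SeedSequence`s, so every stage is independently reproducible.
- Zero-area boxes: rejected at construction (negative sizes), removed
  after augmentation clipping, and IoU against a single zero-area box
  is 0 (only the double-degenerate case errors).
- Encode/decode of boxes against anchors is exact to float64 round-off;
  the round-trip test demands 10⁻⁶ px.
- Splits use largest-remainder rounding of (0.75, 0.10, 0.15) with a
  guarantee that no non-zero fraction receives an empty part (borrowing
  from the largest part), so 3 images split 1/1/1.
- Batch norm uses running statistics (momentum 0.1) at evaluation time;
  training loss curves are bit-reproducible for fixed seeds on one
  machine.

## Known limitations

- The phantom is statistically simple; detection scores on it are
  upper bounds of what the same pipeline would reach on real captures.
- The numpy network trains at desk scale only; the reference 512 px /
  125-epoch configuration is expressible but slow without an
  accelerated backend.
- Midpoint distances ignore box extent; a large vein whose wall is
  near the shrapnel can still report a large centre distance. Corner
  or segmentation distances would refine this.
- The triage gate multipliers carry no clinical calibration; they are
  expressed in units of the artery reference size precisely because
  absolute thresholds would require clinical input.
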