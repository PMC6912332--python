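# Methods

## Pipeline model

The package implements a two-stage cascade for benign/malign
classification of thyroid ultrasound frames. The design assumption is the
standard CAD observation that a cheap, well-calibrated first stage can
decide the easy cases and abstain on the hard ones: stage one is a scalar
frequency-domain statistic with two thresholds producing *benign* /
*benign-malign* / *malign*; only the middle state (an abstention) invokes
the convolutional network. A decision made at stage one is final and the
network is never evaluated for that image.

### ROI extraction

Frames are binarized at the integer Otsu level (exhaustive scan of the
256-bin histogram, classes `< t` and `>= t`, ties toward the smallest
level — fixing the integer convention is why the scan is implemented
in-package rather than delegated). Foreground is intensity at or above
the level, because ultrasound background sits near zero. The binary image
is closed with a disk of radius 5 px before labeling: speckle fragments
the Otsu foreground, and without closing "the largest object" is not
well defined. Components are labeled with 8-connectivity (diagonal
speckle bridges keep the tissue blob whole); the largest-area component
wins, ties broken by centroid distance to the frame center (the thyroid
occupies the central fan). Interior holes are filled by default. A
largest object below 5 % of the frame area raises a no-tissue error —
a guard against frames that are all annotation. Downstream stages consume
the zero-padded crop of the bounding box, not the full masked frame.

### Frequency-domain score

The crop is resampled to a fixed 256×256 square by bilinear interpolation
so that mask geometry (radius in bins, bar half-width in bins) is
comparable across variable-size crops. The image is mean-subtracted and
transformed with the **orthonormal** 2-D DFT, center-shifted, and squared
in magnitude; under this convention total spectral power equals
side² × image variance (Parseval), which the tests assert to 1e-6
relative. The score is the ratio of mask-selected power to total power
with the DC bin excluded from both sums. Mean subtraction plus DC
exclusion make the score invariant to overall echogenicity (brightness)
and to linear intensity scaling — both are asserted as properties.

Five mask shapes are supported: circle (radius r around DC), horizontal
and vertical bars (half-width w around the center row/column), their
union (plus), and circle ∪ plus. Geometry larger than the grid is
clipped, never an error. Mask selection, when not fixed by the caller,
ranks every candidate on the tuning grid (radii {8, 16, 24, 32, 48},
bar half-widths {1, 2, 4, 8} on the 256 grid — spanning the low-to-mid
frequencies where ultrasound texture energy concentrates) by the ROC area
of the benign-vs-malign score separation, orientation-free
(AUC < 0.5 is flipped), ties toward the smaller selected-bin count.

### Threshold calibration and orientation

Which side of the score axis is "malign" depends on the mask geometry:
a DC-centered circle concentrates benign energy, a thin off-axis bar the
opposite. The orientation is therefore **learned** at calibration from
the class medians rather than hard-coded; all thresholds operate on
oriented scores (negated when malign sits low). TH_LOW is the
α-quantile of oriented malign training scores and TH_HIGH the
(1−α)-quantile of oriented benign scores, with linear interpolation
between order statistics (deterministic and standard). At α = 0 this
guarantees zero first-stage training error: no training benign is ever
called malign and vice versa. When the classes separate
(TH_LOW > TH_HIGH), both collapse to their midpoint and the undecided
band is empty. Boundary scores fall into the band, i.e. are forwarded to
the CNN. An image whose crop has no off-DC power cannot be scored and is
likewise routed to the CNN rather than erroring.

### Network

The classifier is a convolutional backbone with the classification top
replaced by global average pooling over the (m, n, k) feature tensor,
batch normalization over the k pooled features, dropout (rate 0.5, a
field default — the rate is otherwise unconstrained), and a 2-unit dense
softmax output. The head adds k×4 batch-norm parameters (scale, shift,
and the two running statistics) and 2×(k+1) output parameters for any k.

Backbones: ResNet-18/34 (basic blocks) and ResNet-50 (bottleneck
blocks), built with biased convolutions; at 224×224 input the last
feature maps are (7, 7, 512) and (7, 7, 2048) respectively. Counting
every tensor including running statistics, the ResNet-50 backbone has
exactly 23,587,712 parameters; our convention gives 11,190,912 for
ResNet-18 and 21,310,208 for ResNet-34. A four-block `tiny_test`
backbone (32 final channels, 12,330 total parameters with head) runs the
full training path on one CPU in seconds and is the default for tests
and examples.

All layers (convolution via im2col, batch norm, pooling, dropout, dense,
residual blocks) are implemented directly on NumPy with manual backward
passes, verified against central finite differences; the optimizer is
Adam. Pretrained-weight transfer is a load-if-provided hook
(`build_classifier(..., weights_file=...)`); random initialization is the
default so the package builds offline. The dense output layer is
zero-initialized — standard for transfer-style heads — so initial
predictions are exactly uniform (p = 0.5) and the small learning rate
orients the decision boundary immediately.

Training minimizes 2-class cross-entropy for 10 epochs with the learning
rate decaying each epoch by the constant factor (end/initial)^(1/9),
hitting 1e-4 at epoch 1 and 1e-5 at epoch 10 — the simplest rule that
matches both endpoints of a continuous per-epoch reduction. Inputs are
resampled to 224×224, replicated to three channels and scaled to [0, 1].
Runs are bit-reproducible given the seed; all randomness (init, batch
order, dropout) flows from named generators. Probability exactly 0.5 is
called malign (documented tie rule). All backbone layers are trainable;
nothing is frozen.

## Evaluation harness

Malign is the positive class. Accuracy, specificity TN/(TN+FP) and
sensitivity TP/(TP+FN) are computed per fold and averaged; a metric whose
denominator is empty is reported as NaN, not raised. Splits are by
patient. The default scheme draws a fixed-size test set (11 benign + 50
malign from a 52/246 cohort, i.e. 61 test / 237 train patients)
independently per fold: a strict disjoint 5-fold partition of 52 benign
patients cannot give 11 test benign in every fold, so repeated random
selection is the default and a disjoint stratified partition is provided
as an alternative mode. Decisions are per image; an optional per-patient
aggregation (malign if any image malign) is available since the natural
reporting unit is genuinely ambiguous — both are supported rather than
picking one silently. Train/test patient disjointness is asserted inside
the cross-validation loop. File outputs round metrics to 3 decimals.

## Phantom generator

The generator emulates exactly the frame features the pipeline keys on:
a background near intensity 8 with mild Gaussian noise; three ~6×10
annotation glyphs at intensity 250 placed at least 20 px clear of the
tissue so closing cannot merge them; a rectangular tissue region
(default 240×320 inside a 360×560 frame, matching common clinical frame
sizes) filled with multiplicative gamma speckle (shape 4, mean 1, scaled
to mean intensity 120) — the standard fully-developed-speckle surrogate;
a hypoechoic nodule disc (radius 42, contrast factor 0.55) in both
classes; and, in malign phantoms only, calcifications: bright discs
(radius 2, intensity 245) on a jittered axis-aligned lattice (pitch 9 px)
inside the nodule. The lattice alignment places the calcification
harmonics on the spectral axes, which is what makes the bar-family masks
discriminative on phantoms. A phantom's label is defined by its
calcification count, so the two classes are generated identically up to
those discs — removing them from a malign spec reproduces the benign
image bit for bit.

What the phantoms do **not** model: attenuation and depth-dependent gain,
the fan-shaped sector geometry, anatomical context (trachea, carotid),
nodule margin irregularity, and real speckle correlation from a
point-spread function. Passing phantom tests therefore demonstrates the
pipeline's mechanics — ROI recovery, score separation under the stated
spectral effect, calibration, hand-off, bookkeeping — not clinical
performance; headline accuracies on phantoms (typically ≈100 %, since
the effect size was chosen to separate the classes) say nothing about
accuracy on patient data.

## Problem sizes and numerical choices

Tests and the acceptance script use a 20+20-patient phantom cohort,
2-fold cross-validation with 5+5 test patients, and the `tiny_test`
backbone — sizes chosen so the whole suite runs in a couple of minutes on
one CPU while still exercising every stage end-to-end. Spectral-score
oracle agreement is checked on 8×8 inputs against a direct O(N⁴)
double-sum DFT at 1e-8 relative tolerance; the Otsu level against an
exhaustive 256-level scan; ROC areas against an all-pairs concordance
count. Degenerate inputs are first-class: constant images raise at
thresholding, flat crops route to the CNN, empty confusion classes yield
NaN markers.

## Known limitations

- The NumPy network trains small backbones comfortably but is not sized
  for training ResNet-50 at scale; the large backbones are primarily for
  architecture accounting, forward passes and weight loading.
- The learning-rate schedule (1e-4 → 1e-5 over 10 epochs) presumes a
  transfer-learning setting; training a large backbone from random
  initialization under this schedule will underfit by design.
- Reported ResNet-18/34 parameter totals follow this package's stated
  accounting; other frameworks' conventions (unbiased convolutions,
  excluded running statistics) give different totals.
- TI-RADS is ingested from CSV manifests only; no DICOM or native XML
  annotation ingestion.
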