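# Methods

`echograde` implements a two-stage computer-aided grading pipeline for
2-D breast ultrasound (B-mode) images: a fully convolutional
identification network proposes the lesion region, a refinement joint
cleans and tightens that region, and a convolutional grading network
assigns one of five BI-RADS-style categories ("3", "4A", "4B", "4C",
"5").  Because clinical breast ultrasound with expert annotation is not
redistributable, the package ships a speckle-phantom generator that
emulates the image properties the pipeline depends on, so every stage
is trainable and testable end to end from a single seed.

## The pipeline

Inputs are grayscale images rescaled to a uniform 288 x 288 frame
(every component accepts a configurable size; the desk-scale studies
use 96 x 96).

**Stage 1 — identification (ROI-CNN).**  A VGG-style encoder applies
four 2x downsamplings, so a 288-px input yields an 18 x 18 deep feature
map.  Two branches read that map: a plain 3 x 3 convolution, and a
3 x 3 atrous convolution with dilation 2 (effective receptive field
5 x 5, i.e. k + (k-1)(d-1)) followed by a 1 x 1 "transitional"
convolution with 512 filters that balances the channel count before the
two branches are concatenated and fused.  The decoder follows the
FCN-16s pattern: the fused one-channel score is upsampled 2x (nearest
neighbour + learnable 3 x 3 convolution), summed with a 1 x 1 skip from
the penultimate pooling stage, restored to the input resolution by an
exact bilinear operator, and squashed by a per-pixel sigmoid into a
tumor-possibility map.

The training loss is the soft Dice loss

    L = 1 - (2 * sum(p * g) + eps) / (sum p + sum g + eps),   eps = 1e-6,

averaged over the batch.  The numerator is the soft *intersection*
sum(p * g); a literal product of the two region areas is not a Dice
overlap and is not minimized by correct predictions, so the standard
intersection reading is used.  With eps in both numerator and
denominator, two empty masks score loss 0 (vacuous agreement).  At the
metric level the same convention holds: DSC(empty, empty) = 1,
DSC(empty, non-empty) = 0.

**Refinement joint.**  The possibility map is binarized at 0.5
(threshold >= by convention).  8-connected components with area below
40% of the largest are discarded, and among the survivors the component
whose centroid is nearest the frame centre (H/2, W/2) is kept; ties in
area or distance resolve to the lowest label index.  The surviving
region seeds a two-phase Chan–Vese active contour minimizing

    E(C) = mu1 * sum_inside |I - c1|^2 + mu2 * sum_outside |I - c2|^2
           + alpha * length(C),

with c1, c2 the inside/outside intensity means recomputed every
iteration.  The curvature term of the continuous model is realized as
the standard contour-length regularizer (a bare curvature scalar is not
a well-defined global energy term); discretely, length(C) counts the
4-neighbour pixel edges crossing the contour.  Defaults mu1 = mu2 =
alpha = 1 with a 50-iteration cap in the pipeline; the level-set-only
ablation raises the cap to 1000.

**Stage 2 — grading (G-CNN).**  Nine blocks with 18 convolution layers
in total, all 3 x 3, each followed by ReLU; all max pools are 2 x 2
with stride 2.  Blocks 1–4 (encode path) hold two convolutions and a
pool each, channel count doubling per block (F, 2F, 4F, 8F; F = 32 by
default — the reference architecture states the doubling but not the
absolute widths).  Block 5 holds three convolutions at the deepest
resolution.  Blocks 6–9 (concatenate path) each concatenate the running
features with a skip from the paired encode block (4-6, 3-7, 2-8, 1-9)
and apply one convolution.  Batch normalization sits on the last
convolution of every block and on the first two fully connected layers
(4096, 1024, 5); a softmax head outputs the category probabilities, and
the predicted grade is the argmax (ties to the lowest index).  Training
uses categorical cross entropy -mean log p(true class) — the softmax
head and the cited multi-class loss imply the categorical form — plus
L2 weight decay (1e-4 by default).

*Side branches.*  The concatenate path runs at the deepest resolution
while encode blocks 1–3 produce larger maps, so those skips pass
through a side branch of one 3 x 3 convolution followed by max pooling
down to the matching size.  The reference description gives each side
branch exactly one convolution and "a max pooling layer", but a single
2 x 2/stride-2 pool can only halve a map once while blocks 1–3 sit at
8x/4x/2x the deepest resolution; this package therefore repeats the
(parameter-free) 2 x 2 pool as often as needed.  The convolution-layer
count remains exactly 18.

**ROI hand-off.**  The refined mask's bounding box, expanded by 10% of
its extent on each side and clipped to the frame, is cropped and
resized to the grading input size.  Context pixels outside the mask are
retained: boundary sharpness and the surrounding texture carry grading
information, and masking them out would delete it.

## Training recipes

Reference defaults: minibatch 16, SGD with momentum 0.9; learning rate
1e-4 for the identification network and 1e-3 for the grading network,
the latter decayed by a factor 0.9 per epoch (the decay trigger is
configurable; per-epoch is the default).  Identification augmentation
(random brightness +-0.1, contrast x0.8–1.2, translation up to 20 px
clamped so the lesion stays fully in frame, horizontal flip p = 0.5,
then standardization to zero mean / unit variance) is redrawn every
epoch, so N epochs see N variants of each image.  Grading augmentation
expands the dataset exactly fourfold offline — translations only, the
last two copies additionally flipped — keeping photometry untouched.
At test time only standardization is applied.

The identification network is trained from Gaussian (He-scaled) random
initialization.  The original recipe warm-starts the encoder from
ImageNet-pretrained VGG weights; the package exposes that as an
`init_mode` hook but does not ship weights, and adds optional batch
normalization to the identification encoder (default on) because a
randomly initialized encoder at desk scale needs it for stable SGD.

## The phantom generator

Each phantom is one hypoechoic lesion in fully developed speckle:

* **Background** — Rayleigh-distributed envelope noise (sigma = 0.25),
  blurred by a small Gaussian (sigma = 0.8 px) standing in for the
  scanner point-spread function.  The Rayleigh mean/std ratio
  sqrt(pi/2)/sqrt(2 - pi/2) ~ 1.91 is checked by test on the
  unsmoothed field.
* **Lesion** — a radial polygon r(theta) = ellipse(theta) * (1 +
  roughness + spicules), rasterized and subtracted from the background
  as an intensity offset (0.15–0.35), clipped to [0, 1].  Roughness is
  a band-limited sinusoid mix (harmonics 2–5) scaled to a grade-specific
  amplitude; spicules are narrow Gaussian bumps in angle.
* **Grade encoding** — per-grade parameter ranges increase
  monotonically: irregularity amplitude from [0, 0.05] (grade 3) to
  [0.35, 0.5] (grade 5), spicule count from 0 to 6–10.  Grade is thus
  recoverable from boundary morphology alone
  (perimeter^2 / 4 pi area increases in expectation with grade), which
  is what makes the grading task learnable.  This is a geometric
  stand-in, not a clinical claim.

What the phantoms do **not** model: posterior acoustic shadowing and
enhancement, heterogeneous internal echotexture, Cooper's-ligament and
rib structures, depth-dependent attenuation and focusing, operator
variability, or any real relationship between morphology and
malignancy.  Passing phantom benchmarks therefore demonstrates that the
implementation is correct and that the pipeline's design claims hold
under its own assumptions — not clinical performance.

## Numerical choices

* Chan–Vese evolution: phi initialized as the signed distance of the
  seed mask (positive inside), explicit updates with the whole-domain
  force extension (dropping the front-localized delta lets a finite
  iteration cap move the contour several pixels — a standard variant),
  time step dt = 0.45, reinitialization to a signed distance every 10
  iterations, convergence when the changed-pixel fraction over a
  5-iteration window falls below 1e-4 (disabled for the 1000-iteration
  level-set-only variant, whose contour starts far from the lesion).
  The region terms carry a fixed gain of 8: mu and alpha are
  unit-dependent, and with intensities in [0, 1] the squared residuals
  are ~two orders of magnitude weaker relative to the length penalty
  than on 8-bit images; the gain restores a region-dominated balance
  at the stated mu1 = mu2 = alpha = 1 (it multiplies the descent
  force only, not the reported energy).  A vanished contour returns
  the initialization with a warning.
* Boundary metrics: contours are mask pixels 8-adjacent to background;
  Hausdorff is the max of the two directed distances, AvgDist the mean
  of the two directed mean nearest-neighbour distances (the reference
  metric names no direction; the symmetric choice is used).  One-vs-rest
  AUC uses the Mann–Whitney rank statistic with ties counted 1/2;
  classes without both positives and negatives report NaN rather than a
  silent 0.
* Cross entropy clips probabilities at 1e-12; batch norm uses eps =
  1e-5 and running-stat momentum 0.9; minibatches of size 1 are skipped
  in grading training (batch statistics are undefined).
* Cross-validation is stratified (the clinical class counts are
  imbalanced 323–565, so unstratified folds could starve a class), with
  per-fold results reported as mean ± sd across folds.

## Desk-scale study conditions

The bundled studies (`echograde.experiments`) run at 96 x 96 with
base_filters = 8 and FC sizes (64, 32, 5): identification recovery on
200 phantoms (160/40 split, 10 epochs, lr 0.05), identification-variant
ordering on 250 fresh phantoms, the 5-category grading study on 100
phantoms per grade (two-stage vs one-stage under an identical 6-epoch,
lr 0.03 budget and seed), and the extreme grade-3-vs-5 task on 100 per
class (4 epochs).  The learning rates are larger than the reference
defaults because the scaled networks are orders of magnitude smaller
and train from random initialization.

## Known limitations

* The CNN engine is plain NumPy: correct (finite-difference checked)
  but not fast; full-resolution 288-px training is possible yet slow,
  and the shipped studies run at 96 px.
* Exact reference channel widths, the VGG variant, the decoder's
  upsampling parameters and the concatenation wiring beyond the stated
  3-7 pairing are not recoverable from the source description; all are
  exposed as configuration with documented defaults.
* With alpha = 1 at 96 px the contour-length penalty is relatively
  stronger than at 288 px, so refinement slightly rounds the most
  spiculated (grade 5) boundaries; the refined-vs-unrefined margin is
  widest for smooth lesions.
* Hole filling after refinement is deliberately not performed; metrics
  are computed on the masks as produced.
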