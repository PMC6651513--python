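# Methods

This note records the models, the numerical choices, and the limits of
what the synthetic experiments show. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline grades one *subject* from a pair of scans: a grayscale OCT
B-scan (assumed to be the foveal B-scan; volumes are out of scope) and a
fundus/FA photograph. Intensities are normalized to [0, 1] at load so
every threshold in `PipelineConfig` is scale-free. Rasters are row-major
with row 0 at the top; OCT depth grows with the row index. Color fundus
images are reduced to the green channel for all tensor math (the green
channel carries the strongest vessel/exudate contrast), keeping the
original for overlays. Only two classes exist: `healthy` and `me`.

## Preprocessing

**Annotation rows.** Scanner annotations are burned into the top and
bottom of B-scans; the first and last 50 rows are set to zero
(OCT-only by default). The rule is applied at native resolution, before
any resizing.

**Degraded-margin repair.** For each column, the first and last
vertical transitions whose absolute row-gradient exceeds
`gradient_thresh` bracket the informative region; everything outside is
replaced by the mean of background pixels (background = below the Otsu
threshold of the scan). The default threshold is 0.65 in normalized
intensity per pixel step: saturation artifacts jump by ≈0.9 against a
dark background while genuine anatomy (including fluid-wall edges under
speckle) stays at or below ≈0.5, and a 0.5 threshold was observed to
blank legitimate retina above strong fluid edges. Columns with no
qualifying transition pass through untouched.

**Adaptive Wiener filter.** Per pixel, with local mean `m` and variance
`s²` over a `wv × wh` window (default 5×5, symmetric padding):

    D = m + max(s² − a², 0) / s² · (O − m),   D = m where s² = 0.

`a²` defaults to the mean of all local variances, the classical noise
estimate for this filter family; it can be fixed in the config. The
filter is validated against a literal per-pixel double-loop oracle to
1e−9.

## Structure tensor and channel selection

Gradients are Gaussian-derivative responses at scale `sigma_d`
(default 1 px); the tensor components are Gaussian-window-weighted
(scale `sigma_w`, default 3 px) products:

    Txx = g * φx², Tyy = g * φy², Txy = g * (φx·φy).

The off-diagonal uses the product of first derivatives — the
second-moment form — because a genuine cross-derivative would break
positive semidefiniteness. Eigenvalues come from the 2×2 closed form;
coherence is `((λ₁−λ₂)/(λ₁+λ₂))²` with 0 where the trace vanishes.
Channel choice is fixed per modality rather than auto-selected
per image: `Tyy` for OCT layers (horizontal structure), elementwise
`max(Txx, Tyy)` ("TMAX") for fundus vessels, rescaled to [0, 1]. The
implementation matches a literal double-loop evaluation of the weighted
sums to 1e−6 on random 32×32 images, and 90° rotation exactly swaps the
diagonal channels.

## OCT analysis

**Edges and candidates.** Canny runs on the square root of the `Tyy`
response (gamma compression: the vitreous and choroid boundaries carry
an order of magnitude more contrast than inner-layer boundaries, and a
single pair of hysteresis thresholds must see both). Canny marks the
flanks of the response ridge, so each edge pixel is snapped to the
response crest of its column (±5 rows) before tracing.

**Boundary tracing.** Each curve grows from the topmost unclaimed
candidate, left and right, taking the strongest-response candidate
within `jump_limit` (3 px) of the previous row; gaps keep the search
anchor but stay undefined. A trace is accepted if it covers ≥50 % of
columns and its mean column-to-column jitter is ≤0.4 px (noise traces
jitter at ≥0.7 px); accepted traces are gap-interpolated and
median-smoothed over 15 columns. Failed traces burn only their seeds so
they cannot fragment later boundaries; ghost duplicates (median
distance <6 px from an accepted curve) are dropped. All acceptable
curves are collected and the `k ≤ 9` best-covered are kept, ordered top
to bottom. Fewer than two curves is an extraction error.

**Designations.** ILM = topmost curve. RPE = whichever of the bottom
two curves has the brighter tissue in the five rows beneath it (the RPE
complex is the brightest band; this picks its top). Curves below the
designated RPE (the bottom of the complex) are retained but sit outside
the ILM–RPE bracket by construction.

**Fovea.** The ILM is gap-interpolated, box-smoothed (15 columns), and
the fovea is the center of the deepest plateau (within 1 px of the
maximum) containing the argmax — the pit is locally flat, so a raw
argmax would be quantization-limited; ties break toward the image
center.

**Fluid.** The denoised scan is masked to strictly between ILM and RPE;
pixels below `fluid_thresh` (0.5) times the in-band mean survive a 3×3
opening and an area filter (≥30 px). The fluid mask is a subset of the
band by construction.

**EDTRS grade.** With lateral calibration (µm/px), edema is
`clinically_significant` if any fluid/exudate pixel lies within 500 µm
lateral (column) distance of the fovea, `non_significant` otherwise,
`none` when no lesions exist. The 500 µm is measured from the fovea
center and is configurable; axial distance is not part of the clinical
definition. The pipeline grades on the OCT frame (fluid vs. the OCT
fovea); fundus exudates live in a different pixel frame and contribute
to the grade only through their own column distance when passed
explicitly.

## Fundus analysis

**Vessels.** The TMAX response is renormalized over the (eroded)
circular field of view — otherwise the aperture rim sets the scale —
then hysteresis-thresholded (0.05/0.20). The response ridge is several
pixels wider than the vessel, so the mask is confined to pixels darker
than a 31-px boxcar background estimate; near bright structure
(>1.25× the field-of-view mean, dilated by 3 px) only decisively dark
pixels (≥0.10 below background) survive, which removes bright-blob
outline responses while letting vessels cross the disc. Components with
skeleton length <20 px are dropped.

**Optic disc.** Argmax of the disc-footprint regional mean (FFT
convolution, radius 40 px); absence (peak below `disc_floor`) is a
value, not an error.

**Exudates.** Candidates are pixels brighter than 1.3× the
field-of-view mean whose white-top-hat response (disk radius 8 px)
exceeds 0.15 — brightness finds candidates, the top-hat floor rejects
large smooth structure like the disc. Components inside the disc zone
(detected radius × 1.5) are removed; components lying >20 % on the
vessel mask are vessel artifacts and removed, while incidental contact
is tolerated (an over-strict contact rule was observed to erase true
exudates ringed by spurious vessel responses). The final mask is forced
disjoint from vessels and the disc zone.

## Neural networks

No deep-learning framework is used; `retfuse.nn` is a compact float32
NumPy stack (same-padded stride-1 convolution via im2col, batch
normalization, ReLU, sigmoid, 2×2 max pooling, inverted dropout, dense
layers, softmax cross-entropy, SGD with momentum) driven by one seeded
generator, so training is bit-reproducible on a machine.

**Feature CNN.** 14 layers: zero-centered input, conv 8×(9×9), BN,
ReLU, 2×2 pool, conv 16×(9×9), BN, ReLU, 50 % dropout, 2×2 pool, conv
32×(9×9), BN, ReLU, fully connected → 8. A detachable 2-class softmax
head is attached for training on healthy/ME labels and dropped at
inference; the 8 activations are the modality's features. One shared
CNN serves both modalities (it fits both comfortably); OCT features
(f1–f8) and fundus features (f9–f16) concatenate in that order. The
input size is parametric: the canonical geometry is 227×227×3, while
cohort training here runs at 64×64 — the same layer pattern at a
resolution where a 200-scan cohort trains in minutes on one CPU.

**Batch-norm inference statistics.** Exponential running averages
collected during training reflect dropout-perturbed small-batch
activations and were observed to collapse evaluation accuracy while
train-mode accuracy was perfect; after training (and before each
validation point) the BN statistics are re-estimated by clean
full-training-set passes with dropout off, aggregating batch moments by
the law of total variance.

**Optimization.** SGD, momentum 0.9, batch 16, cross-entropy
`CL = −Σ I·log P ≥ 0`, validation every 100 iterations. The default
learning rate is 0.001: on the structured overlay images 0.01
oscillates around chance without descending. The modality-recognition
network reuses the same architecture trained on oct/fundus labels; an
AlexNet-geometry transfer-learning backend is intentionally not bundled
(pretrained weights are an external artifact), which is the one place
this implementation substitutes a from-scratch model for a pretrained
one.

**Overlays.** Findings are burned into a 3-channel copy with fixed,
arbitrary colors — fluid red, exudates yellow, vessels blue-cyan,
boundaries blue — chosen so each finding perturbs a channel combination
the grayscale base and the other findings do not.

## Hybrid classifier

Features are z-scored with training-split statistics before every
classifier. The ANN is 16–12–9–2 (sigmoid hidden activations, softmax
output — a 2-unit softmax rather than a single output node, which would
make the softmax degenerate), trained full-batch by gradient descent.
The SVM is sklearn's SVC with an RBF kernel (C=1, γ=1/16) by default or
an MLP/sigmoid kernel (tanh(scale·⟨x,y⟩+offset)). The Gaussian naive
Bayes is implemented directly (class-frequency priors, per-feature
Gaussian likelihoods, variances floored at 1e−9, log-space MAP) so its
posterior matches a direct Bayes-rule oracle to 1e−12; it is
cross-checked against sklearn's GaussianNB in the tests. The final
label needs ≥2 of the 3 votes (no ties are possible), with no
classifier weighting. Metrics use ME as the positive class; a metric
with a zero denominator is reported as absent; `dice(∅, ∅) = 1` so
healthy phantoms with empty truths score perfectly when the prediction
is also empty. Stratified k-fold CV reports per-fold accuracies and
their maximum.

## Synthetic phantoms: what they emulate and what they do not

The OCT phantom stacks `n ≤ 9` boundary curves (ILM … bottom of the RPE
complex) with alternating band reflectivities (0.20–0.44, RPE complex
0.58, background 0.08), a parabolic foveal dip fading with depth,
per-boundary jitter, multiplicative uniform speckle (level 0.2 by
default), and bright annotation bars inside the first/last 50 rows. ME
adds 1–4 elliptical strongly hypo-reflective (0.05) fluid blobs
strictly inside the band, kept mutually separated, plus central retinal
thickening. The fundus phantom has a circular field of view with radial
shading, a smooth-edged bright disc, a darker macula opposite it, a
recursive branching dark vessel tree rooted at the disc (width tapering
4→1 px), and, for ME, 3–8 bright exudate blobs within 1.5
disc-diameters of the macula, kept off the vessels. Default shapes are
496×512 (OCT) and 720×576 (fundus), exercising the 50-row rule at a
realistic aspect ratio; the OCT lateral calibration defaults to
11.6 µm/px so the 500 µm EDTRS radius is ≈43 columns. Cohorts pair one
OCT and one fundus phantom per subject, with stratified
train/validation splits; a seed fixes every pixel.

What the phantoms do *not* contain: real speckle statistics and shadow
artifacts, curved/tilted retinas, vessel shadowing on OCT, drusen,
hemorrhages and micro-aneurysms, illumination fields and color
variation of real fundus cameras, or inter-grader ambiguity. Passing
the recovery thresholds (fluid dice ≥0.80, vessels ≥0.70, exudates
≥0.60, boundary MAE ≤2 px, fovea within ±2 columns) therefore
demonstrates that the algorithms are implemented coherently and recover
known structure under speckle and geometric variation — not that they
would reach the same figures on clinician-annotated clinical data,
whose published dice values are measured against external datasets this
package does not ship.

## Problem sizes and determinism

The test suite and the acceptance script use a 50-subject cohort for
segmentation recovery and a 100-subject (200-scan) cohort for CNN +
ensemble training at 64×64 input, 30 epochs — sizes chosen so the whole
loop runs in minutes on a single CPU while leaving every stage
non-trivially exercised. Every generator, trainer and fold assignment
is seeded; re-running with the same seeds reproduces outputs exactly on
one machine (bit-level for the phantoms and the NumPy networks).

## Known limitations

- Per-B-scan processing only; no volume handling, no foveal-B-scan
  selection, no 3-D tensors.
- The EDTRS grade uses lateral distance in the OCT frame only.
- The layer tracer assumes near-horizontal boundaries (jitter filter at
  0.4 px/column) and will reject heavily tilted scans rather than
  flatten them.
- Fluid subtypes (cystoid vs. subretinal) are not distinguished;
  hemorrhage/micro-aneurysm detection is out of scope.
- The boundary set may include a curve below the designated RPE (the
  bottom of the RPE complex); consumers should use the ILM/RPE indices
  rather than assume the last curve is the RPE.
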