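# Methods

`octafusion` implements a multilevel-information-fusion pipeline for
classifying diabetic retinopathy (DR) from en-face OCTA angiograms. The
pipeline has four stages: (1) a U-Net segments each angiogram into
background, large vessels and the foveal avascular zone (FAZ); (2) the
segmentation is encoded as a grayscale label image and stacked with the raw
angiogram into a two-channel *merged* image; (3) an
isolated-concatenated-block (ICB) residual network classifies the merged
image as normal or DR; (4) Grad-CAM renders the spatial evidence behind each
decision. A synthetic angiogram generator provides data with the statistical
structure the pipeline assumes, so every stage is testable without any
external dataset.

## Neural-network substrate

No deep-learning framework is used; the models run on a small reverse-mode
automatic-differentiation engine (`octafusion.nn`) written on numpy.
Convolution is im2col + BLAS matmul; max pooling, batch normalisation,
bilinear upsampling, concatenation and the two fused cross-entropy losses
each carry hand-written backward passes that are finite-difference-checked
in the test suite. Gradients are retained on every tensor in the graph, not
only parameters, which is what Grad-CAM needs to read
`d(score)/d(feature map)` at an internal layer. All operations preserve
dtype (training runs in float32; gradient checks in float64). Optimisation
is Adam (β₁ = 0.9, β₂ = 0.999); every weight initialisation and data shuffle
is driven by an explicit `numpy.random.Generator`, so training traces are a
pure function of their seeds.

## Synthetic angiogram generator

The generator emulates the en-face (inner-retina maximum-projection) view:
bright branching vessel trees on a mid-gray capillary speckle background,
with a dark avascular disc at the fovea. Vessels are grown by a biased
random walk with bifurcation — not a physiological model; the pipeline only
needs curvilinear bright structures with a controllable density field.
Roots enter from the image border heading inward, meander with directional
persistence (heading noise sd 0.16 rad per 0.9 px step), taper from
`vessel_width_root` (2.6 px) toward `vessel_width_min` (1 px), bifurcate
with probability 0.08 per step, and steer tangentially around the FAZ.

The FAZ is a deformed disc: the radius is modulated by angular harmonics of
order 2–4 (amplitude sd 0.06, clipped to [0.6, 1.4]) so that segmentation
cannot be solved by radius regression alone. The class contrast mirrors the
two established DR biomarkers:

* **FAZ enlargement** — nominal radius is drawn from N(12, 1.8²) px for
  normal eyes and N(19, 2.8²) px for DR (ratio ≈ 1.6, consistent with the
  roughly doubled FAZ area reported in DR cohorts);
* **perifoveal capillary dropout** — inside the annulus [r, 2r] a DR walk
  suppresses whole multi-step segments so that the expected drawn density is
  multiplied by `perifoveal_density_factor_dr` = 0.55, producing the dashed,
  rarefied perifoveal plexus of nonperfusion.

Rendering composes a background level of 0.35, band-passed Gaussian speckle
whose amplitude is tied to `capillary_noise_sd` (default 0.05; the same knob
scales the additive white noise, so `capillary_noise_sd = 0` yields an
exactly constant background), vessels at 0.92, the FAZ near 0.08, a 0.5 px
Gaussian blur, and clipping to [0, 1]. Masks label every pixel exactly once
(background 0, vessel 1, FAZ 2). One global seed fans out to per-sample
streams keyed by the sample counter, so any sample is reproducible
independently of generation order. The default cohort imbalance is 244
normal / 57 DR. An optional field-of-view scale factor scales the FAZ radii;
no claim is made of matching any particular dataset's 3 mm / 6 mm mixture.

What the generator does **not** emulate: projection and motion artifacts,
signal-strength gradients, capillary-level plexus structure, media
opacities, or DR grades beyond the binary label. Passing the end-to-end
tests therefore shows that the pipeline's machinery learns and localises the
engineered FAZ/perifoveal contrast — not that it reaches any particular
performance on clinical OCTA.

## Segmentation

The U-Net has depth 4 and 32 base filters by default (doubling per level,
3×3 convolutions with batch norm and ReLU, 2×2 max-pool downsampling,
bilinear ×2 upsampling followed by a 1×1 channel reduction, skip
concatenation, and a 1×1 softmax head over the three classes). The input
side must be divisible by 2^depth; a 128×128 input has an 8×8 bottleneck.

The loss applies binary cross-entropy per class channel against the one-hot
truth, sums over the three channels, and averages over pixels, with
probabilities clamped to [1e-7, 1 − 1e-7] before the logarithm. With a
softmax head this equals categorical cross-entropy plus the (1 − y) terms of
the other channels; it is implemented this way so the scalar loss matches
the channelwise-BCE reading exactly, and the hand-computed oracle values in
the tests pin that choice down. Decoding is per-pixel argmax with ties to
the lowest class index.

Reported metrics are per-class one-vs-rest pixel accuracy — chosen because
per-class recall cannot produce the near-equal per-class values this metric
family is usually reported with — and per-class intersection-over-union,
with unweighted means (mean accuracy, mIOU). The IOU of a class absent from
both prediction and truth is defined as 1. These definitions are pinned
against a brute-force confusion-matrix oracle.

## Fusion

Masks are encoded black/gray/white: background → 0.0, FAZ → 0.5,
vessel → 1.0 (the numeric codes are a package convention, frozen in tests;
nearest-code decoding recovers the mask exactly). The merged image stacks
(angiogram, label image) in that fixed channel order with no rescaling, so
both inputs are recoverable bit-exactly. At classification time the label
channel may come from ground-truth masks or from the trained segmenter's
predictions; both are supported (deployment only has the latter), and the
end-to-end tests use ground-truth channels so segmentation error does not
confound the classifier measurement.

## ICB classifier

Two input-processing branches feed a four-stage residual backbone:

* **isolated process** — each input channel passes through its own
  (unshared) 7×7 stride-2 convolution at half stem width; the per-channel
  maps are concatenated and integrated by a 3×3 convolution to full stem
  width, then 3×3 stride-2 max-pooled. For single-channel inputs this
  degenerates gracefully to one sub-branch.
* **concatenated process** — the full multi-channel input passes through a
  single 7×7 stride-2 convolution at stem width plus the same pooling; with
  this branch alone the model is exactly the plain ResNet50-style backbone.

Both outputs have equal spatial size and channel count and are concatenated
along channels when both branches are enabled. The backbone is four stages
of 1×1→3×3→1×1 bottleneck blocks with stage counts (3, 4, 6, 3) — each
stage opens with a projection-shortcut convolutional block (stride 2 from
stage 2 on) followed by identity blocks — ending in global average pooling
and a fully connected softmax head over {normal, DR}. `width_multiplier`
scales every channel count (default 1.0; desk-scale studies use 0.25). The
training loss is categorical cross-entropy; class weights are available for
imbalanced cohorts but off by default.

Because positive samples are scarce in screening cohorts, the decision
threshold on the DR probability is a first-class knob (default 0.5, which
equals argmax); lowering it trades specificity for the sensitivity clinical
triage needs. Prediction optionally averages the four horizontal/vertical
flip views (`tta=True`); the end-to-end protocol uses this because it
substantially stabilises borderline cases at desk scale.

## Grad-CAM

Channel weights are the spatial means of `d(score)/d(feature map)`; the map
is `ReLU(Σ_l w_l M^l)`, bilinearly upsampled to the input size. The class
score is by default the pre-softmax logit (standard practice — the gradient
of a saturated probability vanishes); a `sigmoid` mode routes the logit
through a sigmoid for strict fidelity to the activation-named formulation.
Both modes are tested. The default layer is the output of the last residual
stage; any captured layer can be selected. Overlays min-max normalise the
map (all-zero maps stay zero), apply the red-hot colormap, and blend in
proportion to both the alpha and the local heat, so unheated pixels keep
their exact gray value.

One property of the synthetic contrast matters when reading heatmaps: DR
evidence there is the *absence* of central structure (an enlarged dark FAZ,
dropped-out capillaries), and an activation-weighted map cannot highlight
structure that is absent. The model's decision is still driven by the
perifoveal region, but it surfaces on the **normal**-class map — normal
evidence is the *presence* of perifoveal vessels. The Monte-Carlo
localisation test therefore checks that the normal-class heatmap of
held-out normal samples concentrates inside twice the FAZ radius.

## Evaluation protocol

Stratified 6-fold cross-validation by default (57 positives over 6 folds
leaves 9–10 per fold; unstratified splitting risks near-empty positive
cells). Fold-level accuracy, sensitivity and specificity are aggregated as
Student-t means, reported as `X% (95%CI ± Y%)`; the CI construction is a
package decision — the convention this reporting style comes from does not
define one. Sensitivity over a fold with no positives is reported as NaN
with a warning. Out-of-fold DR probabilities are pooled into a single ROC
(swept over all distinct thresholds, trapezoidal AUC, equal to the
Mann-Whitney statistic with ties credited 1/2); per-fold AUCs are also
logged, and both pooled and fold-mean accuracies are emitted since either
convention is common. The harness accepts any classifier exposing
`fit(X, y)` / `predict_proba(X)`, which is how the ablation grid and the
baseline (majority, score-threshold) models run through the same code path.

## Desk-scale study sizes

The shipped studies are sized for a single CPU: Monte-Carlo generator checks
use 200 samples per class; the segmenter study trains on 60 low-noise
samples (depth 4, 16 base filters, 6 epochs, batch 4, lr 1e-3) and evaluates
pooled metrics on 20 held-out samples; the classifier study trains the
(both, merged) variant at width multiplier 0.25 on 120 low-noise samples
with ground-truth label channels (batch 16, flip augmentation, 14 epochs at
lr 3e-4 then 6 at 8e-5) and evaluates flip-averaged predictions on 60
held-out samples. The low-noise cohorts use `capillary_noise_sd = 0.03`.
These sizes are the package's chosen desk-scale study conditions; the same
code runs full-scale by raising the widths, epochs and sample counts.

## Known limitations

* The autodiff engine is single-threaded numpy; it is suitable for the
  desk-scale studies above, not for full-width 400×400 training.
* The generator's vessel trees are phenomenological; their branching
  statistics are not calibrated to retinal vasculature.
* Grad-CAM localisation of absence-type evidence is structurally limited
  (see above); occlusion- or counterfactual-based maps would be needed for
  that, and are out of scope.
* AUC confidence intervals (DeLong) and calibration analysis are not
  implemented.
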