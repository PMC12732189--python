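# Methods

`vfssvit` implements a fully automated pipeline for classifying
videofluoroscopic swallowing studies (VFSS) as normal or abnormal with
respect to airway invasion: cleaning of raw fluoroscopy exports, a
3D-patch vision transformer trained on study-level labels only, a
subject-level evaluation protocol, and attention-rollout saliency maps.
Because clinical VFSS corpora are private, the package ships a synthetic
phantom generator that reproduces the structural nuisances of fluoroscopy
exports and plants a controllable, exactly-known invasion signal; every
quantitative claim the test suite makes is made on that phantom.

## The classification model

A clip is a single-channel video `V` of shape `(T, H, W)` with intensities
in `[0, 1]`. It is cut into non-overlapping spatio-temporal patches
("tubelets") of `Tp` frames by `P x P` pixels, giving

    N = (T / Tp) x (H / P) x (W / P)

tokens after the temporal axis is zero-padded *at the end* to the next
multiple of `Tp` (no observed frame is discarded). Each flattened patch
`x_i in R^{Tp P^2}` is projected by a learned matrix `E` to a
`D`-dimensional embedding. A learnable class token is prepended and a
learned positional embedding `E_pos in R^{(N+1) x D}` is added; position
semantics follow the fixed token order (temporal segment major, then patch
row, then patch column; within a patch: frame, row, column).

The encoder is `L` identical pre-norm layers:

    Z <- Z + MHSA(LN(Z));   Z <- Z + FFN(LN(Z))

with `h`-head scaled dot-product attention (`D_h = D / h`, scale
`1/sqrt(D_h)`), and `FFN(Z) = ReLU(Z W1 + b1) W2 + b2` with hidden width
`4D`. After a final layer norm, the class-token embedding passes through a
two-layer ReLU MLP head (widths 128 and 64 at full scale) to a single
logit; a sigmoid yields `y_hat`, the probability of airway invasion. A
single-linear head (`y_hat = sigmoid(z_cls . w + b)`) is available as
`head_type="linear"`; the MLP head is the default because it is the
configuration the full training recipe describes. Training minimizes binary
cross-entropy, computed in the numerically stable logit form.

The forward pass, the exact reverse-mode gradients of every block
(layer norm, attention, feed-forward, head) and the Adam optimizer are
implemented directly on NumPy arrays. The gradient code is verified against
central finite differences over random parameter directions in the test
suite.

Default hyperparameters (full scale): `Tp=25` frames, `P=16` px, `D=64`,
`h=8`, `L=8`, head widths `(128, 64)`, inputs isotropically resized to
256 x 256, Adam at learning rate 1e-3 for up to 200 epochs with early
stopping. The desk-scale configuration used by the shipped experiment is
`Tp=10, P=8, D=32, h=4, L=2`, head `(32, 16)`, 64 x 64 inputs.

**Initialization.** Projection matrices use a Glorot-scale truncated normal
(std `sqrt(2/(fan_in+fan_out))`, clipped at two standard deviations);
positional embeddings use std 0.02; the class token and all biases start at
zero. A fixed tiny std (0.02) for the projections — common at very large
widths — starves the class token of patch signal at `D = 32..64`: the
desk-scale model then never escapes the chance plateau (validation loss
rises from epoch 1). Glorot scaling trains reliably; this was the single
most consequential numerical choice in the package.

**Positional capacity.** The positional table is sized for the longest
training clip; a longer clip at inference raises an explicit capacity error
naming `N` rather than silently truncating or aliasing positions.

**Parameter accounting.** `count_parameters` gives the closed-form count of
trainable scalars (embedding + class token + positional table + per-layer
terms + head) and is tested to match the instantiated model exactly. For
the stated full-scale configuration it is on the order of a few hundred
thousand scalars plus the positional table — far below nine figures; the
model is small by design, the cost being dominated by the `N^2` attention.

## Preprocessing

The cleaning chain, in order, each stage deterministic and
shape-contracted:

1. **Info-band crop.** Fluoroscopy exports carry a static patient-info
   overlay. On the temporal-mean frame, the mean absolute horizontal
   Prewitt response per row is scanned in the top and bottom 20% of rows;
   the maximal-response row (if above a floor of 0.05 intensity units) is
   the crop boundary. Static overlays give a sharp edge; a constant frame
   is left uncropped. A crop that would leave fewer than `min_rows` rows is
   an error.
2. **Targeting-artifact removal.** Early frames often contain a circular
   alignment/contrast marker. A circle Hough transform over Canny edges of
   the early frames (default: first 10, radius range 5-15% of the frame)
   detects it; the detected disk, dilated by 4 px, is inpainted
   (biharmonic) in every frame whose ring-band intensity stays above the
   clip-wide baseline. The dilation covers the full ring width because the
   Hough estimate sits on the ring's inner Canny edge. Absence of a circle
   is not an error: the clip passes through unchanged.
3. **Resolution unification.** Frames are symmetrically zero-padded (below
   target) or center-cropped (above target) per axis to the corpus-median
   resolution, which is fitted once on the training manifest and persisted;
   inference reuses the stored value.
4. **Field-of-view masking.** Everything outside the inscribed circle of
   the detector window is set to exactly zero, and stays an exact zero set
   through the rest of the chain.
5. **Denoise + contrast.** Per frame: bilateral filter (window 5 px, sigma
   0.1 of the intensity range, 3 px spatial), then CLAHE
   (`clip_limit=0.01` in scikit-image's [0, 1] convention, 8 x 8 tile
   grid), re-masking, and clipping to `[0, 1]`. CLAHE is skipped for
   near-constant frames, whose equalization is undefined. The CLAHE and
   bilateral parameters are conventional defaults and configurable; the
   chain commits to the operators, not to specific values.

## Training and evaluation protocol

Splitting is at the **subject** level: a greedy assignment reserves ~10% of
clips (by whole subjects) for a held-out test set and splits the remainder
0.8 : 0.2 into training and validation; `k`-fold cross-validation
partitions the non-test subjects into folds of near-equal clip counts
(largest-first greedy balancing). The leakage invariant — no subject spans
partitions or folds — is asserted programmatically on every emitted plan.

Training augmentation (training clips only): a rotation within ±5 degrees
and a zoom of up to +10%, each applied to every frame of a clip
identically, plus additive Gaussian noise (sigma 0.01); each transform
fires independently with probability 0.5 per clip per epoch. Batches are
single clips with gradient accumulation (default 8), avoiding cross-clip
padding semantics under learned positional embeddings. The returned
checkpoint is the parameter state at the epoch of minimum validation loss,
never the final state; training stops after `patience` (default 10)
non-improving epochs.

Metrics: accuracy, sensitivity, specificity, precision and F1 from the
confusion matrix at a 0.5 decision threshold (configurable; the ROC sweep
makes the threshold non-binding for AUC), ROC by full threshold sweep, AUC
by the trapezoidal rule. The test suite cross-checks the trapezoidal AUC
against the normalized Mann-Whitney pairwise count at 1e-10. A
single-class evaluation set reports AUC as absent with a warning, not as
zero. Per-fold metric vectors can be compared with a two-sided paired
t-test; zero-variance differences are flagged as degenerate (p -> 0 for a
consistent nonzero difference, p = 1 for identical vectors).

## Attention-rollout saliency

For one clip, the `(N+1) x (N+1)` attention matrices of every head at every
layer are captured during a forward pass. Per layer the heads are averaged,
mixed with the identity to account for the residual path
(`A_bar = rownorm(0.5 mean_h A + 0.5 I)`), and the per-layer matrices are
recursively multiplied; the class-token row of the product, restricted to
patch tokens and renormalized, is the relevance vector `r`. Each temporal
segment's `(H/P) x (W/P)` slice of `r` is bilinearly upsampled to frame
resolution (half-pixel-aligned, edge-clamped — a small explicit routine so
that a patch one-hot peaks at its pixel-block center and the interpolation
has an exact closed form) and min-max normalized to `[0, 1]`; every frame
of a segment shares its map `m_t`.

The model emits one study-level probability, so per-frame weights are
derived at segment granularity: each `Tp`-frame segment is scored
independently, the segment logits for the clip-level predicted class pass
through a softmax, each segment's share is spread uniformly over its
frames, and the weights `w_t` sum to 1. The cumulative map is
`M = sum_t w_t m_t`; the mask is `M >= 90th percentile`, the percentile
taken over field-of-view pixels only (including the zeroed corners would
deflate the threshold). The overlay backdrop is the first "quiescent"
frame, i.e. the first frame whose mean dense optical-flow magnitude (ILK
flow, averaged over the field of view) to the next frame is below 0.5 px;
if none qualifies, the minimum-flow frame is used and flagged.

A gradient-weighted variant (`variant="gradient"`) combines heads as
`mean_h relu(dlogit/dA * A)` before the residual mixing, so heads whose
attention does not influence the logit drop out; the default remains the
deterministic head-averaged rollout.

## The synthetic phantom

Each subject receives a jittered anatomy (shared by all of that subject's
clips): a three-segment pharyngeal polyline from the upper-center to the
lower-center of the field of view, and an airway disk (radius 9% of the
frame) offset anteriorly from the path midpoint. A clip renders a
truncated-Gaussian bolus (peak 0.8, support cut at 2.5 sigma) advancing
along the path over the clip; abnormal clips additionally deposit 60% of
the bolus peak inside the airway disk from an onset frame drawn uniformly
from the middle third of the clip, so the signature always lies inside an
interior temporal patch. Structural nuisances: a bright info band over the
top 12% of rows, a circular targeting ring in the first 3-10 frames
(excluded from the airway disk by construction), additive Gaussian noise
(sigma 0.05) and a circular field of view with dark corners. Defaults:
40 subjects x 5 clips, 64 x 64 frames, 30-60 frames per clip, half
abnormal (clinical corpora of this kind are close to balanced).

The construction guarantees that in normal clips the airway region carries
exactly zero signal before noise, so a geometry-aware oracle — mean
intensity inside the subject's airway disk — upper-bounds any learned
classifier. With default noise the oracle's AUC is ~1.0, certifying the
planted signal is learnable.

**What the phantom does not emulate.** Anatomy, bolus physics, radiographic
noise (quantum mottle), scanner-specific artifacts, label noise, and —
importantly — the *statistical structure* of real abnormality. The planted
signal is a static intensity deposit: it is linearly separable from mean
pixel content. Passing tests therefore demonstrate that the pipeline,
model, optimizer and protocol are correct and that the architecture can
learn a localized spatio-temporal signature from study-level labels; they
do not demonstrate clinical performance.

## Known limitations

- **Rollout saliency needs an unconfounded cue.** On the shipped phantom
  the cumulative maps localize the planted region strongly (inside/outside
  ratios of roughly 2-19 on held-out abnormal clips across seeds). During
  development we observed that a phantom variant in which the targeting
  ring could overlap the airway region still trained to held-out AUC 1.0 —
  but with near-uniform *head-averaged* attention, and no rollout variant
  (head-mean, gradient-weighted, gradient-x-input, per-segment) recovered
  the planted region, even though individual heads localized sharply
  (single-head class-attention ratios of 10-80). Perfect classification
  therefore does not guarantee localized rollout maps: when the
  discriminative cue is confounded or linearly readable through uniform
  value mixing, the head average can bury the localized heads. Treat
  rollout maps as evidence, not ground truth.
- Training at desk scale crosses a 12-17-epoch chance plateau before
  collapsing to near-zero loss; budgets shorter than ~25 epochs with small
  patience can stop inside the plateau and return a chance-level model.
  The shipped experiment uses 60 epochs with patience 25.
- AVI/MP4 input requires an ffmpeg-capable imageio plugin at runtime;
  lossless formats (TIFF/NPZ) are first-class and used for all fixtures.
- DICOM multiframe input requires the optional `pydicom` dependency and
  degrades to an informative error without it.

## Problem sizes in the shipped experiments

The end-to-end experiment (`vfssvit.experiments.run_desk_scale_study`, also
driven by `scripts/acceptance.py` and the heavyweight acceptance tests)
uses the 200-clip/40-subject phantom at 64 x 64 with the reduced model, a
size chosen so a full generate-preprocess-train-evaluate-explain cycle
completes in minutes on one CPU while leaving the protocol identical to
the full-scale configuration.
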