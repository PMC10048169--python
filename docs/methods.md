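# Methods

## Problem and model

One micro-expression instance is an onset frame (motion start), an apex frame
(motion peak), and 68 iBUG-300W landmarks for the onset frame (0-based
indices; landmark detection itself is outside the package — landmarks arrive
in a CSV sidecar or from the synthetic generator). The method has three
stages.

**Geometry (HARS).** The face is rotated in-plane about the image centre by
−θ, θ = atan2(y45−y36, x45−x36)·180/π, so the outer eye corners are level;
the same rigid transform is applied to the landmarks, so no re-detection is
needed. The face crop runs from cheek landmarks 1/15 (left/right) to jaw
landmark 8 (bottom); the top boundary sits a distance d above brow landmark
19, where d is the mean brow-to-eye gap ((y38−y20)+(y43−y23))/2. With y
increasing downward, "margin above the brows" forces the minus sign
(top = y19 − d). Eyebrow ROIs expand the brow's bounding extent by a quarter
of its length horizontally and a quarter of its height upward, and stop a
quarter-height above the upper eyelid (landmarks 37/44) to exclude the eye.
The mouth ROI expands the lip corners (48/54) by m_l/4 and the lip verticals
(51/57) by m_h/2, with m_h the nose-base-to-upper-lip distance. The right
brow uses landmark 44 for its lower boundary, the analogue of 37 on the
left. All boxes are half-open, float-valued, clamped to the image, and
rounded to integer pixels only when slicing. The puzzle tiles the two
eyebrow crops side by side over the mouth crop (50/50 split of the top half;
the source only fixes the order, not the proportions), bilinearly resampled.

**Motion.** Dense TV-L1 optical flow (scikit-image's duality-based solver;
attachment 15, tightness 0.3, 5 warps × 10 iterations, median prefilter) is
estimated between the aligned, cropped onset and apex — and separately
between the two assembled puzzles, so the puzzle branch sees flow of the
puzzle rather than a puzzle of flows. Optical strain is the Frobenius
magnitude of the symmetric flow-gradient tensor,
√(ε_xx² + ε_yy² + 2ε_xy²), computed with central differences (one-sided at
borders); the source literature defines the tensor but not the scalar
reduction, and this choice is zero for rigid translation and rotation. The
(u, v, ε) stack is resized to 28×28 and each channel is scaled by its own
maximum absolute value into [−1, 1]; max-abs (rather than min-max) scaling
preserves the sign of the flow, i.e. the direction of facial motion. The
puzzle is assembled at 56×56 by default and its flow computed there before
resizing, so ROI motion is measured near its native amplitude; 28×28
assembly is a configuration away.

**Network and objective.** Each branch is two Inception blocks (four paths —
1×1, 1×1→3×3, 1×1→5×5, 3×3/1 max-pool→1×1 — each path `filters` channels,
ReLU after every convolution, 2×2 stride-2 max-pool after the concat).
Filters 6 then 12 give the chain 3×28×28 → 24×14×14 → 48×7×7; 2×2/2 pooling
is the only kernel geometry that reproduces that chain exactly. The
full-face branch output passes through CBAM: a channel gate
σ(MLP(maxpool) + MLP(avgpool)) with a shared two-layer MLP (reduction 16,
hidden floor 4), then a spatial gate σ(conv7×7[channel-max; channel-mean]) —
the cited attention module's defaults, which the source adopts without
restating. The puzzled branch has no attention by default (its input is
already region-selected); a config flag adds it only to reproduce the
corresponding ablation. The two 48×7×7 maps are channel-concatenated
(96×7×7), flattened (4704), and classified through a 512-unit hidden layer
with dropout 0.5 and a softmax over three classes. No batch normalisation
anywhere; fan-in uniform initialisation from a seed.

The objective is L = L_cls + λ·L_con with λ = 0.01. L_con = 1 − sim(Ve, Vp),
where both maps are min-max scaled to [−1, 1], flattened and compared by
cosine; only positive pairs (the two views of the same sample) enter — no
negative-pair term exists in the formula and none is invented. The strict
`cosine_similarity` op raises on a constant map (scaling undefined); the
batched training path guards the scaling denominator with 1e-8 so a
transiently all-zero ReLU map cannot abort a run. L_cls is the focal loss
−α_y(1−p_y)^γ log p_y with γ = 2 and uniform α; γ = 0 with uniform α is
exactly cross-entropy. A weighted-CE preset exposes the published composite
class weights (0.2857/0.1329/0.1695) verbatim — they are not derivable from
the class counts, so they are data, not a formula.

**Protocol.** Raw emotion labels are remapped to the composite three-class
scheme (CASME II: Disgust+Repression→Negative, Happiness→Positive,
Surprise→Surprise, others dropped; SAMM: Anger/Contempt/Disgust/Fear/
Sadness→Negative, Happiness→Positive, Surprise→Surprise, Others dropped;
SMIC labels pass through). The published CASME II raw counts remap to 90
Negative while the published composite table prints 88; the mapping is
implemented as stated and the mismatch surfaces as a warning at full-corpus
scale instead of being silently reconciled. LOSO holds out one namespaced
subject per fold; per-fold models re-initialise from `seed + fold_index`.
Metrics come from the pooled confusion matrix (rows true, columns
predicted); classes with no true samples are excluded from the UAR/UF1
macro averages; argmax prediction breaks ties toward the lowest class
index. Training follows the published recipe: Adam(β₁ = 0.5, β₂ = 0.999),
initial LR 1e-3 with cosine annealing, 60 epochs, mini-batch 128, random
horizontal flips. Flipping operates on the flow features — spatial mirror
of all channels plus sign negation of u, the only reading consistent with
flow physics; for the puzzled feature a full-width mirror simultaneously
swaps the eyebrow tiles, matching the puzzle of a mirrored face.

## Numerical engine

The network, reverse-mode autodiff, and Adam/cosine training loop are
implemented in NumPy (`dual_atme.nn`). Convolutions run channels-last as k²
batched matmuls on shifted views; max-pooling loops window offsets with
strided slices; backward rules live next to forward rules and are verified
against central finite differences in the test suite (atol 1e-7 in float64).
Training uses float32 parameters. `backward()` frees the tape eagerly —
backward closures hold large intermediates in reference cycles that
count-based garbage collection reclaims too late. One training epoch on ~270
samples takes about 1.2 s on one CPU; a full 60-epoch, 10-fold LOSO run
about 11–12 minutes.

## Synthetic data

The generator emulates exactly what the pipeline consumes: per-subject face
templates (shaded ellipse, brows/eyes/nose/mouth, smooth per-subject random
texture over the whole frame) with landmarks placed by the same parametric
layout, and apex frames produced by warping the template with
Gaussian-weighted displacement fields (radius 15 % of face width) anchored
on action-unit-like loci — lip corners up/outward for Positive (AU12-like),
inner brows down/inward for Negative (AU4-like), brows up plus lower lip
down for Surprise (AU1/2+25-like). Defaults: 10 subjects × 30 samples,
3 px peak displacement, additive Gaussian pixel noise (sd 1 on the 0–255
scale) independent in onset and apex, 128×128 frames, class proportions
250:109:83 assigned by a quota sequence so every prefix matches the
proportions within one sample. The texture covers the background too:
brightness-constancy flow is unconstrained on uniform regions, and a real
static scene behind a face is textured.

What the generator does not emulate: identity-realistic appearance, 3-D pose,
illumination change, landmark detection error, label noise, and overlapping
AU combinations. Passing the end-to-end test therefore shows the pipeline is
wired correctly and can recover localized, class-specific motion — not that
it reaches any particular accuracy on real corpora.

## Test-scale choices

The end-to-end acceptance check trains full LOSO (10 folds, 60 epochs,
batch 128) on the default synthetic conditions with one training seed and
requires pooled UAR ≥ 0.70 and ≥ 2× chance; the measured result is UAR 1.0,
so seed-to-seed variation has no bearing on the outcome at these conditions.
Oracle checks run at 100 random flow fields (strain, deviation < 1e-6),
1000 random confusion matrices (metrics, 1e-12), and 100 randomized
manifests (LOSO invariants). The mirrored-regeneration check for flip
augmentation asserts v-channel correlation > 0.85 and mean absolute
deviation < 0.12 on the [−1, 1] features: the u channel is near zero for
all three warp classes, so max-abs scaling amplifies solver noise there,
and the residual gap combines bilinear resampling, the inherent 1 px
crop-box offset under landmark mirroring, and the TV-L1 solver's own small
mirror asymmetry (measured v-correlations 0.90–0.98).

## Limitations

- Only in-plane rotation is normalised; non-frontal pose is out of scope.
- Flow uses exactly the onset/apex pair; no multi-frame temporal modelling.
- The NumPy engine is single-threaded and tuned for this network's tiny
  feature maps; it is not a general deep-learning runtime.
- Results on the licensed corpora are not reproducible here; the remapping
  tables and metrics are tested against published counts and counting
  oracles instead.
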