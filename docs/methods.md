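# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `radulna`, the way one would document a simulation or
analysis package: what is computed, under which assumptions, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

The package implements a single-view 2D–3D reconstruction pipeline for the
distal forearm: given one posteroanterior radiograph-like image, estimate
the 3D voxel labels of the radius and ulna within a normalized ±40 mm field
of view about the distal radial articular surface. The pipeline has two
learned parts — a paired image-translation network that maps a degraded
radiograph to a clean segmented-bone DRR, and a TL-embedding network that
maps a clean DRR to a 3D label volume — surrounded by deterministic
machinery: DRR rendering, anatomical normalization, rigid/affine
augmentation, intensity-based 2D–3D registration, and surface-distance
evaluation. No clinical data ships with the package; every stage is
exercised on procedurally generated wrist phantoms.

## Wrist phantoms (`radulna.phantoms`)

A phantom is two analytic solids in an elliptical soft-tissue cylinder:

* **Radius-like bone** — a tapered capped cylinder along +Z (distal up)
  with a hemispherical styloid bump on the lateral edge of the distal cap.
  The hemisphere sits entirely distal to the cap plane, so the solid volume
  has the closed form `πL(r₁² + r₁r₂ + r₂²)/3 + (2/3)πa³`, used as a
  voxelization oracle.
* **Ulna-like bone** — a cylinder with a spherical head, its distal end
  recessed 4 mm below the radial articular plane, placed at a configurable
  azimuth about the radial axis (default 15°). The non-zero default matters:
  a phantom that is mirror-symmetric about the coronal plane makes the signs
  of the two out-of-plane rotations jointly unidentifiable from a single
  orthographic view, which would make pose-recovery benchmarks ill-posed
  through no fault of the estimator. A slightly dorsal ulna is also the
  anatomically realistic arrangement.

Intensities are piecewise-constant Hounsfield levels (air −1000, soft
tissue 40, trabecular 300, cortical 1200 HU by default) with a cortical
shell of configurable thickness (default 2 mm). Population variability is
uniform per parameter over literature-plausible adult ranges (radius length
70–84 mm, proximal radius 7–9.5 mm, etc.); `sample_phantom_spec` is a pure
function of its seed. Rasterization evaluates the implicit solids at grid
points, optionally under a rigid pose — posed volumes are therefore exact,
not resampled, which keeps pose-recovery and normalization benchmarks free
of interpolation confounds. Landmarks (styloid tip, sigmoid-notch surface
point, two shaft-axis points, articular-surface point) are computed
analytically from the spec.

### Degradation model

`degrade_to_xray` turns a full-volume DRR into an "actual X-ray"-like
image: global soft-tissue weight, gamma mapping of normalized intensity,
seeded smooth clutter blobs, radial vignette, additive Gaussian noise.
The clutter term stands in for projections of structures a two-bone
phantom lacks — carpal bones, tendon sheaths, skin folds. It is the
component that makes translation genuinely necessary: monotone intensity
distortions (gamma, weight) are undone by within-mask histogram matching,
and i.i.d. noise barely moves a reconstruction network, but structured
clutter can only be removed by a model that knows what bones look like.
The blobs are deliberately broad (σ between 0.15 and 0.35 of the image
side): strong intensity corruption with weak gradient energy, the way
smooth overlapping tissue behaves, so intensity-based registration remains
possible the way it is on real radiographs. Severity (clutter amplitude
0.4 of the image peak, noise σ 0.015, γ 1.4, vignette 0.3) was calibrated
once, by pilot, so that the trained translator's residual error on
held-out phantoms lands near MAE ≈ 0.025 on the [0, 0.2] optical-depth
scale — about one tenth of the display range, the regime in which
translation is good but not perfect — and then frozen. In the pipeline the degraded radiograph is rendered at a
random acquisition pose (±4° / ±4 mm, zero depth component): a real
radiograph is taken with the wrist in its own pose, and this pose is
precisely what makes the radiograph-derived input conditions harder than
the canonical clean DRR. The model remains a surrogate: it is not
calibrated to any scanner or acquisition physics.

## DRR rendering (`radulna.drr`)

Hounsfield units convert to linear attenuation via
`μ = global_scale · max(0, μ_water (1 + HU/1000))`, clipped at zero (air
attenuates nothing). `μ_water = 0.02 mm⁻¹`; `global_scale = 0.227` is a
display calibration chosen once so the reference phantom's bone-only DRR
peaks near 0.20 optical depth, matching the convention that segmented-bone
DRRs occupy roughly [0, 0.2]. Rendering is fixed-step ray marching with
trilinear sampling (step ≤ the smallest voxel pitch, refused otherwise);
samples outside the volume contribute zero. Orthographic projection along
−Y is the default — under orthography the slab and sphere line integrals
have closed forms, which the test suite asserts to 1–2%. A pinhole
perspective mode exists for realism but is not the tested default. Rigid
poses are applied by inverse-transforming sample points, so posing costs
nothing extra and introduces no second resampling.

## Anatomical normalization (`radulna.frames`)

The anatomical frame follows the standard distal-radius construction: Z is
the shaft axis (proximal→distal), the origin is the articular-surface
landmark projected onto the shaft line, X is the projection of the
styloid→sigmoid-notch reference line onto the plane through the origin
perpendicular to Z, and Y = Z × X. Because X is rebuilt from the same two
landmarks in every subject, resampling into this frame unifies rotation
about the bone axis without altering the radius–ulna relationship.
Volumes are resampled onto a canonical grid spanning exactly ±40 mm along
Z (trilinear for HU, nearest-neighbour for labels; regions outside the
source volume are padded with air/background). Round-trip fidelity is
resolution-limited: at 1 mm grids, a posed phantom normalizes back to its
canonical labels with radius Dice > 0.95; the residual is nearest-neighbour
boundary jitter, not frame error (frames themselves are equivariant to
machine precision).

## Augmentation and splitting (`radulna.augment`)

The 3D regime poses the normalized volume rigidly — rotations and
translations uniform in ±30° / ±30 mm per axis, the full-scale ranges —
*before* DRR rendering, pairing each posed DRR with the unposed label
(40× per volume at full scale; 8× in the desk preset). The Euler
convention is intrinsic Z–Y–X. The 2D regime applies one sampled affine
(translation ±10 mm, rotation ±10°, scale 0.9–1.1, shear ±5°; ranges are
package defaults) to both members of an
(X-ray, registration-DRR) pair, 100× at full scale. Dataset splits are
patient-level throughout: every augmented item derived from one source
volume lands on the same side of each train/validation/test divide. The
85/15 train/validation split of augmented data is therefore realized at
patient granularity — a deliberately stricter reading that rules out
augmentation leakage.

## 2D–3D registration (`radulna.registration`)

Similarity is gradient correlation: the mean over the two image axes of
the Pearson correlation between central-difference gradient images. It is
invariant to affine intensity rescaling of either input, which is what
makes registering a clean bone DRR against a degraded target safe, and it
raises on constant images rather than returning a silent zero.

The moving image is selectable: the bone-only DRR when the target is
itself a segmented DRR, or the full-volume DRR when the target is a
radiograph-like image. The distinction matters — a bone-only rendering
shares only bone-edge gradients with a radiograph whose soft-tissue
boundary, vignette and clutter dominate the gradient field, and
registration against such targets fails; rendering from the full volume
turns the soft-tissue edges into alignment signal, after which the
bone-only "registration-DRR" is emitted at the found pose.

The search reformulates the same objective as nonlinear least squares on
mean-removed, unit-norm gradient images (per axis, ‖r‖² = 2(1 − GC)).
This matters: for near-cylindrical bones seen in a single orthographic
view, out-of-plane rotations trace a faint, strongly curved valley in GC
(poses several degrees apart can differ by < 10⁻⁶ in similarity), and a
direct scalar search — Powell included — reliably stalls on that ridge. A
least-squares solver sees the full residual vector and follows the valley;
a coarse-level Powell search is retained as the capture stage when the
least-squares path starts outside its basin, and the returned pose is never
worse than the initialization (ascent contract). Translation along the
viewing direction is excluded from the default search space because an
orthographic projection is exactly invariant to it; with perspective
geometry all six degrees of freedom are searched. Within its documented
capture range (~10 mm / 10°) the registrar recovers exact synthetic poses
to well under 1 mm / 1°.

## Image translation (`radulna.translate`)

The translator follows the paired conditional-adversarial recipe: a
generator maps degraded image → clean bone DRR and is trained with
`100 · L1 + 1 · adversarial` (the conventional 100:1 weighting of the
paired-translation literature); the
discriminator scores (input, candidate) patch pairs (8×8 patches at desk
scale). Both networks are fully connected, built on the package's own
numpy autodiff core (`radulna.nn`) — a deliberate desk-scale realization;
no deep-learning framework is a dependency of this package. The generator
is residual (output = input + correction), which makes the identity map
the zero-parameter starting point and "better than identity" a meaningful
learning criterion. Images are normalized by one dataset-level scale
recorded in the trained state, never per image, so absolute intensity —
which carries depth information in single-view reconstruction — survives
translation. Validation MAE is computed on raw, non-augmented pairs.

## TL-embedding reconstruction (`radulna.tlnet`)

Three fully connected parts share a latent space (default 64-d): encoder E
(one-hot 3-class label grid → latent), decoder D (latent → per-voxel
logits), predictor P (DRR pixels → latent). Training is staged:

1. **Denoising autoencoder.** E and D minimize
   `L_label(D(E(y_noised)), y) + λ₁‖E(y_noised)‖₁` with y corrupted by
   Gaussian noise (σ = 0.1 on the one-hot encoding; the encoding and σ are
   package choices) — 35,000 iterations at lr 10⁻⁴ at full scale.
2. **Predictor, decoder frozen.** P minimizes
   `L_label(D(P(x)), y) + λ₁‖P(x)‖₁` — 35,000 iterations at lr 10⁻⁴.
3. **Fine-tuning, encoder frozen.** P and D minimize the stage-2 terms plus
   `λ₂‖E(y) − E(D(P(x)))‖₂` — 15,000 iterations at lr 10⁻⁵.

λ₁ = λ₂ = 10⁻⁴. `L_label` is softmax cross-entropy averaged over voxels,
and latent norms are averaged over the batch, so the λ values are
resolution- and batch-independent. The consistency norm is the Euclidean
norm as printed, not its square (a `squared_consistency` switch provides
the alternative); since D emits logits while E consumes one-hot-like
grids, `E(D(P(x)))` feeds the softmax of the decoder logits into the
encoder to keep the term differentiable. Two readings were genuinely open:
the stage-1 objective is implemented as a sum of its two terms (consistent
with stages 2–3), and the stage-3 consistency compares `E(y)` with
`E(D(P(x)))` exactly as written rather than with `P(x)`. Freezing is
enforced by giving the optimizer only the live parameter set, and verified
by SHA-256 checksums of every network recorded at each stage boundary.
Adam is the optimizer at all stages; a non-finite loss aborts training
naming the stage and step. Reconstruction is `argmax D(P(x))` on the label
grid, which spans the same ±40 mm field of view.

## Evaluation (`radulna.metrics`)

* **MAE** — mean absolute pixel difference, on the optical-depth scale.
* **Surfaces** — marching-cubes vertices of the binarized class at iso 0.5,
  scaled into mm; masks are zero-padded by one voxel so boundary-touching
  shapes close. Iso level and the use of vertices (rather than resampled
  surface points) are package conventions.
* **ASD** — the symmetrized mean nearest-neighbour distance
  `(Σ_A min d + Σ_B min d) / (|A|+|B|)`, computed with a KD-tree; the test
  suite keeps an exhaustive double-loop oracle and requires agreement to
  10⁻⁹, not approximate equality.
* **Histogram-matched baseline** — within the bone mask only (segmentation
  precedes matching), intensities are remapped through a 256-point quantile
  map onto the template's within-mask distribution; outside the mask the
  output is exactly zero.
* **Experiment driver** — evaluates reconstruction from four input
  conditions (clean CT-DRR, translated GAN-DRR, registration-DRR,
  histogram-matched baseline) on identical case lists, reporting per-case
  per-bone ASD rows and mean ± SD aggregates recomputable from the rows.
  The baseline's bone mask comes from Otsu thresholding of the degraded
  radiograph itself — handing the no-learning baseline the ground-truth
  silhouette would overstate what simple image processing delivers.
  Between-condition differences are reported descriptively; inferential
  testing is out of scope. At desk scale the condition ordering is read on
  the fold-mean ASD per condition pooled over both bones: per-bone gaps
  between the clean-DRR and translated conditions are of order 0.01 mm,
  below what a 16³ label grid resolves, while the pooled fold mean is
  stable.

## Desk scale versus full scale

Two presets ship. `paper.yaml` encodes the full-scale configuration
verbatim — 400³ volumes at 0.625 mm, 500×625 images at 0.4 mm, factors
40 and 100, 35,000/35,000/15,000 iterations — and exists for fidelity and
config validation; running it is a multi-day CPU job and is not part of
the routine test path. `desk.yaml` is the configuration the test suite and
the acceptance script actually run: 32 phantoms on 72×72×96 grids at
1.25 mm, 32×32 DRRs at 2.5 mm, 16³ reconstruction labels over the ±40 mm
field of view (5.33 mm label pitch), augmentation factors 8 and 12, and
1200/1200/600 training iterations. These sizes were chosen once, by pilot,
as the smallest configuration on which the learning criteria are
meaningful; they are stated here so that every reported number is read at
its scale. Scaled-down results demonstrate that the pipeline's mechanisms
work and order correctly — they do not predict clinical accuracy in
millimetres; clinical-grade accuracy (≈1 mm) requires clinical
training data, which this package does not ship.

## What the phantom benchmarks show — and what they cannot

Passing tests establish: geometric and radiometric correctness of the
renderer against closed forms; exactness of the metric implementations
against oracles; equivariance and round-trip fidelity of the normalization;
recoverability of synthetic poses; that the translator beats the identity
baseline by a wide margin on held-out phantoms; that the TL net reconstructs
held-out phantom bones to sub-voxel mean surface distance; and that
reconstruction quality degrades in the expected order (clean DRR ≤
translated ≤ histogram-matched baseline) on the shipped configuration's
fold means. The between-condition gaps are small relative to their
case-to-case spread at this scale — the desk study resolves the large
effects (translation versus identity, absolute reconstruction error), while
the clean-versus-translated gap sits near its noise floor. They cannot
establish robustness
to real anatomical shape variation (the phantom population is a smooth
parametric family, not a statistical shape model of real radii), real
scatter/beam-hardening physics, or manual-segmentation noise — the phantom
provides exact labels.

## Known limitations

* Fully connected networks at desk scale: adequate for 16³/32² phantoms,
  not a drop-in for 400³ clinical volumes without a convolutional backbone.
* The degradation model (gamma, vignette, blobs, noise) is a surrogate for
  unmodeled clinical variation, not calibrated physics.
* Orthographic default geometry; perspective exists but the analytic test
  oracles are exact only under orthography.
* Registration capture range is local (~10 mm / 10°); no multi-start
  global search.
* Labels are hard argmax reconstructions; no calibrated uncertainty.
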