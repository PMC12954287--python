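# Methods

## Problem setting

The package addresses prostate whole-gland segmentation and volume
estimation from multi-planar T2w-like volumes when plane availability varies
between training and deployment. The design constraint is asymmetric
supervision: segmentation masks exist only on the axial grid (the canonical
plane for prostate evaluation), while sagittal and coronal stacks are
available as unannotated context — and possibly absent altogether at
deployment (abbreviated protocols).

## Network

A single 2D U-Net-style encoder serves the axial, sagittal and coronal
roles. Weight sharing is structural (one parameter set, not three synced
copies), so it cannot drift apart during training and all views project into
a common latent space. Per level the encoder applies conv3×3→ReLU twice and
downsamples with 2×2 average pooling; channel width doubles per level
(default depth 3, base 6 channels). The deepest feature map is
global-average-pooled and linearly projected to a `latent_dim`-vector
(default 32).

Fusion is the arithmetic mean of the available views' latents. The mean was
chosen over learned fusion because it makes axial-only inference an exact
special case (mean of one) — no retraining or architectural change when
views are missing; only the mean's support changes. The fused latent is
broadcast over the deepest axial feature map's spatial extent, concatenated,
and reduced by a 1×1 convolution before decoding. Skip connections come
exclusively from the axial pass; consequently non-axial inputs influence the
output only through the bottleneck (this is asserted by tests that perturb
sagittal inputs and check the skip tensors bit-exactly).

Latent alignment operates at exam level: each training step pairs the axial
slice latents with the latent of one sagittal and one coronal slice drawn
from the central 50% of their stacks, where gland-bearing slices
concentrate. Per-slice anatomical correspondence across orthogonal planes is
deliberately not modelled; global pooling removes the spatial-correspondence
problem at the cost of a coarser consistency signal.

## Loss

`L_KB = L_dice + L_ce + λ·(d_cos(z_ax, z_sag) + d_cos(z_ax, z_cor))` with
`d_cos(u,v) = 1 − cos(u,v)` averaged over pairs. λ defaults to 0.25 and a
missing view drops its term without rescaling λ. Soft Dice uses smoothing
ε = 1e-5 and foreground-only formulation; CE is computed from logits in a
numerically stable form. The alignment term is pure positive-pair cosine
distance; an InfoNCE-style mode (other exams in the batch as negatives,
temperature 0.1) is available behind `contrastive_mode="infonce"` but off by
default, since plain alignment is the more conservative reading of a
"similarity term based on cosine distance" and introduces no extra
hyperparameter.

The fully supervised reference variant shares the architecture, sets λ = 0,
and supervises the sagittal and coronal views through the *same* decoder
(weight-tied, with each view's own encoder features as skips and its own
latent as the fused input), using masks resliced to those views' grids. The
auxiliary paths add no parameters and are simply not used at inference, so
inference is identical across variants.

## Training

SGD with Nesterov momentum 0.99 and polynomial learning-rate decay
`lr·(1−t/T)^0.9`, base lr 0.01. One optimization step per exam per epoch:
4 axial slices drawn uniformly from the stack (foreground and background
slices both matter), plus one central sagittal and coronal slice for
context. Exam-level 5-fold cross-validation with fold assignment derived
from the sorted exam ids and a seeded permutation, so membership is
invariant to input order; ensemble inference averages the five members'
probabilities before the 0.5 threshold. All randomness flows from a single
seed through named `SeedSequence` substreams (phantoms, folds,
initialization, batching), making full pipeline runs bit-reproducible.

Desk-scale defaults (20 epochs, 64×64 in-plane, depth 3, base 6 channels,
≈19k parameters) train a 5-fold ensemble on 40 phantoms in a few minutes on
one CPU; `paper_preset()` switches to full-scale settings (300 epochs).
These sizes are the package's reference configuration, chosen so the
complete benchmark is convenient to run repeatedly.

The network and optimizer run on `mpkb.nn`, a compact NumPy reverse-mode
autodiff engine written for this package (im2col convolutions as single
GEMMs, average pooling, nearest upsampling, channel concat, pointwise
nonlinearities). Every primitive is verified against central finite
differences in the test suite, and the convolution additionally against
direct 2D correlation.

## Preprocessing

Intensity normalization is percentile-clipped per-volume z-scoring: clip to
the [0.5, 99.5] percentiles, then standardize to zero mean / unit SD. The
clip percentiles are configurable; percentile-clipped z-scoring is the de
facto standard for T2w pipelines, but other normalizations can be
substituted. Resampling to a common reference spacing (default
0.5×0.5×3.0 mm) uses third-order spline interpolation for images and linear
interpolation for masks, re-binarized at 0.5 — the threshold is a package
decision, as is the fallback to linear interpolation (with a logged warning)
on degenerate single-slice axes. Voxel indices are 0-based; physical
coordinates derive from origin + index·spacing per axis, with NIfTI affines
built in RAS. Resampling preserves the physical field of view to within one
voxel per axis and shifts the stored origin to the new first-voxel centre so
grids remain physically aligned across resolutions.

## Phantoms

The synthetic gland is an ellipsoid (semi-axes a, b, c) with an optional
smooth radial perturbation built from even, zero-mean degree-2 real
spherical harmonics, applied in the ellipsoidal coordinate: a point q =
(x/a, y/b, z/c) is inside iff ‖q‖ ≤ 1 + d·f(q̂) with ‖f‖∞ = 1. At d = 0 the
volume is exactly (4/3)πabc; for d > 0 it is computed by Gauss-Legendre ×
uniform-longitude spherical quadrature of (abc/3)(1+d·f)³, accurate to
~1e-10. The maximal extents W, H, L along the anatomical axes (which feed
the ellipsoid-formula reference volume) are evaluated analytically from the
radial field; because f is even, extents are symmetric about the centre.

Intensities are two-class piecewise-constant (defaults fg 150 / bg 60) with
a 0.8-voxel Gaussian edge blur standing in for partial-volume effects, a
multiplicative low-frequency bias field (three random cosine modes,
amplitude ≤ 0.2) mimicking coil-profile heterogeneity, and additive Gaussian
noise. Per view, the fine isotropic rendering (0.5 mm) is axis-permuted into
the view's slicing order and resampled to that view's anisotropic spacing.

Cohort defaults: semi-axes U[12, 17] mm per axis, deformation amplitude
U[0.02, 0.08], noise SD U[8, 15], bias amplitude U[0.05, 0.2], in-plane
spacing U[0.4, 0.6] mm and slice thickness U[2.5, 3.5] mm (bracketing
typical clinical T2w acquisitions). The compact gland sizes keep the default
fine rendering at ≤ ~96³ voxels so cohort generation and training stay
fast; they correspond to smaller-than-average glands (≈7–21 ml), which is a
deliberate trade-off of the reference configuration, not a claim about
clinical anatomy.

What the phantoms do **not** emulate: MR physics (no k-space, TE/TR or
sequence simulation), surrounding anatomy (bladder, rectum, seminal
vesicles), zonal structure, lesions, motion or susceptibility artifacts, and
inter-view misregistration (all views are rendered from one aligned fine
grid). Passing the benchmark therefore demonstrates that the architecture,
losses, training loop and evaluation stack behave as specified on
well-posed, high-contrast data — not that the model reaches clinical-grade
accuracy on real MRI.

## Volumetry and agreement

Mask volume is foreground voxel count × voxel volume. DSC is 2|A∩B|/(|A|+|B|)
with the both-empty case defined (and logged) as 1. ASD is the *symmetric*
average surface distance: boundary voxels by 6-connectivity erosion,
physical distances by spacing-aware Euclidean distance transform, the two
directional means averaged. RVD is signed, 100·(PV_pred − PV_ref)/PV_ref
(negative = underestimation); reports also carry |RVD| as a secondary
column since some summaries quote the magnitude. ICC is fixed to the
two-way random-effects, absolute-agreement, single-measurement variant
(ICC(2,1), computed via pingouin and cross-checked against an ANOVA
mean-squares hand calculation in the tests), with the interpretation bands
<0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good, >0.90 excellent. Perfect
agreement (all differences exactly zero) short-circuits to ICC = 1 because
the ANOVA error mean square is exactly zero there. Bland-Altman limits are
mean ± 1.96·SD (sample SD, n−1). Paired comparisons use Shapiro-Wilk at
α = 0.05 to choose between the paired t-test and the Wilcoxon signed-rank
test; all-zero differences return p = 1 with a degenerate-case label.

On phantoms the reference volume PV_ref is the ellipsoid formula applied to
the analytic ground-truth diameters — never re-measured from masks — so the
reference stays independent of the segmentation under test, mirroring its
radiologist-derived role. For deformed glands the ellipsoid formula is
itself only approximate (it overestimates slightly for convex
perturbations), which bounds the achievable RVD even for a perfect
segmentation; at the default deformation amplitudes this contributes a few
percent at most.

## Numerical and design notes

* Probability threshold 0.5; no largest-connected-component postprocessing
  (off by default — not part of the modelled pipeline).
* Inference context latents average the encoder outputs of the central 50%
  of each context view's slices (deterministic), where training sampled one
  random central slice (stochastic); averaging is the lower-variance choice
  at test time.
* Fine-grid rendering auto-sizes the field of view to the gland plus a 5 mm
  margin, so arbitrary semi-axes remain representable.
* View-consistency of the three per-view mask renderings (pairwise DSC
  after mapping back to a common grid) is governed by the ratio of gland
  size to slice thickness: ≈0.92–0.94 for the compact default-cohort glands
  at 3 mm slices (pure partial-volume loss) and ≥0.96 for clinically
  typical ~60 ml glands, which is what the property test uses.
* Scenario monotonicity (multi-planar ≥ axial-only DSC) is logged and
  bounded in the benchmark (gap ≤ 0.05) but not asserted as a theorem; the
  method's claim is comparability, not dominance.

## Known limitations

* 2D slice-wise decoding; no 3D context beyond the fused exam-level latent.
* Exam-level (not anatomically localized) cross-view correspondence.
* The NumPy training loop is single-threaded and CPU-bound; it is meant for
  desk-scale studies, not full-resolution clinical training runs.
* The fully supervised baseline's wiring (weight-tied decoder on every
  view) is one reasonable realization of "trained with masks for all three
  planes"; other wirings (separate decoders, 2.5D fusion) are not explored.
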