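# Methods

This note records the model, the numerical choices, and what the phantom
world does and does not establish. It documents design decisions in the
package's own terms; every number quoted here is computed by the test suite
or the acceptance script.

## Preprocessing

The common grid is defined by the MR's physical bounding box (clinically
the MR field of view is contained in the CT's; if not, the box is clipped
to the intersection and a warning logged). Voxel membership is decided by
voxel *centers* against a half-open physical box, which makes cropping
unambiguous on both grids. Both volumes are then resampled onto the same
target grid spanning that box — identical shape, spacing, and origin by
construction — using order-3 spline interpolation (`scipy.ndimage.
map_coordinates`); out-of-extent lookups clamp to the nearest edge sample,
which avoids ringing into the air background. Spline prefiltering is exact
for interior samples but perturbs a narrow band near the volume faces, so
the polynomial-reproduction property of cubic splines holds away from the
boundary (the tests check the central region to 1e-6).

Intensity normalization is per image and two-stage: a z-score followed by
the affine map of the z-scored range onto exactly [−1, 1]. The four
constants (μ, σ, m, d) are stored so the map is invertible to 1e-6. The
z-score stage is redundant for the final range but kept because the
composition is the stated procedure; normalization happens on the full
re-FOV image *before* patching, so all five patch datasets share one
intensity baseline (per-patch normalization produces mosaic artifacts at
patch seams in the merged prediction).

## Patch layout

Five overlapping patches cover the grid: four in-plane corner patches plus
one centered patch (p3), all spanning the full z extent. For the production
grid 200×200×128 with 128³ patches the offsets are (0,0,0), (72,0,0),
(36,36,0), (0,72,0), (72,72,0); the construction generalizes to any grid
whose patch side is at least half the in-plane side. The overlap map (how
many patches contain each voxel, 1..5 here) is computed by direct
membership counting and is the divisor when per-patch predictions are
accumulated on a zero base map — i.e. overlapping predictions are averaged,
which removes patch-seam discontinuities.

## Rotation augmentation

One angle triple per epoch, applied identically to every pair of that epoch
(the pair rotates rigidly, so MR/CT correspondence is preserved). The fixed
parts enumerate {1,−1,3,−3,5,−5,7,−7}³ lexicographically with the z
component fastest — 512 distinct triples per cycle — and the jitter is an
independent U(−1,1)-degree draw per axis per epoch, keyed by (seed, epoch)
so draws are reproducible regardless of call order. Angles are in degrees;
rotation is about the grid's geometric center in physical (mm) space,
composed as intrinsic x-then-y-then-z. Interpolation is trilinear with fill
value −1 (air after normalization): cheap, monotone, and free of overshoot
at the skull/air boundary. The interpolation blur means rotation is not
exactly invertible; on a smooth phantom a forward-inverse round trip keeps
MSSIM above 0.98.

## The translation model

The generator is a 3D u-net: stride-2 convolutions of size k³ halve each
axis per level while filters double from the base count f (capped at 8f);
the decoder mirrors with stride-2 transpose convolutions, concatenating the
matching encoder feature map at each resolution, and ends in tanh. Instance
normalization is used everywhere except the first encoder and the final
output block. Depth defaults to enough levels for a 2³–4³ bottleneck
(6 levels at 128³). The production presets k4_f80, k6_f60, k8_f30 hold
183M, 347M, and 206M trainable parameters respectively at 128³ — order
hundreds of millions; tests check the order analytically without
allocating.

The discriminator is a conditional PatchGAN: the channel-concatenated
(MR, candidate) volume passes three stride-2 k³ convolution blocks and a
final 1³ convolution to a single sigmoid channel, giving an M³ grid of
probability-real scores, each judging only its own receptive field
(verified by a finite-difference locality test).

Training minimizes, at batch size 1,

    loss_D = −mean log D(c, x) − mean log(1 − D(c, G(c)))
    loss_G = −mean log D(c, G(c)) + λ · mean |x − G(c)|,   λ = 100

the non-saturating generator form of the minimax objective. Scores are
clamped away from 0/1 by 1e-7 before logs. The stochastic input z is
realized as decoder dropout (rate 0.5, first three decoder blocks), active
only during training — inference is deterministic. Optimizer: Adam,
learning rate 2e-4, β₁ = 0.5, the standard image-translation defaults;
the source work tuned its rates without publishing them, so these are
exposed as parameters. Training is exactly reproducible given (seed, data,
config).

**No deep-learning framework is used.** The layers (strided conv, transpose
conv, instance norm, activations, dropout, Adam) are implemented in numpy:
forward im2col + matmul, backward as the adjoint scatter with a cached
index map. All layer gradients are validated against central finite
differences in the test suite. This keeps the package dependency-light; the
cost is that only the desk-scale configurations are practical to train
(the production presets build and run forward passes, but training them at
128³ would take GPU hardware and a framework).

## Ensembling

Per patch, the three kernel-size predictions are averaged 1:1:1. Each
patch's mixed prediction is then linearly mapped so its (min, max) match
the centered p3 patch's mixed prediction for the *same volume* (per-volume
statistics, computed at assembly time; training-time output ranges are also
stored in the bundle as a fallback). p3 itself passes through unchanged.
Range alignment removes inter-model brightness offsets that would otherwise
show as tiling in the merged volume, but it is not the identity when a
patch's prediction does not attain the global extremes — callers who need
the strict identity property (e.g. plumbing tests with identity generators)
can pass `align="none"`.

## Similarity metrics

CAD and L2 are computed on raw intensities. MSE, PSNR, and MSSIM are
computed after mapping both volumes jointly (shared min/max) onto [0, 1],
so the data range is L = 1; on that scale MSE ≈ 1e-3 and PSNR ≈ 30 dB are
mutually consistent, which fixes the otherwise ambiguous choice of scale.
L2 is reported as the rooted Euclidean distance. MSSIM uses an 11³
Gaussian window (σ = 1.5 samples, truncated, unit sum), population (not
sample) weighted moments, constants C1 = (0.01L)², C2 = (0.03L)²,
C3 = C2/2, and unit exponents; a uniform 7³-window mode is provided for
parity with tools whose default skips Gaussian weighting. The separable
implementation is verified against a direct per-window summation to 1e-8
and against scikit-image's Gaussian-weighted SSIM to 1e-7. PSNR of
identical volumes is reported as the +inf sentinel.

## The phantom world

Each subject is an ellipsoidal head (rotated axes, jittered center,
semi-axes 0.66–0.86 of the half-FOV) in air, with a ~2-voxel skull shell,
a brain interior carrying Gaussian-correlated texture (correlation length 2
lattice voxels), and 0–3 soft-edged lesion blobs. MR and CT intensities are
class-dependent bases plus texture gains with deliberately *opposite*
contrast (MR: bright brain, dark skull; CT: bright skull, damped inverted
brain texture), so the MR→CT mapping is piecewise monotone, learnable, and
— crucially — exactly known: the CT equals a fixed function of the class
map and texture, which the tests use as an oracle. Additive Gaussian noise
(sd 1% of the dynamic range) keeps the task non-degenerate. The MR is
generated on a finer grid covering exactly the target FOV and the CT on a
coarser grid extending 32 mm beyond it, exercising the re-FOV/resampling
path. Of 31 subjects, the last 2 (the 2-in-31 outlier fraction) get extreme
pathology: 4–6 large lesions, an 80%-probability skull-shell defect, and
CT-bright "postoperative" lesions — the held-out tail that stresses
generalization like wide-tumor and postsurgical cases do clinically.

What the phantom does *not* emulate: MR/CT physics (no bias fields, beam
hardening, metal artifacts, partial-volume mixtures beyond interpolation),
registration error between the pair (the pair is co-registered by
construction), anatomical detail, or Hounsfield calibration. A green
end-to-end test therefore establishes that the pipeline's machinery —
preprocessing, patching, augmentation, adversarial training, ensembling,
evaluation — is correct and that the model class can learn a nontrivial
cross-contrast mapping; it does not establish clinical image quality.

## Scaled-down experiments

The default desk scale is a 64×64×32 grid with 32³ patches (the layout
construction, architecture, and all contracts are size-free). The
end-to-end run trains the five patch models with the reduced configuration
k = 4, f = 8, depth 3 for 780 iterations each (30 epochs of the 26
training subjects; the acceptance budget allows up to 2,000) and requires
the synthesized test volumes to beat the MR-as-prediction baseline on MSSIM
and MSE for at least 4 of 5 held-out subjects; at seed 0 it wins 5/5. The
augmentation ablation trains the p3 model twice (520 iterations, identical
seed and data, augmentation off/on) and compares final train−test MSSIM
gaps; at seed 0 the no-augmentation gap is larger (0.128 vs 0.119), the
overfitting signature augmentation is meant to suppress. Both checks are
stochastic; the seeds are fixed in the tests and were not searched.

## Numerical details and degenerate inputs

- Constant images cannot be normalized (σ = 0) and constant predictions
  cannot be range-aligned (warned, passed through).
- CAD is undefined for an all-zero volume (error).
- Local SSIM variances are clipped at 0 before square roots to absorb
  float roundoff.
- Conv geometry requires each spatial side divisible by 2^depth; even
  kernels with stride 2 use padding (k−2)/2 for exact halving.
- Non-finite training losses abort with a diagnostic rather than continue.
- Epoch rotation is lazy: only the pairs actually consumed in an epoch are
  rotated.

## Known limitations

- Training at the production 128³/f80 scale is impractical in numpy; the
  presets exist, build, and forward, but the trained experiments are
  desk-scale.
- The patch layout family is the fixed corners-plus-center construction;
  arbitrary sliding-window tilings are out of scope.
- Only rigid rotation augmentation is implemented (no flips, elastic, or
  intensity augmentation).
- Pairs are assumed co-registered; no registration is performed.
- No DICOM ingestion; NIfTI-1 only.
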