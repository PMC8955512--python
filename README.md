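# voxtrans

Patch-based 3D conditional-GAN translation of MR head volumes into
synthetic CT, with a fully desk-testable phantom world.

## The problem

Radiotherapy treatment planning needs CT: electron density and geometry for
dose calculation come from CT, while tumor delineation is best done on MR.
An MR-only workflow must therefore *synthesize* the CT from the MR.
`voxtrans` implements such a pipeline for paired, co-registered 3D volumes:

1. **Preprocessing** — a common field of view is defined from the MR (the
   smaller FOV), both volumes are cropped, resampled onto one grid with
   order-3 spline interpolation, then each image is normalized in two
   stages: a z-score `img' = (img − μ)/σ` followed by the affine map
   `img'' = (img' − m)/d` with `m = (max+min)/2`, `d = (max−min)/2`, so the
   result spans exactly [−1, 1].
2. **Patching** — the common grid (production size 200×200×128) is covered
   by five overlapping 128³ patches: four in-plane corners plus a centered
   patch (p3), never subdividing z. A per-voxel overlap map records how
   many patches cover each voxel.
3. **Augmentation** — each training epoch rotates every pair by one angle
   triple `(θx, θy, θz) = (θf[i]+θr, θf[j]+θr, θf[k]+θr)` with the fixed
   parts cycling through `{1, −1, 3, −3, 5, −5, 7, −7}` per axis
   (8³ = 512 combinations, z varying fastest) and `θr ~ U(−1, 1)` degrees
   redrawn per epoch. With 26 training subjects one full cycle spans
   26 × 512 = 13,312 iterations.
4. **3D pix2pix** — a u-net generator (stride-2 k³ convolutions, filters
   doubling from the base count f, skip concatenations, tanh output) and a
   conditional PatchGAN discriminator (a grid of sigmoid scores, each with
   a limited receptive field) trained with
   `G* = arg min_G max_D L_cGAN(G, D) + λ L_L1(G)`, λ = 100, batch size 1,
   Adam(2e-4, β₁ = 0.5). Production presets: `k4_f80`, `k6_f60`, `k8_f30`.
5. **Ensembling** — per patch, the three kernel-size predictions are mixed
   1:1:1; every patch's mixed prediction is linearly converted to the
   output range of the centered p3 model; the five aligned predictions are
   accumulated on a zero base map and divided by the overlap count.
   A complete bundle holds 5 × 3 = 15 models.
6. **Metrics** — CAD (cosine of the angle between flattened volumes), L2
   (Euclidean distance), MSE, PSNR = 10·log₁₀(L²/MSE), and MSSIM (mean
   local SSIM under an 11³ Gaussian window, σ = 1.5, unit sum).

Because clinical paired MR/CT data are access-restricted, the package ships
a **phantom generator**: ellipsoidal heads with skull shell, textured brain,
and lesion blobs, where the CT is a known deterministic function of the
tissue classes and texture. Translation quality therefore has an exactly
computable ground truth, and the whole pipeline trains in minutes on one
CPU at the 64×64×32 test scale. The networks are implemented in pure
numpy (im2col convolutions with manual backpropagation), so no GPU or deep
learning framework is required.

## Worked example

```python
import voxtrans as vt
from voxtrans.gan3d import GeneratorConfig, ModelBundle, train_model
from voxtrans.patching import extract_patch
from voxtrans.preprocess import PairedSample

spec = vt.PhantomSpec(seed=0)                       # 64 x 64 x 32 world
samples = vt.preprocess_dataset(vt.generate_dataset(spec, 31), spec.shape)
train, test = vt.split_train_test(samples)          # 26 train / 5 test
layout = vt.default_layout(spec.shape, (32, 32, 32))

bundle = ModelBundle(n_patches=5, presets=("k4_f8",))
for p in range(1, 6):
    patches = [PairedSample(s.subject_id, extract_patch(s.mr, layout, p),
                            extract_patch(s.ct, layout, p)) for s in train]
    bundle.add(p, "k4_f8", train_model(
        patches, GeneratorConfig(kernel_size=4, base_filters=8, depth=3),
        iterations=780, schedule=vt.RotationSchedule(rng_seed=0), seed=p))

for s in test:
    sct = vt.synthesize(s.mr, bundle, layout)
    r = vt.evaluate(s.ct, sct)
    print(s.subject_id, f"mssim={r.mssim:.3f} mse={r.mse:.5f} psnr={r.psnr:.1f}")
```

prints (seeded run):

```
phantom-0026 mssim=0.533 mse=0.01106 psnr=19.6
phantom-0027 mssim=0.528 mse=0.01187 psnr=19.3
phantom-0028 mssim=0.531 mse=0.01073 psnr=19.7
phantom-0029 mssim=0.541 mse=0.01179 psnr=19.3
phantom-0030 mssim=0.451 mse=0.01355 psnr=18.7
```

i.e. every held-out synthetic CT is far closer to the true CT than the MR
itself is (the MR baseline scores MSSIM ≤ 0.14 on the same subjects,
because MR and CT contrast are inverted at the skull). The last two
subjects are deliberate outliers (large or postoperative-bright lesions,
skull defects) and score lowest.

There is also a CLI (`voxtrans phantom / preprocess / train / predict /
evaluate / ablation`); see `voxtrans --help`.

Scikit-learn-style estimators `Pix2PixTranslator` (one patch model) and
`PatchKernelEnsemble` (the whole patch × kernel family) wrap the same
functions with `fit`/`predict` and `get_params`/`set_params`.

## Acceptance script

`scripts/acceptance.py` re-runs the main computation from scratch: it
generates the 31-subject phantom dataset, preprocesses it, trains the five
patch models with rotation augmentation, synthesizes the five held-out test
volumes, and prints all five similarity indices (mean ± SD) against the
known ground truth alongside the MR-as-prediction baseline:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/voxtrans/volume_io.py` — NIfTI-1 reading/writing, HDF5 pair container
- `src/voxtrans/preprocess.py` — FOV, cropping, spline resampling, normalization
- `src/voxtrans/patching.py` — overlapping patch layout, overlap map, merge
- `src/voxtrans/augmentation.py` — rotation schedule and paired rotation
- `src/voxtrans/nn.py` — numpy conv-net layers with manual backprop
- `src/voxtrans/gan3d.py` — u-net, PatchGAN, losses, training loop
- `src/voxtrans/ensemble.py` — kernel mixing, range alignment, synthesis
- `src/voxtrans/metrics.py` — CAD, L2, MSE, PSNR, MSSIM
- `src/voxtrans/phantom.py` — paired head-phantom generator
- `src/voxtrans/experiments.py`, `cli.py` — ablation runner and CLI

See `docs/methods.md` for modeling assumptions, parameter choices, and
limitations.
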