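"""Multi-model merging: kernel-size mixing and full-volume assembly.

Per patch, the predictions of the three kernel-size models are mixed 1:1:1
(voxelwise mean).  Every patch's mixed prediction is then linearly converted
to the output range of the center (p3) model — the reference, since its
patch sees the middle of the head — and the five aligned patch predictions
are merged into the full grid by overlap-weighted averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gan3d import ModelBundle, predict
from .patching import PatchLayout, extract_patch, merge_patches
from .volume_io import Volume

__all__ = ["RangeStats", "merge_kernels", "align_range", "synthesize",
           "PatchKernelEnsemble"]

log = logging.getLogger(__name__)

REFERENCE_PATCH = 3  # the centered patch; its model's range is the target


@dataclass(frozen=True)
class RangeStats:
    """Observed (min, max) of a model's prediction."""

    min: float
    max: float

    def __post_init__(self):
        if not self.min < self.max:
            raise ValueError(f"degenerate range [{self.min}, {self.max}]")


def merge_kernels(*preds) -> Volume:
    """Voxelwise 1:1:1 mean of per-kernel predictions of one patch."""
    if len(preds) == 1 and isinstance(preds[0], (list, tuple)):
        preds = tuple(preds[0])
    arrays = [p.data if isinstance(p, Volume) else np.asarray(p) for p in preds]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError("kernel predictions have differing shapes")
    out = np.mean(arrays, axis=0)
    first = preds[0]
    if isinstance(first, Volume):
        return first.copy_with(data=out)
    return Volume(data=out)


def align_range(pred: Volume, ref: RangeStats) -> Volume:
    """Affine map sending (min(pred), max(pred)) onto (ref.min, ref.max).

    A constant prediction has no range to map; it is returned unchanged with
    a warning.
    """
    arr = pred.data if isinstance(pred, Volume) else np.asarray(pred)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        log.warning("align_range: constant prediction, returned unchanged")
        return pred
    scale = (ref.max - ref.min) / (hi - lo)
    out = ref.min + (arr - lo) * scale
    if isinstance(pred, Volume):
        return pred.copy_with(data=out)
    return Volume(data=out)


def synthesize(mr_full: Volume, bundle: ModelBundle, layout: PatchLayout,
               align: str = "p3") -> Volume:
    """Full-volume synthetic CT from a complete model bundle.

    Per patch p: predict with every preset, mix the kernel outputs 1:1:1,
    then (``align="p3"``) linearly convert each patch's mixed prediction to
    the range of the p3 patch's mixed prediction for this volume;
    ``align="none"`` skips the conversion.  Finally the aligned patch
    predictions are merged on the full grid by overlap averaging.
    """
    if align not in ("p3", "none"):
        raise ValueError(f"align must be 'p3' or 'none', got {align!r}")
    if not bundle.is_complete:
        raise ValueError(f"incomplete bundle; missing entries: {bundle.missing()}")
    if mr_full.shape != layout.grid_shape:
        raise ValueError(
            f"volume shape {mr_full.shape} != layout grid {layout.grid_shape}")
    mixed = []
    for p in range(1, layout.n_patches + 1):
        patch = extract_patch(mr_full, layout, p)
        preds = [predict(bundle.get(p, preset).generator, patch)
                 for preset in bundle.presets]
        mixed.append(merge_kernels(preds))
    if align == "p3":
        ref_arr = mixed[REFERENCE_PATCH - 1].data
        ref = RangeStats(min=float(ref_arr.min()), max=float(ref_arr.max()))
        mixed = [m if p == REFERENCE_PATCH else align_range(m, ref)
                 for p, m in enumerate(mixed, start=1)]
    return merge_patches(mixed, layout)


try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass


class PatchKernelEnsemble(BaseEstimator):
    """Estimator over the whole patch x kernel model family.

    ``fit`` trains one generator per (patch, preset) combination on the
    corresponding patch datasets; ``predict`` runs the full synthesis
    (per-patch prediction, kernel mixing, p3 range alignment, overlap
    merge).  ``configs`` maps preset names to reduced
    :class:`~voxtrans.gan3d.GeneratorConfig` objects so the family can be
    trained at desk scale.
    """

    def __init__(self, layout: PatchLayout | None = None, configs: dict | None = None,
                 iterations: int = 200, augment: bool = True, seed: int = 0,
                 eval_every: int | None = None, lam: float = 100.0,
                 lr: float = 2e-4, beta1: float = 0.5, align: str = "p3"):
        self.layout = layout
        self.configs = configs
        self.iterations = iterations
        self.augment = augment
        self.seed = seed
        self.eval_every = eval_every
        self.lam = lam
        self.lr = lr
        self.beta1 = beta1
        self.align = align

    def fit(self, pairs, test_pairs=None) -> "PatchKernelEnsemble":
        from .augmentation import RotationSchedule
        from .gan3d import PRESETS, train_model
        from .preprocess import PairedSample

        layout = self.layout
        if layout is None:
            raise ValueError("layout must be provided")
        configs = self.configs or PRESETS
        bundle = ModelBundle(n_patches=layout.n_patches, presets=tuple(configs))
        for p in range(1, layout.n_patches + 1):
            patch_pairs = [PairedSample(subject_id=s.subject_id,
                                        mr=extract_patch(s.mr, layout, p),
                                        ct=extract_patch(s.ct, layout, p))
                           for s in pairs]
            patch_test = [PairedSample(subject_id=s.subject_id,
                                       mr=extract_patch(s.mr, layout, p),
                                       ct=extract_patch(s.ct, layout, p))
                          for s in (test_pairs or [])] or None
            for j, (name, cfg) in enumerate(configs.items()):
                schedule = RotationSchedule(rng_seed=self.seed) if self.augment else None
                entry = train_model(patch_pairs, cfg, iterations=self.iterations,
                                    schedule=schedule, eval_every=self.eval_every,
                                    seed=self.seed + 1000 * p + j,
                                    test_dataset=patch_test, lam=self.lam,
                                    lr=self.lr, beta1=self.beta1)
                bundle.add(p, name, entry)
        self.bundle_ = bundle
        return self

    def predict(self, mr_full: Volume) -> Volume:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("estimator is not fitted")
        return synthesize(mr_full, self.bundle_, self.layout, align=self.align)
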