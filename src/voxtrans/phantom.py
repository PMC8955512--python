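"""Synthetic co-registered MR/CT head-phantom pairs.

Each subject is an ellipsoidal "head" (rotated axes, jittered center) in an
air background: a thin bright-on-CT / dark-on-MR skull shell, a textured
brain interior, and a variable number of soft-edged lesion blobs.  The CT
is a fixed deterministic function of the tissue-class map and the shared
texture field, so the MR -> CT mapping is a learnable piecewise-monotone
function and the true target of any translation is exactly known.

The MR is generated on a finer grid with a smaller field of view than the
CT, which exercises the re-FOV and resampling path of the preprocessing
workflow.  A configurable fraction of subjects are "outliers" (many/large
lesions, a skull defect, CT-bright postoperative blobs), mimicking a test
set that stresses the model with pathology extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import PairedSample, preprocess_pair
from .volume_io import Volume

__all__ = ["PhantomSpec", "generate_pair", "generate_dataset",
           "split_train_test", "preprocess_dataset", "ct_from_classes",
           "AIR", "SKULL", "BRAIN", "LESION"]

AIR, SKULL, BRAIN, LESION = 0, 1, 2, 3

# class-dependent intensity bases and texture gains; the CT column is the
# ground-truth mapping every model tries to learn
_MR_BASE = {AIR: 0.02, SKULL: 0.12, BRAIN: 0.75, LESION: 0.55}
_MR_GAIN = {AIR: 0.00, SKULL: 0.03, BRAIN: 0.15, LESION: 0.10}
_CT_BASE = {AIR: 0.02, SKULL: 0.95, BRAIN: 0.35, LESION: 0.50}
_CT_GAIN = {AIR: 0.00, SKULL: 0.00, BRAIN: -0.08, LESION: -0.05}
_CT_BRIGHT_LESION = 0.85  # postoperative hyperdense variant (outliers)


@dataclass(frozen=True)
class PhantomSpec:
    """The stated world of the generator.

    shape/spacing describe the common target grid after preprocessing; the
    raw MR and CT grids are derived from them (MR: finer voxels over the
    same FOV; CT: coarser voxels over a larger FOV).  semi_axes_range is the
    ellipsoid semi-axis as a fraction of the half-FOV; shell_voxels the
    skull shell thickness in target voxels; texture_length the Gaussian
    correlation length of the brain texture in texture-lattice voxels;
    noise_sd the additive Gaussian noise as a fraction of the dynamic range.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    semi_axes_range: tuple[float, float] = (0.66, 0.86)
    shell_voxels: float = 2.0
    lesion_count_range: tuple[int, int] = (0, 3)
    outlier_lesion_count_range: tuple[int, int] = (4, 6)
    texture_length: float = 2.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.semi_axes_range[0] <= self.semi_axes_range[1] < 1.0:
            raise ValueError("semi-axes fractions must fit inside the grid")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


def _rotation(rng) -> np.ndarray:
    ang = np.deg2rad(rng.uniform(-10, 10, size=3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _subject_params(spec: PhantomSpec, rng, outlier: bool) -> dict:
    fov = spec.fov_mm
    center = fov / 2.0 + rng.uniform(-1.5, 1.5, size=3) * np.asarray(spec.spacing) / 2.0
    frac = rng.uniform(*spec.semi_axes_range, size=3)
    semi = frac * fov / 2.0
    shell_frac = spec.shell_voxels * float(np.mean(spec.spacing)) / float(np.mean(semi))
    lo, hi = (spec.outlier_lesion_count_range if outlier else spec.lesion_count_range)
    n_lesions = int(rng.integers(lo, hi + 1))
    lesions = []
    for _ in range(n_lesions):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u) + 1e-12
        rad_frac = rng.uniform(0.55, 0.75) if outlier else rng.uniform(0.10, 0.45)
        pos = center + _unit_scale(u, semi) * rad_frac * 0.6
        radius = rng.uniform(9.0, 18.0) if outlier else rng.uniform(6.0, 12.0)
        lesions.append((pos, radius))
    defect_dir = None
    if outlier and rng.random() < 0.8:  # skull defect: a missing shell sector
        d = rng.normal(size=3)
        defect_dir = d / (np.linalg.norm(d) + 1e-12)
    # texture lattice over the MR FOV, one independent field per subject
    tex_shape = (48, 48, 32)
    tex = rng.normal(size=tex_shape)
    tex = ndimage.gaussian_filter(tex, spec.texture_length, mode="wrap")
    tex /= max(tex.std(), 1e-9)
    return {"center": center, "semi": semi, "rot": _rotation(rng),
            "shell_frac": shell_frac, "lesions": lesions,
            "defect_dir": defect_dir, "bright_lesions": outlier,
            "tex": tex, "tex_shape": tex_shape, "fov": fov}


def _unit_scale(u, semi):
    return u * semi


def _grid_positions(shape, spacing, origin):
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _evaluate_subject(params: dict, shape, spacing, origin):
    """Tissue classes and texture sampled at one grid's voxel centers."""
    px, py, pz = _grid_positions(shape, spacing, origin)
    pos = np.stack([px, py, pz], axis=-1) - params["center"]
    # normalized ellipsoid radius in the rotated frame
    local = pos @ params["rot"]
    r = np.sqrt(((local / params["semi"]) ** 2).sum(axis=-1))
    classes = np.full(shape, AIR, dtype=np.int8)
    inner = 1.0 - params["shell_frac"]
    classes[r <= 1.0] = SKULL
    classes[r <= inner] = BRAIN
    if params["defect_dir"] is not None:
        unit = local / (np.linalg.norm(local, axis=-1, keepdims=True) + 1e-12)
        sector = unit @ params["defect_dir"] > np.cos(np.deg2rad(40.0))
        classes[(classes == SKULL) & sector] = BRAIN
    for lpos, lrad in params["lesions"]:
        d2 = (((np.stack([px, py, pz], axis=-1) - lpos) / lrad) ** 2).sum(axis=-1)
        classes[(d2 < 1.0) & (classes == BRAIN)] = LESION
    # texture: pure function of physical position via the subject lattice
    fov = params["fov"]
    tex_shape = np.asarray(params["tex_shape"], dtype=float)
    coords = [np.clip((np.stack([px, py, pz], axis=-1)[..., a] / fov[a])
                      * tex_shape[a] - 0.5, 0, tex_shape[a] - 1) for a in range(3)]
    tex = ndimage.map_coordinates(params["tex"], coords, order=1, mode="nearest")
    return classes, tex


def ct_from_classes(classes: np.ndarray, texture: np.ndarray,
                    bright_lesions: bool = False) -> np.ndarray:
    """The ground-truth CT mapping: deterministic in (class, texture)."""
    out = np.empty(classes.shape, dtype=np.float64)
    for cls in (AIR, SKULL, BRAIN, LESION):
        mask = classes == cls
        base = _CT_BASE[cls]
        gain = _CT_GAIN[cls]
        if cls == LESION and bright_lesions:
            base, gain = _CT_BRIGHT_LESION, 0.0
        out[mask] = base + gain * texture[mask]
    return out


def _mr_from_classes(classes: np.ndarray, texture: np.ndarray) -> np.ndarray:
    out = np.empty(classes.shape, dtype=np.float64)
    for cls in (AIR, SKULL, BRAIN, LESION):
        mask = classes == cls
        out[mask] = _MR_BASE[cls] + _MR_GAIN[cls] * texture[mask]
    return out


def generate_pair(spec: PhantomSpec, subject_seed: int,
                  outlier: bool = False) -> PairedSample:
    """One raw (pre-normalization) co-registered pair.

    The MR grid is finer and covers exactly the target FOV; the CT grid is
    coarser and extends 32 mm beyond it on every side.  Tissue classes and
    texture are evaluated per grid from the same functions of physical
    position, so the pair is co-registered by construction; the class map
    and texture are kept in each volume's ``meta`` for oracle checks.
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, int(subject_seed)])
    params = _subject_params(spec, rng, outlier)
    fov = spec.fov_mm

    mr_shape = tuple(int(round(s * 1.25)) for s in spec.shape)
    mr_sp = fov / np.asarray(mr_shape)
    mr_origin = mr_sp / 2.0
    margin = 32.0
    ct_shape = tuple(int(round(s * 1.1)) for s in spec.shape)
    ct_sp = (fov + 2 * margin) / np.asarray(ct_shape)
    ct_origin = -margin + ct_sp / 2.0

    vols = {}
    for name, shape, sp, orig in (("mr", mr_shape, mr_sp, mr_origin),
                                  ("ct", ct_shape, ct_sp, ct_origin)):
        classes, tex = _evaluate_subject(params, shape, tuple(sp), tuple(orig))
        if name == "mr":
            data = _mr_from_classes(classes, tex)
        else:
            data = ct_from_classes(classes, tex, bright_lesions=params["bright_lesions"])
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=shape)
        vols[name] = Volume(data=data, spacing=tuple(sp), origin=tuple(orig),
                            meta={"tissue_class": classes, "texture": tex,
                                  "bright_lesions": params["bright_lesions"]})
    return PairedSample(subject_id=f"phantom-{subject_seed:04d}",
                        mr=vols["mr"], ct=vols["ct"])


def generate_dataset(spec: PhantomSpec, n_subjects: int, seed: int | None = None,
                     outlier_fraction: float = 2.0 / 31.0) -> list[PairedSample]:
    """``n_subjects`` reproducible pairs with distinct subject seeds.

    The last ``round(outlier_fraction * n)`` subjects are generated from the
    extreme ends of the lesion/defect ranges, mirroring a validation set
    that includes wide-tumor and postsurgical outliers.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is not None:
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    n_out = int(round(outlier_fraction * n_subjects))
    samples = []
    for i in range(n_subjects):
        outlier = i >= n_subjects - n_out
        samples.append(generate_pair(spec, subject_seed=i, outlier=outlier))
    return samples


def split_train_test(samples, n_test: int = 5):
    """Default split: the last ``n_test`` subjects (the outlier-containing
    tail) are the held-out test pairs — 26 train / 5 test for 31 subjects."""
    if not 0 < n_test < len(samples):
        raise ValueError("n_test must be in 1..n_subjects-1")
    return list(samples[:-n_test]), list(samples[-n_test:])


def preprocess_dataset(samples, target_shape) -> list[PairedSample]:
    """Run the full preprocessing workflow on every raw pair."""
    return [preprocess_pair(s.mr, s.ct, target_shape, subject_id=s.subject_id)
            for s in samples]
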