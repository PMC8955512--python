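"""Pair preprocessing: common FOV, cropping, spline resampling, normalization.

The workflow takes a raw MR/CT pair acquired on different grids and produces
two volumes on one common grid with intensities in [-1, 1]:

1. re-FOV — a common field of view is defined from the MR (clinically the MR
   FOV is the smaller one); voxels outside it are dropped.
2. resampling — both volumes are interpolated (order-3 spline) onto the same
   target grid spanning that FOV.
3. normalization — each image is z-scored, then affinely mapped so its
   minimum is exactly -1 and its maximum exactly +1; the four constants are
   kept so the map can be inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = ["FovBox", "NormalizationRecord", "PairedSample",
           "common_fov", "crop_to_fov", "resample", "normalize",
           "denormalize", "preprocess_pair"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FovBox:
    """Axis-aligned physical box in mm; half-open, voxel centers decide membership."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self):
        if not all(lo < hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate FOV box: lower={self.lower} upper={self.upper}")

    @property
    def size(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)


@dataclass(frozen=True)
class NormalizationRecord:
    """Constants of the two-stage intensity map, stored for inversion.

    mu, sigma: mean/std of the raw image (z-score stage);
    m, d: midpoint and half-range of the z-scored image (range stage).
    """

    mu: float
    sigma: float
    m: float
    d: float

    def __post_init__(self):
        if not (self.sigma > 0 and self.d > 0):
            raise ValueError("sigma and d must be positive")


@dataclass
class PairedSample:
    """Co-registered MR and CT of one subject, plus their normalization records."""

    subject_id: str
    mr: Volume
    ct: Volume
    mr_norm: NormalizationRecord | None = None
    ct_norm: NormalizationRecord | None = None

    def validate_grids(self) -> None:
        if self.mr.shape != self.ct.shape:
            raise ValueError(f"grid mismatch: {self.mr.shape} vs {self.ct.shape}")
        if not np.allclose(self.mr.spacing, self.ct.spacing, atol=1e-9):
            raise ValueError("spacing mismatch between MR and CT")
        if not np.allclose(self.mr.origin, self.ct.origin, atol=1e-9):
            raise ValueError("origin mismatch between MR and CT")


def common_fov(mr: Volume, ct: Volume) -> FovBox:
    """Common field of view of a pair: the MR's physical bounding box.

    If the MR extent protrudes beyond the CT on some axis the box is clipped
    to the intersection and a warning is logged (the protruding voxels are
    abandoned downstream).
    """
    mr_lo, mr_hi = mr.extent()
    ct_lo, ct_hi = ct.extent()
    lo = np.maximum(mr_lo, ct_lo)
    hi = np.minimum(mr_hi, ct_hi)
    if np.any(lo >= hi):
        raise ValueError("MR and CT extents do not intersect")
    if np.any(lo > mr_lo + 1e-9) or np.any(hi < mr_hi - 1e-9):
        log.warning("MR FOV not contained in CT FOV; clipping to the intersection")
    return FovBox(lower=tuple(lo), upper=tuple(hi))


def crop_to_fov(vol: Volume, box: FovBox) -> Volume:
    """Keep exactly the voxels whose centers lie inside ``box`` (half-open)."""
    o = np.asarray(vol.origin)
    sp = np.asarray(vol.spacing)
    n = np.asarray(vol.shape)
    lo = np.asarray(box.lower)
    hi = np.asarray(box.upper)
    # voxel centers are at o + i*sp; keep lo <= center < hi (half-open box)
    # with a small absolute tolerance against float noise on the mm scale
    i0 = np.maximum(0, np.ceil((lo - o) / sp - 1e-6)).astype(int)
    i1 = np.minimum(n, np.floor((hi - o) / sp - 1e-6).astype(int) + 1)
    if np.any(i1 <= i0):
        raise ValueError("FOV box does not intersect the volume")
    data = vol.data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    return Volume(data=np.ascontiguousarray(data), spacing=vol.spacing,
                  origin=tuple(o + i0 * sp), meta=dict(vol.meta))


def _resample_to_box(vol: Volume, box: FovBox, target_shape, order=3) -> Volume:
    """Order-``order`` spline resampling onto a new grid of ``target_shape``
    voxels spanning ``box``.  Out-of-extent lookups clamp to the edge sample."""
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or min(target_shape) < 2:
        raise ValueError(f"target shape must be 3 values >= 2, got {target_shape}")
    new_sp = box.size / np.asarray(target_shape)
    lo = np.asarray(box.lower)
    o = np.asarray(vol.origin)
    sp = np.asarray(vol.spacing)
    # new voxel centers in input index coordinates
    axes = [(lo[a] + (np.arange(target_shape[a]) + 0.5) * new_sp[a] - o[a]) / sp[a]
            for a in range(3)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(vol.data, dtype=np.float64), coords,
                                  order=order, mode="nearest")
    return Volume(data=out, spacing=tuple(new_sp),
                  origin=tuple(lo + 0.5 * new_sp), meta=dict(vol.meta))


def resample(vol: Volume, target_shape, order: int = 3) -> Volume:
    """Resample a volume onto ``target_shape`` voxels over its own physical extent."""
    lo, hi = vol.extent()
    return _resample_to_box(vol, FovBox(tuple(lo), tuple(hi)), target_shape, order=order)


def normalize(img: Volume) -> tuple[Volume, NormalizationRecord]:
    """Two-stage intensity normalization onto exactly [-1, 1].

    Stage 1 (z-score):      img' = (img - mu) / sigma
    Stage 2 (range shift):  img'' = (img' - m) / d,
    with m the midpoint and d the half-range of img'.  The composition is the
    unique affine map sending min -> -1 and max -> +1; its constants are
    returned so :func:`denormalize` can invert it exactly.
    """
    data = np.asarray(img.data, dtype=np.float64)
    mu = float(data.mean())
    sigma = float(data.std())
    if sigma == 0:
        raise ValueError("constant image cannot be normalized (sigma = 0)")
    z = (data - mu) / sigma
    m = float((z.max() + z.min()) / 2.0)
    d = float((z.max() - z.min()) / 2.0)
    out = (z - m) / d
    rec = NormalizationRecord(mu=mu, sigma=sigma, m=m, d=d)
    return img.copy_with(data=out), rec


def denormalize(img: Volume, rec: NormalizationRecord) -> Volume:
    """Invert :func:`normalize`: img = mu + sigma * (d * img'' + m)."""
    data = rec.mu + rec.sigma * (rec.d * np.asarray(img.data, dtype=np.float64) + rec.m)
    return img.copy_with(data=data)


def preprocess_pair(mr_raw: Volume, ct_raw: Volume, target_shape,
                    subject_id: str = "subject") -> PairedSample:
    """Full preprocessing of one co-registered raw pair.

    common_fov -> crop (both) -> resample (both, onto the SAME grid spanning
    the common FOV) -> normalize (each image independently).
    """
    box = common_fov(mr_raw, ct_raw)
    mr_c = crop_to_fov(mr_raw, box)
    ct_c = crop_to_fov(ct_raw, box)
    mr_r = _resample_to_box(mr_c, box, target_shape)
    ct_r = _resample_to_box(ct_c, box, target_shape)
    mr_n, mr_rec = normalize(mr_r)
    ct_n, ct_rec = normalize(ct_r)
    sample = PairedSample(subject_id=subject_id, mr=mr_n, ct=ct_n,
                          mr_norm=mr_rec, ct_norm=ct_rec)
    sample.validate_grids()
    return sample
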