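"""NIfTI-1 volume reading and writing.

The only module that touches image files.  Volumes are held as plain
``(x, y, z)``-ordered numpy arrays plus voxel spacing and origin in mm;
files are reoriented to the closest RAS-like axis order on read and the
original orientation code is kept in ``Volume.meta``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

__all__ = ["Volume", "VolumeFormatError", "read_volume", "write_volume",
           "save_pair", "load_pair"]


class VolumeFormatError(ValueError):
    """Raised when a file on disk is not a usable 3D scalar image."""


@dataclass
class Volume:
    """A 3D scalar grid with geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, arbitrary units. Axis order is fixed as (x, y, z).
    spacing : tuple of 3 floats
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of 3 floats
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"volume data must be 3D with each axis >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive finite values, got {self.spacing}")
        if not all(np.isfinite(o) for o in self.origin):
            raise VolumeFormatError(f"origin must be finite, got {self.origin}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume intensities must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lower, upper) of the voxel-center model:
        half a voxel beyond the first/last centers on every axis."""
        o = np.asarray(self.origin, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        n = np.asarray(self.shape, dtype=float)
        return o - sp / 2.0, o + (n - 0.5) * sp

    def copy_with(self, data=None, spacing=None, origin=None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing if spacing is None else spacing,
            origin=self.origin if origin is None else origin,
            meta=dict(self.meta),
        )


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI-1 file (.nii or .nii.gz) into a :class:`Volume`.

    The image is reoriented to the closest canonical (RAS) axis order so the
    in-memory axis convention is always (x, y, z) with positive spacing; the
    original orientation string is stored in ``meta['orig_orientation']``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    orig_orientation = "".join(nib.aff2axcodes(img.affine))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, file has {data.ndim} dimensions {data.shape}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise VolumeFormatError(f"{path}: malformed affine, voxel spacing {spacing}")
    origin = tuple(float(v) for v in aff[:3, 3])
    vol = Volume(data=data, spacing=spacing, origin=origin)
    vol.meta["orig_orientation"] = orig_orientation
    return vol


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI-1; geometry goes into the affine."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_from_geometry(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - OS specific
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


# -- paired-sample container (HDF5) -----------------------------------------

def save_pair(sample, path) -> None:
    """Store a preprocessed pair (both arrays + normalization records) in HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = str(sample.subject_id)
        for name, vol, rec in (("mr", sample.mr, sample.mr_norm),
                               ("ct", sample.ct, sample.ct_norm)):
            g = f.create_group(name)
            g.create_dataset("data", data=vol.data)
            g.attrs["spacing"] = vol.spacing
            g.attrs["origin"] = vol.origin
            if rec is not None:
                g.attrs["norm_mu"] = rec.mu
                g.attrs["norm_sigma"] = rec.sigma
                g.attrs["norm_m"] = rec.m
                g.attrs["norm_d"] = rec.d


def load_pair(path):
    """Inverse of :func:`save_pair`."""
    from .preprocess import NormalizationRecord, PairedSample

    with h5py.File(path, "r") as f:
        vols, recs = {}, {}
        for name in ("mr", "ct"):
            g = f[name]
            vols[name] = Volume(data=g["data"][()],
                                spacing=tuple(g.attrs["spacing"]),
                                origin=tuple(g.attrs["origin"]))
            if "norm_mu" in g.attrs:
                recs[name] = NormalizationRecord(
                    mu=float(g.attrs["norm_mu"]), sigma=float(g.attrs["norm_sigma"]),
                    m=float(g.attrs["norm_m"]), d=float(g.attrs["norm_d"]))
            else:
                recs[name] = None
        return PairedSample(subject_id=f.attrs["subject_id"],
                            mr=vols["mr"], ct=vols["ct"],
                            mr_norm=recs["mr"], ct_norm=recs["ct"])
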