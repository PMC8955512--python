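"""Rotation-schedule data augmentation.

Each training epoch rotates every volume pair by one angle triple
(theta_x, theta_y, theta_z) in degrees.  Each angle is a fixed part drawn
from the eight values {1, -1, 3, -3, 5, -5, 7, -7} — enumerated
lexicographically over the three axes, z varying fastest, giving 8^3 = 512
distinct combinations per cycle — plus an independent uniform random jitter
in the open interval (-1, 1) redrawn every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import PairedSample
from .volume_io import Volume

__all__ = ["THETA_FIXED", "RotationSchedule", "fixed_triple", "draw_angles",
           "rotate_volume", "rotate_pair"]

THETA_FIXED: tuple[int, ...] = (1, -1, 3, -3, 5, -5, 7, -7)
CYCLE = len(THETA_FIXED) ** 3  # 512


@dataclass
class RotationSchedule:
    """Deterministic fixed-angle cycle plus seeded per-epoch jitter."""

    rng_seed: int = 0
    theta_f: tuple[int, ...] = THETA_FIXED
    epoch_counter: int = field(default=0)

    def fixed_triple(self, epoch: int) -> tuple[float, float, float]:
        return fixed_triple(epoch, self.theta_f)

    def draw_angles(self, epoch: int) -> tuple[float, float, float]:
        """Angles for ``epoch``: fixed triple + independent jitter per axis.

        Reproducible: the draw depends only on (rng_seed, epoch), not on
        call order.
        """
        fx, fy, fz = self.fixed_triple(epoch)
        rng = np.random.default_rng([int(self.rng_seed) & 0x7FFFFFFF, int(epoch)])
        r = rng.uniform(-1.0, 1.0, size=3)
        while np.any(np.abs(r) >= 1.0):  # keep the interval open, paranoia-cheap
            r = rng.uniform(-1.0, 1.0, size=3)
        return (fx + r[0], fy + r[1], fz + r[2])


def fixed_triple(epoch: int, theta_f: tuple[int, ...] = THETA_FIXED):
    """Fixed-part triple for ``epoch`` (modulo the 512-epoch cycle).

    Lexicographic enumeration over (i, j, k) with the z index varying
    fastest: epoch 0 -> (1, 1, 1), epoch 1 -> (1, 1, -1), ...,
    epoch 511 -> (-7, -7, -7).
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    n = len(theta_f)
    e = int(epoch) % (n ** 3)
    i, j, k = e // (n * n), (e // n) % n, e % n
    return (float(theta_f[i]), float(theta_f[j]), float(theta_f[k]))


def draw_angles(schedule: RotationSchedule, epoch: int):
    return schedule.draw_angles(epoch)


def _rotation_matrix(angles_deg) -> np.ndarray:
    """Intrinsic rotations applied in x-then-y-then-z order (R = Rz @ Ry @ Rx)."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate_volume(vol: Volume, angles_deg, fill: float = -1.0,
                  order: int = 1) -> Volume:
    """Rotate about the grid's geometric center, in physical (mm) space.

    Trilinear interpolation by default; voxels mapped from outside the input
    extent are filled with ``fill`` (-1 = air background after
    normalization).  Shape and geometry metadata are unchanged.
    """
    sp = np.asarray(vol.spacing, dtype=float)
    n = np.asarray(vol.shape, dtype=float)
    center = (n - 1) / 2.0  # index-space center
    r = _rotation_matrix(angles_deg)
    # output index -> input index: scale to mm, rotate backwards, scale back
    s = np.diag(sp)
    s_inv = np.diag(1.0 / sp)
    m = s_inv @ r.T @ s
    offset = center - m @ center
    out = ndimage.affine_transform(np.asarray(vol.data, dtype=np.float64), m,
                                   offset=offset, order=order, mode="constant",
                                   cval=fill)
    return vol.copy_with(data=out)


def rotate_pair(sample: PairedSample, angles_deg, fill: float = -1.0,
                order: int = 1) -> PairedSample:
    """Rotate MR and CT of a pair by the same angles (spatial equivariance)."""
    return PairedSample(subject_id=sample.subject_id,
                        mr=rotate_volume(sample.mr, angles_deg, fill=fill, order=order),
                        ct=rotate_volume(sample.ct, angles_deg, fill=fill, order=order),
                        mr_norm=sample.mr_norm, ct_norm=sample.ct_norm)
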