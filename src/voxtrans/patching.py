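"""Overlapping patch decomposition of the common grid.

The full grid is covered by five overlapping cubic patches — the four
in-plane corners plus one centered patch — each spanning the full z extent.
Per-voxel overlap counts are tracked so per-patch predictions can be merged
back by overlap-weighted averaging ("base map" accumulation followed by
division by the overlap count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["PatchLayout", "default_layout", "overlap_map",
           "extract_patch", "merge_patches"]


@dataclass(frozen=True)
class PatchLayout:
    """Placement of patches in the common grid.

    offsets are lower-corner voxel indices, in patch order p1..pN
    (1-based patch indices in the public API).
    """

    grid_shape: tuple[int, int, int]
    patch_shape: tuple[int, int, int]
    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        g = np.asarray(self.grid_shape)
        p = np.asarray(self.patch_shape)
        if np.any(p > g):
            raise ValueError(f"patch {self.patch_shape} exceeds grid {self.grid_shape}")
        for off in self.offsets:
            if np.any(np.asarray(off) < 0) or np.any(np.asarray(off) + p > g):
                raise ValueError(f"patch at offset {off} does not fit in grid {self.grid_shape}")
        cov = overlap_map(self)
        if cov.min() < 1:
            raise ValueError("patch union does not cover the grid")

    @property
    def n_patches(self) -> int:
        return len(self.offsets)

    def slices(self, index: int) -> tuple[slice, slice, slice]:
        """Index slices of patch ``index`` (1-based) in the grid."""
        off = self.offsets[self._check_index(index) - 1]
        return tuple(slice(o, o + s) for o, s in zip(off, self.patch_shape))

    def _check_index(self, index: int) -> int:
        if not 1 <= index <= self.n_patches:
            raise IndexError(f"patch index must be in 1..{self.n_patches}, got {index}")
        return index


def default_layout(grid_shape, patch_shape) -> PatchLayout:
    """Four in-plane corner patches plus a centered one (p3), full z extent.

    For the production grid (200, 200, 128) with 128^3 patches this yields
    offsets p1=(0,0,0), p2=(72,0,0), p3=(36,36,0), p4=(0,72,0), p5=(72,72,0).
    Degenerate axes (patch size == grid size) collapse; if the patch covers
    the whole plane a single patch is returned.
    """
    g = np.asarray(grid_shape, dtype=int)
    p = np.asarray(patch_shape, dtype=int)
    if np.any(p > g):
        raise ValueError(f"patch {tuple(p)} larger than grid {tuple(g)}")
    far = g - p  # flush-to-far-corner offset per axis
    center = (g - p) // 2
    offsets = [(0, 0, 0), (far[0], 0, 0), (center[0], center[1], 0),
               (0, far[1], 0), (far[0], far[1], 0)]
    if far[0] == 0 and far[1] == 0:
        offsets = [(0, 0, 0)] * 5  # degenerate: grid == patch in-plane
    if far[2] != 0:
        # z is never subdivided by this layout family; require full-z patches
        raise ValueError("default layout requires patch z extent == grid z extent")
    return PatchLayout(grid_shape=tuple(int(v) for v in g),
                       patch_shape=tuple(int(v) for v in p),
                       offsets=tuple(tuple(int(v) for v in o) for o in offsets))


def overlap_map(layout: PatchLayout) -> np.ndarray:
    """Integer per-voxel count of how many patches contain each voxel."""
    counts = np.zeros(layout.grid_shape, dtype=np.int32)
    p = layout.patch_shape
    for off in layout.offsets:
        counts[off[0]:off[0] + p[0], off[1]:off[1] + p[1], off[2]:off[2] + p[2]] += 1
    return counts


def extract_patch(vol: Volume, layout: PatchLayout, index: int) -> Volume:
    """Sub-volume of patch ``index`` (1-based); geometry metadata updated."""
    if vol.shape != layout.grid_shape:
        raise ValueError(f"volume shape {vol.shape} != layout grid {layout.grid_shape}")
    sl = layout.slices(index)
    off = layout.offsets[index - 1]
    origin = tuple(o + i * s for o, i, s in zip(vol.origin, off, vol.spacing))
    return Volume(data=np.ascontiguousarray(vol.data[sl]), spacing=vol.spacing,
                  origin=origin, meta=dict(vol.meta))


def merge_patches(preds, layout: PatchLayout, grid_spacing=(1.0, 1.0, 1.0),
                  grid_origin=(0.0, 0.0, 0.0)) -> Volume:
    """Merge per-patch predictions into one full-grid volume.

    A zero "base map" accumulates each prediction at its patch offsets; every
    voxel is then divided by its overlap count, i.e. overlapping predictions
    are averaged.
    """
    if len(preds) != layout.n_patches:
        raise ValueError(f"expected {layout.n_patches} predictions, got {len(preds)}")
    base = np.zeros(layout.grid_shape, dtype=np.float64)
    for i, pred in enumerate(preds, start=1):
        arr = pred.data if isinstance(pred, Volume) else np.asarray(pred)
        if arr.shape != layout.patch_shape:
            raise ValueError(
                f"prediction {i} has shape {arr.shape}, expected {layout.patch_shape}")
        base[layout.slices(i)] += arr
    base /= overlap_map(layout)
    first = preds[0]
    if isinstance(first, Volume):
        grid_spacing = first.spacing
        grid_origin = tuple(o - i * s for o, i, s in
                            zip(first.origin, layout.offsets[0], first.spacing))
    return Volume(data=base, spacing=grid_spacing, origin=grid_origin)
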