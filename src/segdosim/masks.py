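"""Geometric measurements on 3D binary lesion masks.

A contour read is represented as a :class:`VoxelMask`: a binary occupancy
array on a regular grid with physical voxel spacing in mm. By convention the
third array axis is the slice (axial) direction; this matters only for the
RECIST diameter, which is measured within a single axial plane.

All functions operate on in-memory masks; NIfTI round-tripping lives in
:mod:`segdosim.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclass(frozen=True)
class VoxelMask:
    """Binary occupancy on a regular 3D grid.

    Parameters
    ----------
    occupancy : ndarray of bool, shape (nx, ny, nz)
        True where the voxel belongs to the lesion.
    spacing_mm : tuple of float
        Physical voxel size (dx, dy, dz) in mm, all positive.
    axial_axis : int
        Array axis running across slices; the axial plane is spanned by the
        other two axes. Default 2 (third axis = slice direction).
    """

    occupancy: np.ndarray
    spacing_mm: tuple[float, float, float]
    axial_axis: int = 2

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("occupancy values must be binary {0,1}")
            occ = occ.astype(bool)
        object.__setattr__(self, "occupancy", occ)
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three positive components")
        object.__setattr__(self, "spacing_mm", sp)
        if self.axial_axis not in (0, 1, 2):
            raise ValueError("axial_axis must be 0, 1 or 2")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    def same_grid(self, other: "VoxelMask") -> bool:
        return self.occupancy.shape == np.shape(other.occupancy) and np.allclose(
            self.spacing_mm, other.spacing_mm
        )


@dataclass
class ReadRecord:
    """One contouring event: a (lesion, reader, round) triple and its mask.

    ``round`` is a 1-based session index. Derived measurements (volume in mL,
    RECIST diameter in mm) are filled at construction time by the cohort
    generator or the manifest loader.
    """

    lesion_id: str
    reader_id: str
    round: int
    volume_ml: float
    diameter_mm: float
    mask: Optional[VoxelMask] = field(default=None, repr=False)

    def __post_init__(self):
        if self.round < 1:
            raise ValueError("round is 1-based, got %r" % (self.round,))
        if self.volume_ml < 0:
            raise ValueError("volume_ml must be non-negative")


def mask_volume(mask: VoxelMask) -> float:
    """Volume of a mask in mL (voxel count x voxel volume / 1000).

    An empty mask returns 0.0 and emits a warning: downstream pairing and
    summary stages reject zero-volume reads, but volume itself is defined.
    """
    n = mask.n_voxels
    if n == 0:
        warnings.warn("empty mask: volume is 0 mL", stacklevel=2)
        return 0.0
    return n * mask.voxel_volume_mm3 / 1000.0


def dice_coefficient(mask_a: VoxelMask, mask_b: VoxelMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two masks on a shared grid.

    Raises
    ------
    GridMismatchError
        If shapes or spacings differ.
    ValueError
        If both masks are empty (the coefficient is undefined).
    """
    if not mask_a.same_grid(mask_b):
        raise GridMismatchError("masks not on common grid")
    a = mask_a.occupancy
    b = mask_b.occupancy
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def _slice_points_mm(mask: VoxelMask, k: int) -> np.ndarray:
    """In-plane physical coordinates (mm) of occupied voxel centers in slice k."""
    ax = mask.axial_axis
    sl = np.take(mask.occupancy, k, axis=ax)
    idx = np.argwhere(sl)
    in_plane_axes = [a for a in range(3) if a != ax]
    sp = np.array([mask.spacing_mm[a] for a in in_plane_axes])
    return idx * sp


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a 2D point set; convex hull first, all pairs on the hull."""
    n = len(points)
    if n < 2:
        return 0.0
    pts = points
    if n > 3:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except QhullError:
            # collinear / degenerate slice: fall back to the raw points
            pts = points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def recist_diameter(mask: VoxelMask) -> float:
    """Longest in-plane (axial) diameter in mm.

    The maximum over axial slices of the maximum pairwise distance between
    occupied-voxel centers within that slice. Distances are voxel-center to
    voxel-center, so the result underestimates a caliper (edge-to-edge)
    measurement by at most about one voxel.
    """
    if mask.n_voxels == 0:
        raise ValueError("RECIST diameter undefined for an empty mask")
    nslices = mask.occupancy.shape[mask.axial_axis]
    best = 0.0
    for k in range(nslices):
        pts = _slice_points_mm(mask, k)
        if len(pts) >= 2:
            best = max(best, _max_pairwise_distance(pts))
    return best
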