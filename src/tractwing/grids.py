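"""Voxel grids, masks and analytic ROIs in MNI millimetre space.

All volumes in this package live on an axis-aligned RAS grid with an
invertible voxel-index -> mm affine. Voxel centers sit at integer indices;
a mm point belongs to the voxel whose (continuous) index rounds to it,
with half-integer ties rounded away from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Mask",
    "SphereROI",
    "default_analysis_grid",
    "read_nifti",
    "write_nifti",
    "rasterize_sphere",
    "center_of_gravity",
    "average_masks",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class VoxelGrid:
    """A 3-D scalar lattice with an invertible voxel->mm affine (RAS mm).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; densities and masks are non-negative.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> mm transform. Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("singular affine")
        self._inv = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices (..., 3) to mm coordinates."""
        idx = np.asarray(idx, dtype=np.float64)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to continuous voxel indices."""
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self._inv[:3, :3].T + self._inv[:3, 3]

    def mm_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates to the integer index of the containing voxel."""
        return _round_half_away(self.mm_to_voxel(pts)).astype(np.int64)

    def inside(self, idx: np.ndarray) -> np.ndarray:
        """Boolean: which integer indices (..., 3) fall inside the lattice."""
        idx = np.asarray(idx)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)

    def same_grid(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def empty_like(self) -> "VoxelGrid":
        return VoxelGrid(np.zeros(self.shape), self.affine.copy())

    def index_coords_mm(self) -> np.ndarray:
        """mm coordinates of every voxel center, shape (*shape, 3)."""
        ii = np.indices(self.shape).reshape(3, -1).T.astype(np.float64)
        return self.voxel_to_mm(ii).reshape(*self.shape, 3)


def default_analysis_grid(spacing: float = 1.0) -> VoxelGrid:
    """The default 1 mm isotropic MNI analysis box.

    Covers x in [-40, 40], y in [-80, 20], z in [-50, 30] mm, which contains
    the rubral wing, red nucleus, VIM, both superior cerebellar peduncles,
    the decussation and a precentral-gyrus block.
    """
    lo = np.array([-40.0, -80.0, -50.0])
    hi = np.array([40.0, 20.0, 30.0])
    shape = tuple((_round_half_away((hi - lo) / spacing)).astype(int) + 1)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = lo
    return VoxelGrid(np.zeros(shape), affine)


@dataclass
class Mask:
    """A binary or probability mask on a :class:`VoxelGrid`.

    ``kind='binary'`` requires values in {0, 1}; ``kind='probability'``
    requires values in [0, 1]. Probability masks keep native float values —
    no implicit binarization anywhere.
    """

    grid: VoxelGrid
    kind: str = "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "probability"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        d = self.grid.data
        if self.kind == "binary":
            if not np.all(np.isin(np.unique(d), [0.0, 1.0])):
                raise ValueError("binary mask must contain only {0, 1}")
        else:
            if d.min() < 0 or d.max() > 1 + 1e-9:
                raise ValueError("probability mask values must lie in [0, 1]")

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    def total_mass(self) -> float:
        return float(self.data.sum())

    def volume_mm3(self) -> float:
        """Mass-weighted volume: voxel count (binary) or total probability
        mass (probability), times the voxel volume. No Jacobian modulation."""
        vox_vol = float(np.prod(self.grid.voxel_sizes))
        return self.total_mass() * vox_vol

    def binarize(self, threshold: float) -> "Mask":
        g = VoxelGrid((self.data >= threshold).astype(float), self.affine.copy())
        return Mask(g, kind="binary")


@dataclass(frozen=True)
class SphereROI:
    """A spherical region of interest: center in mm (MNI RAS), radius in mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean membership test for mm points, shape (..., 3)."""
        pts = np.asarray(pts, dtype=np.float64)
        d2 = ((pts - np.asarray(self.center)) ** 2).sum(axis=-1)
        return d2 <= self.radius**2

    def mirrored(self) -> "SphereROI":
        cx, cy, cz = self.center
        return SphereROI((-cx, cy, cz), self.radius)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path) -> VoxelGrid:
    """Load a 3-D NIfTI volume, reoriented to closest RAS canonical axes."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: missing or singular affine")
    return VoxelGrid(np.asarray(data, dtype=np.float64), np.asarray(affine))


def write_nifti(grid: VoxelGrid | Mask, path) -> None:
    """Write a grid (or mask) as NIfTI-1, float32 on disk."""
    if isinstance(grid, Mask):
        grid = grid.grid
    img = nib.Nifti1Image(grid.data.astype(np.float32), grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Operations


def rasterize_sphere(roi: SphereROI, like: VoxelGrid) -> Mask:
    """Binary mask of voxels whose centers lie within ``roi``.

    A voxel is included iff the Euclidean distance from its center (in mm)
    to the sphere center is <= radius. Spheres entirely outside the grid
    yield an empty mask with a warning.
    """
    out = like.empty_like()
    # bounding box in voxel space to avoid scanning the whole lattice
    c_vox = like.mm_to_voxel(np.asarray(roi.center))
    r_vox = roi.radius / like.voxel_sizes.min() + 1.0
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1, np.array(like.shape))
    if np.any(lo >= hi):
        warnings.warn("sphere lies entirely outside the grid; empty mask")
        return Mask(out, kind="binary")
    ii = np.stack(
        np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij"),
        axis=-1,
    )
    mm = like.voxel_to_mm(ii.reshape(-1, 3))
    hit = roi.contains(mm).reshape(ii.shape[:3])
    out.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = hit.astype(float)
    if not hit.any():
        warnings.warn("sphere lies entirely outside the grid; empty mask")
    return Mask(out, kind="binary")


def center_of_gravity(mask: Mask | VoxelGrid) -> np.ndarray:
    """Mass-weighted mean of voxel-center mm coordinates.

    Weights are the mask/grid values, so probability masks are supported.
    Raises on empty masks.
    """
    grid = mask.grid if isinstance(mask, Mask) else mask
    w = grid.data
    total = w.sum()
    if total <= 0:
        raise ValueError("empty mask")
    idx = np.argwhere(w != 0).astype(np.float64)
    weights = w[w != 0]
    mm = grid.voxel_to_mm(idx)
    return (mm * weights[:, None]).sum(axis=0) / total


def average_masks(masks: list[Mask]) -> Mask:
    """Voxel-wise arithmetic mean of delineations on a common grid.

    Binary inputs average to a probability map (the group-mean mask).
    Values are averaged as loaded; no binarization or interpolation.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    ref = masks[0].grid
    for m in masks[1:]:
        if not ref.same_grid(m.grid):
            raise ValueError("masks are not on the same grid")
    mean = np.mean([m.data for m in masks], axis=0)
    return Mask(VoxelGrid(mean, ref.affine.copy()), kind="probability")
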