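"""Slice-wise tract-tightness and overlap statistics along an MNI axis.

For each axial (xy) slice of a streamline density volume we compute

* the maximum streamline density within the slice,
* the Shannon entropy H of the slice after normalizing it to total mass 1,
  in nats, and the inverse diversity exp(-H) — the reciprocal perplexity.
  exp(-H) is 1 when all slice mass sits in a single voxel (a perfect
  bottleneck) and 1/n when spread uniformly over n voxels, so local maxima
  of the profile mark funnel points of a bundle (superior cerebellar
  peduncle, decussation, rubral wing).

Natural logarithm is used throughout so that exp(-H) is exactly the
reciprocal perplexity. Empty slices get inverse diversity 0 (not 1) so
support gaps never masquerade as bottlenecks; they are flagged in the
profile.

Slice-wise cosine similarity between a density and a reference nucleus
mask normalizes both slice vectors to unit Euclidean norm and takes their
inner product: 1 means proportional slices, 0 disjoint support. Slices
where either vector vanishes are undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .grids import Mask, VoxelGrid

__all__ = [
    "SliceProfile",
    "SimilarityProfile",
    "slice_entropy",
    "inverse_diversity_profile",
    "find_bottlenecks",
    "cosine_profile",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def _check_axis_aligned(grid: VoxelGrid) -> None:
    off = grid.affine[:3, :3].copy()
    np.fill_diagonal(off, 0.0)
    if np.abs(off).max() > 1e-6:
        raise ValueError("volume must be axis-aligned to MNI for slicing")


def _slice_coords(grid: VoxelGrid, ax: int) -> np.ndarray:
    n = grid.shape[ax]
    idx = np.zeros((n, 3))
    idx[:, ax] = np.arange(n)
    return grid.voxel_to_mm(idx)[:, ax]


@dataclass
class SliceProfile:
    """Per-slice bottleneck statistics along one grid axis."""

    axis: str
    slice_coords: np.ndarray  # mm position of each slice center
    max_density: np.ndarray
    entropy_nats: np.ndarray  # NaN on empty slices
    inverse_diversity: np.ndarray  # 0 on empty slices
    n_nonzero: np.ndarray

    @property
    def spacing(self) -> float:
        return float(np.diff(self.slice_coords).mean())


@dataclass
class SimilarityProfile:
    """Per-slice cosine similarity with one or more reference structures."""

    axis: str
    slice_coords: np.ndarray
    cosine: dict[str, np.ndarray]  # name -> per-slice values, NaN if undefined


def slice_entropy(density_slice: np.ndarray) -> float:
    """Shannon entropy (nats) of a slice normalized to total mass 1.

    0 * ln 0 := 0. Raises on negative values or an empty (all-zero) slice.
    """
    s = np.asarray(density_slice, dtype=np.float64).ravel()
    if np.any(s < 0):
        raise ValueError("slice contains negative values")
    total = s.sum()
    if total == 0:
        raise ValueError("empty slice: entropy undefined")
    p = s[s > 0] / total
    return float(-(p * np.log(p)).sum())


def inverse_diversity_profile(density: VoxelGrid, axis: str = "z") -> SliceProfile:
    """Per-slice max density, entropy and inverse diversity exp(-H)."""
    _check_axis_aligned(density)
    if np.any(density.data < 0):
        raise ValueError("density must be non-negative")
    if density.data.sum() == 0:
        raise ValueError("all-empty volume")
    ax = _AXES[axis]
    n = density.shape[ax]
    max_d = np.zeros(n)
    ent = np.full(n, np.nan)
    inv_div = np.zeros(n)
    nnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        sl = np.take(density.data, k, axis=ax)
        max_d[k] = sl.max()
        nnz[k] = int((sl > 0).sum())
        if sl.sum() > 0:
            h = slice_entropy(sl)
            ent[k] = h
            inv_div[k] = np.exp(-h)
    return SliceProfile(
        axis=axis,
        slice_coords=_slice_coords(density, ax),
        max_density=max_d,
        entropy_nats=ent,
        inverse_diversity=inv_div,
        n_nonzero=nnz,
    )


def find_bottlenecks(
    profile: SliceProfile,
    min_prominence: float = 0.05,
    min_separation_mm: float = 5.0,
) -> np.ndarray:
    """Positions (mm) of bottleneck peaks in the inverse-diversity profile.

    Local maxima with prominence >= ``min_prominence`` and mutual distance
    >= ``min_separation_mm``, sorted by ascending coordinate. May be empty
    (e.g. for a flat profile).
    """
    y = profile.inverse_diversity
    distance = max(int(np.ceil(min_separation_mm / profile.spacing)), 1)
    peaks, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    return np.sort(profile.slice_coords[peaks])


def cosine_profile(
    density: VoxelGrid,
    references: Mask | dict[str, Mask],
    axis: str = "z",
) -> SimilarityProfile:
    """Slice-wise cosine similarity of a density with reference structures.

    Each slice of the density and of the reference is scaled to unit
    Euclidean norm and the two are multiplied point-wise and summed. For
    non-negative inputs values lie in [0, 1]; 1 only for proportional
    non-zero slices. Slices where either vector is all-zero are NaN.
    """
    _check_axis_aligned(density)
    if isinstance(references, Mask):
        references = {"reference": references}
    ax = _AXES[axis]
    n = density.shape[ax]
    out: dict[str, np.ndarray] = {}
    for name, ref in references.items():
        if not density.same_grid(ref.grid):
            raise ValueError(f"reference {name!r} is not on the density grid")
        if np.any(density.data < 0) or np.any(ref.data < 0):
            raise ValueError("cosine profile requires non-negative inputs")
        cos = np.full(n, np.nan)
        for k in range(n):
            d = np.take(density.data, k, axis=ax).ravel()
            r = np.take(ref.data, k, axis=ax).ravel()
            nd, nr = np.linalg.norm(d), np.linalg.norm(r)
            if nd == 0 or nr == 0:
                continue
            cos[k] = float(d @ r / (nd * nr))
        out[name] = cos
    return SimilarityProfile(
        axis=axis, slice_coords=_slice_coords(density, ax), cosine=out
    )
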