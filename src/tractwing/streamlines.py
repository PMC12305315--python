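"""Tractogram container, TRK/TCK I/O, resampling, and density maps.

Coordinates are always RAS mm (MNI convention). File I/O goes through
nibabel's streamlines API, which converts TRK voxel-order points to RAS mm
using the header transform on load.

Visitation densities count each streamline at most once per voxel, making
the map a streamline-count measure (a flag switches to per-point counting
for comparison). Streamlines are resampled at half the voxel spacing before
binning so straight segments cannot skip voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VoxelGrid

__all__ = [
    "Tractogram",
    "read_tractogram",
    "write_tractogram",
    "resample_streamline",
    "arc_length",
    "density_map",
    "terminal_map",
    "ratio_map",
]


def _validate_streamline(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("a streamline needs >= 2 points of dimension 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """An ordered set of 3-D polylines in mm with space metadata.

    ``space_tag`` must be ``"MNI-mm"`` before any voxel-space operation;
    ``labels`` optionally tags each streamline (e.g. planted bundle names).
    """

    streamlines: list[np.ndarray]
    space_tag: str = "MNI-mm"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.streamlines = [_validate_streamline(s) for s in self.streamlines]
        if self.labels is not None and len(self.labels) != len(self.streamlines):
            raise ValueError("labels length must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def check_space(self) -> None:
        if self.space_tag != "MNI-mm":
            raise ValueError(
                f"tractogram space is {self.space_tag!r}; voxel-space "
                "operations require 'MNI-mm'"
            )

    def subset(self, indices) -> "Tractogram":
        idx = list(indices)
        return Tractogram(
            [self.streamlines[i] for i in idx],
            space_tag=self.space_tag,
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


def read_tractogram(path) -> Tractogram:
    """Read a TCK or TRK file; points are returned in RAS mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header/format errors
        raise ValueError(f"{path}: cannot parse tractogram ({exc})") from exc
    sls = [np.asarray(s, dtype=np.float64) for s in tfile.streamlines]
    if len(sls) == 0:
        return Tractogram([np.zeros((2, 3))][:0], space_tag="MNI-mm")
    return Tractogram(sls, space_tag="MNI-mm")


def write_tractogram(tg: Tractogram, path) -> None:
    """Write TCK or TRK (chosen by extension); coordinates stored as RAS mm."""
    path = Path(path)
    nt = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tg.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".tck":
        nib.streamlines.save(nt, str(path))
    elif path.suffix == ".trk":
        nib.streamlines.save(nt, str(path))
    else:
        raise ValueError(f"unknown tractogram format {path.suffix!r}")


def arc_length(points: np.ndarray) -> float:
    """Polyline arc length (sum of segment lengths), mm."""
    pts = np.asarray(points, dtype=np.float64)
    return float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (at most) ``step`` mm between points.

    Output points lie exactly on the input polyline; both endpoints are
    preserved; consecutive output points are <= step apart. Original
    vertices are retained, so the arc length is preserved exactly.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pts = _validate_streamline(points)
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return pts[[0, -1]].copy()
    n_seg = max(int(np.ceil(total / step)), 1)
    t = np.union1d(np.linspace(0.0, total, n_seg + 1), cum)
    out = np.column_stack([np.interp(t, cum, pts[:, k]) for k in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _visited_flat_indices(
    points: np.ndarray, like: VoxelGrid, step: float
) -> np.ndarray:
    """Flat voxel indices visited by one streamline (unique, inside grid)."""
    rs = resample_streamline(points, step)
    idx = like.mm_to_index(rs)
    ok = like.inside(idx)
    if not ok.any():
        return np.empty(0, dtype=np.int64)
    idx = idx[ok]
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), like.shape)
    return np.unique(flat)


def density_map(
    tg: Tractogram,
    like: VoxelGrid,
    step: float | None = None,
    count_per_point: bool = False,
) -> VoxelGrid:
    """Streamline visitation-count map.

    Each voxel holds the number of distinct streamlines that visit it
    (default) or, with ``count_per_point=True``, the raw resampled-point
    count. Streamlines are resampled at ``step`` (default: half the minimum
    voxel spacing) before binning.
    """
    tg.check_space()
    if len(tg) == 0:
        raise ValueError("empty tractogram")
    if step is None:
        step = 0.5 * float(like.voxel_sizes.min())
    out = like.empty_like()
    flat_out = out.data.reshape(-1)
    for sl in tg.streamlines:
        if count_per_point:
            rs = resample_streamline(sl, step)
            idx = like.mm_to_index(rs)
            ok = like.inside(idx)
            if not ok.any():
                continue
            idx = idx[ok]
            flat = np.ravel_multi_index(
                (idx[:, 0], idx[:, 1], idx[:, 2]), like.shape
            )
        else:
            flat = _visited_flat_indices(sl, like, step)
        np.add.at(flat_out, flat, 1.0)
    return out


def terminal_map(tg: Tractogram, like: VoxelGrid) -> VoxelGrid:
    """Streamline endpoint (terminal) map.

    Only the first and last point of each streamline increment a voxel, so
    total mass is 2 x n_streamlines when all endpoints fall inside the grid.
    Endpoints outside the grid are dropped with a counted warning. No
    Jacobian modulation is applied when such maps are later averaged.
    """
    tg.check_space()
    if len(tg) == 0:
        raise ValueError("empty tractogram")
    ends = np.array([[s[0], s[-1]] for s in tg.streamlines]).reshape(-1, 3)
    idx = like.mm_to_index(ends)
    ok = like.inside(idx)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} streamline endpoint(s) fell outside the grid")
    out = like.empty_like()
    idx = idx[ok]
    np.add.at(out.data, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return out


def ratio_map(
    a: VoxelGrid, b: VoxelGrid, epsilon: float = 1.0, log2: bool = False
) -> VoxelGrid:
    """Voxel-wise regularized ratio (a + eps) / (b + eps) of two densities.

    With ``log2=True`` the map is returned in log2 units (0 where a == b),
    the usual scale for comparing terminal densities between two selection
    strategies.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not a.same_grid(b):
        raise ValueError("grids do not match")
    r = (a.data + epsilon) / (b.data + epsilon)
    if log2:
        r = np.log2(r)
    return VoxelGrid(r, a.affine.copy())
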