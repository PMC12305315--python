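"""Waypoint-based bundle selection for the dentato-rubro-thalamic tract.

Two selection families are implemented:

* ``select_rw_drt`` — keep streamlines visiting the rubral-wing probability
  mask at a threshold (default 0.6) and disambiguate crossed from uncrossed
  fibers with the ipsi-/contralateral superior cerebellar peduncle (SCP)
  sphere (centers (+/-7, -41, -26) mm, radius 4 mm).
* ``select_classical_drt`` — the classical definition: precentral gyrus
  (PCG) terminus plus SCP waypoint (``drt_pcg_scp``), or red nucleus plus
  SCP with the cortical constraint dropped (``drt_rn_scp``).

PCG "connectivity" is an endpoint condition (endpoint inside the PCG mask
dilated by one voxel), not mere passage, so u-fibers grazing the gyrus do
not qualify. Streamlines visiting both SCP spheres are labelled
``unresolved`` and excluded from both bundles by default; a flag reassigns
them by whichever sphere is visited first along the streamline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Mask, SphereROI
from .streamlines import Tractogram, resample_streamline

__all__ = [
    "SCP_LEFT",
    "SCP_RIGHT",
    "SelectionSpec",
    "SelectionResult",
    "visits",
    "visits_sphere",
    "select_rw_drt",
    "select_classical_drt",
]

SCP_LEFT = SphereROI((-7.0, -41.0, -26.0), 4.0)
SCP_RIGHT = SphereROI((7.0, -41.0, -26.0), 4.0)


@dataclass(frozen=True)
class SelectionSpec:
    """Provenance record of a selection run."""

    variant: str
    hemisphere: str
    threshold: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.variant not in (
            "rw_drt",
            "drt_pcg_scp",
            "drt_rn_scp",
            "unconstrained_rw",
        ):
            raise ValueError(f"unknown selection variant {self.variant!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.threshold is not None and not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Selected streamline indices with per-streamline crossing labels."""

    indices: np.ndarray
    crossed_flag: list[str]  # 'crossed' | 'uncrossed' | 'unresolved'
    provenance: SelectionSpec

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")
        if len(self.crossed_flag) != len(self.indices):
            raise ValueError("crossed_flag length mismatch")

    def indices_with_flag(self, flag: str) -> np.ndarray:
        keep = [i for i, f in zip(self.indices, self.crossed_flag) if f == flag]
        return np.asarray(keep, dtype=np.int64)


def _resampled(sl: np.ndarray, spacing: float) -> np.ndarray:
    return resample_streamline(sl, 0.5 * spacing)


def visits(sl: np.ndarray, mask: Mask, threshold: float, step: float | None = None) -> bool:
    """True iff any resampled point of ``sl`` falls in a voxel whose mask
    value is >= threshold (inclusive convention)."""
    spacing = float(mask.grid.voxel_sizes.min())
    pts = resample_streamline(sl, step if step is not None else 0.5 * spacing)
    idx = mask.grid.mm_to_index(pts)
    ok = mask.grid.inside(idx)
    if not ok.any():
        return False
    idx = idx[ok]
    return bool(np.any(mask.data[idx[:, 0], idx[:, 1], idx[:, 2]] >= threshold))


def visits_sphere(sl: np.ndarray, roi: SphereROI, step: float = 0.5) -> bool:
    """True iff any resampled point of ``sl`` lies inside the sphere (mm test)."""
    pts = resample_streamline(sl, step)
    return bool(roi.contains(pts).any())


def _first_sphere_visited(
    sl: np.ndarray, a: SphereROI, b: SphereROI, step: float = 0.5
) -> str:
    pts = resample_streamline(sl, step)
    in_a = np.flatnonzero(a.contains(pts))
    in_b = np.flatnonzero(b.contains(pts))
    if in_a.size and (not in_b.size or in_a[0] < in_b[0]):
        return "a"
    if in_b.size:
        return "b"
    return "none"


def _scp_pair(side: str) -> tuple[SphereROI, SphereROI]:
    """(ipsilateral, contralateral) SCP spheres for a bundle on ``side``.

    Laterality of a sphere is the sign of its center's x coordinate.
    """
    if side == "left":
        return SCP_LEFT, SCP_RIGHT
    return SCP_RIGHT, SCP_LEFT


def select_rw_drt(
    tg: Tractogram,
    rw_prob: Mask,
    side: str,
    threshold: float = 0.6,
    scp_ipsi: SphereROI | None = None,
    scp_contra: SphereROI | None = None,
    reassign_unresolved_by_first_visit: bool = False,
) -> SelectionResult:
    """Select the rubral-wing DRT bundle and label crossing.

    Streamlines visiting the RW probability mask at ``threshold`` are kept.
    A kept streamline is ``crossed`` if it visits the SCP sphere
    contralateral to the RW side, ``uncrossed`` if ipsilateral, and
    ``unresolved`` if it visits neither or both.
    """
    tg.check_space()
    spec = SelectionSpec(variant="rw_drt", hemisphere=side, threshold=threshold)
    ipsi, contra = _scp_pair(side)
    if scp_ipsi is not None:
        ipsi = scp_ipsi
    if scp_contra is not None:
        contra = scp_contra
    spacing = float(rw_prob.grid.voxel_sizes.min())

    keep: list[int] = []
    flags: list[str] = []
    for i, sl in enumerate(tg.streamlines):
        pts = _resampled(sl, spacing)
        idx = rw_prob.grid.mm_to_index(pts)
        ok = rw_prob.grid.inside(idx)
        if not ok.any():
            continue
        vals = rw_prob.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        if not np.any(vals >= threshold):
            continue
        hit_c = contra.contains(pts).any()
        hit_i = ipsi.contains(pts).any()
        if hit_c and not hit_i:
            flag = "crossed"
        elif hit_i and not hit_c:
            flag = "uncrossed"
        elif hit_c and hit_i and reassign_unresolved_by_first_visit:
            first = _first_sphere_visited(sl, contra, ipsi)
            flag = "crossed" if first == "a" else "uncrossed"
        else:
            flag = "unresolved"
        keep.append(i)
        flags.append(flag)
    if not keep:
        warnings.warn("rw_drt selection is empty")
    return SelectionResult(np.asarray(keep, dtype=np.int64), flags, spec)


def _endpoint_in_dilated(sl: np.ndarray, mask_bool: np.ndarray, mask: Mask) -> bool:
    ends = np.array([sl[0], sl[-1]])
    idx = mask.grid.mm_to_index(ends)
    ok = mask.grid.inside(idx)
    if not ok.any():
        return False
    idx = idx[ok]
    return bool(mask_bool[idx[:, 0], idx[:, 1], idx[:, 2]].any())


def select_classical_drt(
    tg: Tractogram,
    variant: str,
    side: str,
    crossed: bool,
    pcg: Mask | None = None,
    rn: Mask | None = None,
    scp_ipsi: SphereROI | None = None,
    scp_contra: SphereROI | None = None,
    rn_threshold: float = 0.5,
) -> SelectionResult:
    """Classical DRT selection: conjunction of the variant's waypoints.

    ``drt_pcg_scp`` requires a streamline endpoint in the one-voxel-dilated
    PCG mask and a visit to the SCP sphere (contralateral if ``crossed``
    else ipsilateral). ``drt_rn_scp`` drops the cortical constraint and
    requires a red-nucleus visit plus the SCP visit.
    """
    tg.check_space()
    if variant not in ("drt_pcg_scp", "drt_rn_scp"):
        raise ValueError(f"unknown classical variant {variant!r}")
    spec = SelectionSpec(variant=variant, hemisphere=side)
    ipsi, contra = _scp_pair(side)
    if scp_ipsi is not None:
        ipsi = scp_ipsi
    if scp_contra is not None:
        contra = scp_contra
    scp = contra if crossed else ipsi
    flag = "crossed" if crossed else "uncrossed"

    if variant == "drt_pcg_scp":
        if pcg is None:
            raise ValueError("drt_pcg_scp requires a PCG mask")
        pcg_dil = ndimage.binary_dilation(pcg.data > 0)
        spacing = float(pcg.grid.voxel_sizes.min())
    else:
        if rn is None:
            raise ValueError("drt_rn_scp requires a red-nucleus mask")
        spacing = float(rn.grid.voxel_sizes.min())

    keep: list[int] = []
    for i, sl in enumerate(tg.streamlines):
        if not visits_sphere(sl, scp, step=0.5 * spacing):
            continue
        if variant == "drt_pcg_scp":
            if not _endpoint_in_dilated(sl, pcg_dil, pcg):
                continue
        else:
            if not visits(sl, rn, rn_threshold):
                continue
        keep.append(i)
    if not keep:
        warnings.warn(f"{variant} selection is empty")
    return SelectionResult(
        np.asarray(keep, dtype=np.int64), [flag] * len(keep), spec
    )
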