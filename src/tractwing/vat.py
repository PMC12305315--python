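"""Volume of activated tissue (VAT) model and stimulation-outcome analysis.

The VAT of a DBS contact is modelled as a sphere whose radius is calibrated
so that 1 mA of stimulation current activates tissue out to 2 mm:

    r(I) = 2 mm * (I / 1 mA) ** q

with scaling exponent q = 0.5 by default (square-root falloff of a point
source); any admissible exponent keeps r(1 mA) = 2 mm exactly.

Activation measures per contact: the mean crossed/uncrossed DRT streamline
density within the VAT, and the relative overlay of the VAT with the
probability-weighted rubral-wing mask. The overlay denominator defaults to
the total RW probability mass (fraction of the RW covered); normalizing by
the VAT's own mass is available behind ``normalize='vat'``.

Outcome analysis is univariate ordinary least squares of a clinical score
(CGI, 1 best .. 7 worst) on an activation measure, reporting slope,
intercept, two-sided p, R^2 and the 95% CI of the slope. Left and right
hemispheres are analysed separately; no multiple-testing correction is
applied (raw p-values, noted in output metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .grids import Mask, SphereROI, VoxelGrid, rasterize_sphere

__all__ = [
    "ContactRecord",
    "ActivationMeasures",
    "RegressionResult",
    "vat_radius",
    "vat_mask",
    "activation_measures",
    "min_distance_to_mask",
    "univariate_regress",
]


@dataclass(frozen=True)
class ContactRecord:
    """One effectively stimulated electrode contact in MNI mm."""

    patient_id: str
    side: str
    position: tuple[float, float, float]
    current_mA: float
    cgi: int | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.current_mA < 0:
            raise ValueError("stimulation current must be >= 0")
        if self.cgi is not None and not 1 <= int(self.cgi) <= 7:
            raise ValueError("CGI must lie in 1..7")


@dataclass(frozen=True)
class ActivationMeasures:
    mean_density_drtx: float
    mean_density_drtu: float
    rw_overlap: float
    vat_radius_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.rw_overlap <= 1 + 1e-9:
            raise ValueError("rw_overlap must lie in [0, 1]")
        if self.vat_radius_mm < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    ci95_low: float
    ci95_high: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R^2 must lie in [0, 1]")
        if not self.ci95_low <= self.slope <= self.ci95_high:
            raise ValueError("slope must lie within its 95% CI")


def vat_radius(current_mA: float, scaling_exponent: float = 0.5) -> float:
    """Activation radius (mm) for a stimulation current.

    Calibrated so 1 mA -> exactly 2 mm for every exponent; monotone
    increasing in current.
    """
    if current_mA < 0:
        raise ValueError("current must be >= 0")
    return 2.0 * float(current_mA) ** scaling_exponent


def vat_mask(
    contact: ContactRecord, like: VoxelGrid, scaling_exponent: float = 0.5
) -> Mask:
    """Rasterized spherical VAT of a contact. Zero current -> empty mask."""
    r = vat_radius(contact.current_mA, scaling_exponent)
    if r == 0:
        warnings.warn("zero current: empty VAT")
        return Mask(like.empty_like(), kind="binary")
    return rasterize_sphere(SphereROI(contact.position, r), like)


def activation_measures(
    contact: ContactRecord,
    drtx_density: VoxelGrid,
    drtu_density: VoxelGrid,
    rw_prob: Mask,
    scaling_exponent: float = 0.5,
    normalize: str = "rw",
) -> ActivationMeasures:
    """Per-contact activation measures on a common grid.

    mean_density_* is the mean streamline density over VAT voxels;
    rw_overlap is sum of RW probability inside the VAT divided by the total
    RW probability mass (``normalize='rw'``, fraction of the RW activated)
    or by the VAT voxel count (``normalize='vat'``).
    """
    for g in (drtu_density, rw_prob.grid):
        if not drtx_density.same_grid(g):
            raise ValueError("all volumes must share one grid")
    vat = vat_mask(contact, drtx_density, scaling_exponent)
    sel = vat.data > 0
    if not sel.any():
        raise ValueError("empty VAT: contact outside grid or zero current")
    rw_total = rw_prob.data.sum()
    if rw_total <= 0:
        raise ValueError("RW mask has no probability mass")
    covered = float(rw_prob.data[sel].sum())
    if normalize == "rw":
        overlap = covered / float(rw_total)
    elif normalize == "vat":
        overlap = covered / float(sel.sum())
    else:
        raise ValueError("normalize must be 'rw' or 'vat'")
    return ActivationMeasures(
        mean_density_drtx=float(drtx_density.data[sel].mean()),
        mean_density_drtu=float(drtu_density.data[sel].mean()),
        rw_overlap=min(overlap, 1.0),
        vat_radius_mm=vat_radius(contact.current_mA, scaling_exponent),
    )


def min_distance_to_mask(
    contact: ContactRecord, mask: Mask, threshold: float = 0.5
) -> float:
    """Minimum Euclidean distance (mm) from the contact to any voxel center
    with mask value >= threshold; 0 if the contact sits on such a center."""
    idx = np.argwhere(mask.data >= threshold)
    if idx.size == 0:
        raise ValueError("no supra-threshold voxels in mask")
    mm = mask.grid.voxel_to_mm(idx.astype(np.float64))
    d = np.linalg.norm(mm - np.asarray(contact.position), axis=1)
    return float(d.min())


def univariate_regress(x, y) -> RegressionResult:
    """OLS of outcome y on a single activation measure x.

    Two-sided t-test p for the slope, R^2, and the slope's 95% CI.
    Requires n >= 3, finite values and non-constant x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if x.std() == 0:
        raise ValueError("zero variance in predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    # a constant outcome has no variance to explain: define R^2 = 0
    r2 = float(model.rsquared) if y.std() > 0 else 0.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=r2,
        ci95_low=float(ci[1, 0]),
        ci95_high=float(ci[1, 1]),
        n=int(len(x)),
    )
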