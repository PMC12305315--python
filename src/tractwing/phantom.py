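"""Synthetic phantom cohort with the statistical structure the analysis assumes.

The phantom emulates, at desk scale, the three data sources the pipeline is
built for:

* two streamline bundles sharing a precentral-gyrus (PCG) origin that
  diverge at the superior cerebellar peduncle (SCP): a crossed bundle
  (DRTx) funnelled through a tight rubral-wing (RW) waypoint near
  MNI z = -6 and decussating at z = -15 before reaching the contralateral
  SCP (z ~ -26), and an uncrossed bundle (DRTu) that stays ipsilateral and
  never enters the RW funnel; plus distractor streamlines avoiding all
  waypoints,
* several raters' noisy binary delineations of a common RW volume, with
  the noise concentrated at the anterior/posterior (y) borders where real
  delineations disagree,
* electrode contacts clustered near the RW with stimulation currents, and
  a clinical score (CGI) linearly coupled to a chosen activation measure
  plus Gaussian noise.

Anchor coordinates are the study values: RW centers (+/-12, -17.5, -5) mm,
funnel planes z = -25 / -15 / -6, SCP spheres (+/-7, -41, -26) r = 4 mm,
contact cluster centers (-10.5, -18.5, -5.7) and (10.0, -17.8, -5.9) mm.

Streamlines are cubic splines through per-streamline jittered waypoints.
Funnel waypoints jitter uniformly inside a ball of the funnel radius
(bounded, so construction guarantees hold exactly); loose waypoints jitter
with component-wise Gaussian noise clipped at 2.5 sigma. Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .grids import Mask, SphereROI, VoxelGrid, default_analysis_grid, rasterize_sphere
from .interrater import RaterSet
from .streamlines import Tractogram, resample_streamline
from .vat import ContactRecord

__all__ = [
    "PhantomSpec",
    "make_atlas",
    "make_bundles",
    "make_raters",
    "make_cohort",
    "rw_probability_at",
]

# mm anchors for the left-hemisphere target; right is the x-mirror.
DEFAULT_WAYPOINTS: dict[str, tuple[float, float, float]] = {
    "pcg_lo": (-34.0, -30.0, 23.0),  # uniform start box corners
    "pcg_hi": (-18.0, -10.0, 29.0),
    "thalamus_entry": (-16.0, -16.0, 10.0),
    "vim": (-14.0, -17.0, 1.0),
    "rw": (-12.0, -17.5, -6.0),  # RW funnel plane z = -6
    "prerubral": (-7.0, -27.0, -10.5),
    "commissure": (0.0, -38.0, -15.0),  # decussation plane z = -15
    "pre_scp": (4.0, -40.0, -20.0),
    "scp": (7.0, -41.0, -25.0),  # SCP funnel plane z = -25, inside the r=4 sphere
    "cerebellum": (12.0, -46.0, -38.0),
    # uncrossed route (ipsilateral), posterior to the RW
    "vim_post": (-14.0, -27.0, 0.0),
    "u_mid1": (-12.0, -34.0, -10.0),
    "u_mid2": (-9.0, -37.0, -18.0),
    "scp_ipsi": (-7.0, -41.0, -25.0),
    "cerebellum_ipsi": (-12.0, -46.0, -38.0),
}

RW_CENTER_LEFT = (-12.0, -17.5, -5.0)
RW_AXES = (3.5, 2.5, 1.5)  # mm semi-axes of the probability blob
RW_FLOOR = 0.15  # probabilities below this are zeroed (compact support)
RN_CENTER_LEFT = (-8.0, -23.0, -10.0)
RN_RADIUS = 3.0
VIM_CENTER_LEFT = (-14.0, -16.0, 1.0)
VIM_AXES = (3.0, 3.0, 3.5)
CONTACT_ANCHORS = {"left": (-10.5, -18.5, -5.7), "right": (10.0, -17.8, -5.9)}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort.

    ``noise_scale`` multiplies every geometric jitter (0 gives the
    noise-free construction); ``outcome`` is (slope, intercept, noise_sd)
    linking the continuous clinical score to ``outcome_measure``.
    """

    seed: int = 0
    n_streamlines_per_bundle: int = 700
    distractor_fraction: float = 0.3  # of the total tractogram
    funnel_radii: dict[str, float] = field(
        default_factory=lambda: {"rw": 0.7, "commissure": 1.0, "scp": 1.2}
    )
    transverse_jitter: float = 2.5
    noise_scale: float = 1.0
    n_raters: int = 3
    n_subjects: int = 20
    rater_boundary_jitter: float = 1.5
    n_patients: int = 28
    contact_noise: float = 1.0
    current_range_mA: tuple[float, float] = (1.0, 4.0)
    outcome: tuple[float, float, float] = (-6.0, 4.0, 1.0)
    outcome_measure: str = "rw_overlap"

    def __post_init__(self) -> None:
        for name, v in (
            ("transverse_jitter", self.transverse_jitter),
            ("noise_scale", self.noise_scale),
            ("rater_boundary_jitter", self.rater_boundary_jitter),
            ("contact_noise", self.contact_noise),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.funnel_radii.values()):
            raise ValueError("funnel radii must be >= 0")

    def noiseless(self) -> "PhantomSpec":
        return replace(self, noise_scale=0.0)


def _rng(spec: PhantomSpec, stream: int) -> np.random.Generator:
    # independent child streams so each generator is deterministic on its own
    return np.random.default_rng([int(spec.seed), stream])


def _mirror(p: tuple[float, float, float], side: str) -> np.ndarray:
    q = np.asarray(p, dtype=np.float64)
    if side == "right":
        q = q * np.array([-1.0, 1.0, 1.0])
    return q


def _gaussian_blob(
    like: VoxelGrid, center, axes, floor: float
) -> Mask:
    """Anisotropic Gaussian probability blob exp(-m^2/2), zeroed below floor."""
    out = like.empty_like()
    c_vox = like.mm_to_voxel(np.asarray(center, dtype=np.float64))
    ext = np.asarray(axes) * np.sqrt(-2.0 * np.log(floor)) / like.voxel_sizes + 1
    lo = np.maximum(np.floor(c_vox - ext).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + ext).astype(int) + 1, np.array(like.shape))
    ii = np.stack(
        np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    mm = like.voxel_to_mm(ii.astype(np.float64))
    m2 = (((mm - np.asarray(center)) / np.asarray(axes)) ** 2).sum(axis=1)
    prob = np.exp(-0.5 * m2)
    prob[prob < floor] = 0.0
    out.data[ii[:, 0], ii[:, 1], ii[:, 2]] = prob
    return Mask(out, kind="probability")


def _ellipsoid(like: VoxelGrid, center, axes) -> Mask:
    blob = _gaussian_blob(like, center, axes, floor=np.exp(-0.5))  # m <= 1
    return Mask(
        VoxelGrid((blob.data > 0).astype(float), like.affine.copy()), kind="binary"
    )


def _box(like: VoxelGrid, lo, hi) -> Mask:
    out = like.empty_like()
    ii = np.indices(like.shape).reshape(3, -1).T.astype(np.float64)
    mm = like.voxel_to_mm(ii)
    inside = np.all((mm >= np.asarray(lo)) & (mm <= np.asarray(hi)), axis=1)
    out.data.reshape(-1)[inside] = 1.0
    return Mask(out, kind="binary")


def make_atlas(
    spec: PhantomSpec, like: VoxelGrid | None = None
) -> dict[str, Mask]:
    """Phantom ROI masks on the analysis grid, both hemispheres.

    RW is a flat wing-shaped probability blob with center of gravity at the
    planted anchor; RN/VIM are binary ellipsoids; PCG is a binary cortical
    block; SCP spheres are rasterized at the study coordinates.
    """
    like = like if like is not None else default_analysis_grid()
    atlas: dict[str, Mask] = {}
    wp = DEFAULT_WAYPOINTS
    for side in ("left", "right"):
        atlas[f"rw_{side}"] = _gaussian_blob(
            like, _mirror(RW_CENTER_LEFT, side), RW_AXES, RW_FLOOR
        )
        atlas[f"rn_{side}"] = _ellipsoid(
            like, _mirror(RN_CENTER_LEFT, side), (RN_RADIUS,) * 3
        )
        atlas[f"vim_{side}"] = _ellipsoid(
            like, _mirror(VIM_CENTER_LEFT, side), VIM_AXES
        )
        lo, hi = _mirror(wp["pcg_lo"], side), _mirror(wp["pcg_hi"], side)
        atlas[f"pcg_{side}"] = _box(
            like, np.minimum(lo, hi) - 1.0, np.maximum(lo, hi) + 1.0
        )
        sign = -1.0 if side == "left" else 1.0
        atlas[f"scp_{side}"] = rasterize_sphere(
            SphereROI((sign * 7.0, -41.0, -26.0), 4.0), like
        )
    return atlas


def _spline_streamline(anchors: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    pts = anchors + offsets
    chord = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    t = np.concatenate([[0.0], np.cumsum(chord)])
    cs = CubicSpline(t, pts, axis=0)
    dense = cs(np.linspace(0.0, t[-1], 200))
    return resample_streamline(dense, 0.5)


def _bundle_offsets(
    rng: np.random.Generator,
    n: int,
    sigmas: np.ndarray,
    funnel: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Per-streamline waypoint offsets, shape (n, n_wp, 3).

    Waypoints with funnel[k] True jitter uniformly in a transverse (xy)
    disk of radius sigmas[k] — every streamline pierces the funnel plane at
    the funnel's z, which is what makes it a bottleneck; others are
    transverse (xy) Gaussian with sd sigmas[k], clipped at 2.5 sd so
    excursions are bounded and separation guarantees are deterministic.
    All jitter is transverse: the z-course of a bundle is shared, so each
    streamline crosses every axial plane exactly once.
    """
    n_wp = len(sigmas)
    out = np.zeros((n, n_wp, 3))
    for k in range(n_wp):
        s = sigmas[k] * scale
        if s == 0:
            continue
        if funnel[k]:
            # uniform in a transverse disk of radius s
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
            r = s * np.sqrt(rng.uniform(size=n))
            out[:, k, 0] = r * np.cos(theta)
            out[:, k, 1] = r * np.sin(theta)
        else:
            out[:, k, :2] = np.clip(
                rng.normal(0.0, s, size=(n, 2)), -2.5 * s, 2.5 * s
            )
    return out


def _make_one_bundle(
    rng: np.random.Generator,
    n: int,
    anchor_names: list[str],
    sigmas: list[float],
    funnel_names: set[str],
    side: str,
    spec: PhantomSpec,
) -> list[np.ndarray]:
    wp = DEFAULT_WAYPOINTS
    anchors = np.array([_mirror(wp[a], side) for a in anchor_names])
    funnel = np.array([a in funnel_names for a in anchor_names])
    offsets = _bundle_offsets(
        rng, n, np.asarray(sigmas, dtype=float), funnel, spec.noise_scale
    )
    # PCG start: uniform inside the cortical box rather than Gaussian
    lo, hi = _mirror(wp["pcg_lo"], side), _mirror(wp["pcg_hi"], side)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    starts = lo + (hi - lo) * rng.uniform(size=(n, 3))
    if spec.noise_scale == 0:
        starts = np.tile((lo + hi) / 2.0, (n, 1))
    # terminal waypoint: transverse jitter only, so every streamline ends on
    # one z-plane and no sparse end slice can mimic a bottleneck
    offsets[:, -1, 2] = 0.0
    z_end = anchors[-1, 2]
    sls = []
    for i in range(n):
        a = anchors.copy()
        a[0] = starts[i]
        sl = _spline_streamline(a, offsets[i])
        sl = sl[sl[:, 2] >= z_end - 0.25]
        sls.append(sl)
    return sls


def make_bundles(spec: PhantomSpec, side: str = "left") -> Tractogram:
    """Phantom tractogram with planted labels {DRTx, DRTu, distractor}.

    DRTx: PCG -> thalamus/VIM -> RW funnel (z = -6) -> decussation
    (z = -15) -> contralateral SCP (z ~ -25) -> cerebellum. DRTu: PCG ->
    posterior thalamic route -> ipsilateral SCP -> cerebellum, never
    entering the RW funnel. Distractors avoid every waypoint.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    rng = _rng(spec, 1)
    n = spec.n_streamlines_per_bundle
    fr = spec.funnel_radii
    j = spec.transverse_jitter

    drtx = _make_one_bundle(
        rng,
        n,
        ["pcg_lo", "thalamus_entry", "vim", "rw", "prerubral", "commissure",
         "pre_scp", "scp", "cerebellum"],
        [0.0, 3.0, 2.0, fr["rw"], j, fr["commissure"], j, fr["scp"], 4.0],
        {"rw", "commissure", "scp"},
        side,
        spec,
    )
    drtu = _make_one_bundle(
        rng,
        n,
        ["pcg_lo", "thalamus_entry", "vim_post", "u_mid1", "u_mid2",
         "scp_ipsi", "cerebellum_ipsi"],
        [0.0, 3.0, 2.0, j, 2.0, fr["scp"], 4.0],
        {"scp_ipsi"},
        side,
        spec,
    )
    n_dis = int(round(spec.distractor_fraction / (1 - spec.distractor_fraction) * 2 * n))
    sign = 1.0 if side == "left" else -1.0  # distractors in the far hemisphere
    dis: list[np.ndarray] = []
    for i in range(n_dis):
        x0 = sign * rng.uniform(22.0, 36.0)
        y0 = rng.uniform(-4.0, 14.0)
        anchors = np.array(
            [[x0, y0, 15.0], [x0 + 2.0 * sign, y0 + 2.0, -8.0], [x0, y0, -30.0]]
        )
        if spec.noise_scale > 0:
            off = np.clip(
                rng.normal(0.0, 2.0 * spec.noise_scale, size=(3, 3)), -5.0, 5.0
            )
        else:
            off = np.zeros((3, 3))
        dis.append(_spline_streamline(anchors, off))
    labels = ["DRTx"] * n + ["DRTu"] * n + ["distractor"] * n_dis
    return Tractogram(drtx + drtu + dis, space_tag="MNI-mm", labels=labels)


def make_raters(
    spec: PhantomSpec,
    truth: Mask,
    hemisphere: str = "left",
    n_subjects: int | None = None,
) -> list[RaterSet]:
    """Noisy rater delineations of a shared truth mask, one RaterSet per subject.

    The truth's anterior/posterior (y) extents are perturbed per rater by
    rounded Gaussian shifts of sd ``rater_boundary_jitter`` (mm), plus
    sparse voxel flips along the perturbed borders — delineation noise
    concentrated where real raters disagree.
    """
    if truth.total_mass() == 0:
        raise ValueError("empty truth mask")
    rng = _rng(spec, 2)
    n_subjects = n_subjects if n_subjects is not None else spec.n_subjects
    tdata = truth.data > 0
    cols = np.argwhere(tdata.any(axis=1))  # (x, z) columns with any mass
    dy_vox = spec.rater_boundary_jitter / float(truth.grid.voxel_sizes[1])
    ny = tdata.shape[1]

    out: list[RaterSet] = []
    for s in range(n_subjects):
        masks: dict[str, Mask] = {}
        for r in range(spec.n_raters):
            d_ant = int(np.clip(round(rng.normal(0.0, dy_vox)), -3, 3))
            d_post = int(np.clip(round(rng.normal(0.0, dy_vox)), -3, 3))
            p_flick = 0.2 if spec.rater_boundary_jitter > 0 else 0.0
            new = np.zeros_like(tdata)
            for x, z in cols:
                ys = np.flatnonzero(tdata[x, :, z])
                y0, y1 = ys.min(), ys.max()
                # per-column flicker of +/-1 voxel on top of the rater shift
                f0 = int(rng.uniform() < p_flick) - int(rng.uniform() < p_flick)
                f1 = int(rng.uniform() < p_flick) - int(rng.uniform() < p_flick)
                a = max(y0 - d_post + f0, 0)
                b = min(y1 + d_ant + f1, ny - 1)
                if a <= b:
                    new[x, a : b + 1, z] = True
                else:
                    # raters always mark at least the run's central voxel
                    new[x, (y0 + y1) // 2, z] = True
            if not new.any():
                raise ValueError("boundary jitter destroyed a rater mask")
            masks[f"rater{r + 1}"] = Mask(
                VoxelGrid(new.astype(float), truth.grid.affine.copy()), kind="binary"
            )
        out.append(RaterSet(subject_id=f"sub-{s + 1:03d}", hemisphere=hemisphere, masks=masks))
    return out


def rw_probability_at(points, side: str = "left") -> np.ndarray:
    """Analytic RW probability at mm points: the generator's Gaussian blob
    evaluated in closed form (zeroed below the support floor). A cheap
    point-wise activation measure for large replicate simulations."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    center = _mirror(RW_CENTER_LEFT, side)
    m2 = (((pts - center) / np.asarray(RW_AXES)) ** 2).sum(axis=-1)
    prob = np.exp(-0.5 * m2)
    prob[prob < RW_FLOOR] = 0.0
    return prob


def make_cohort(
    spec: PhantomSpec,
    activation_fn: Callable[[ContactRecord], float],
) -> pd.DataFrame:
    """Synthetic DBS cohort: contacts, currents, activation and CGI.

    Contacts are the per-side cluster anchors plus isotropic Gaussian noise
    (sd ``contact_noise``); currents are uniform over ``current_range_mA``.
    The continuous outcome is intercept + slope * activation + N(0, sd)
    (column ``cgi_raw``); the ordinal CGI is its clip-round to 1..7 with
    half-grade ties going to the better (lower) grade.
    """
    rng = _rng(spec, 3)
    slope, intercept, noise_sd = spec.outcome
    rows = []
    for p in range(spec.n_patients):
        for side in ("left", "right"):
            pos = np.asarray(CONTACT_ANCHORS[side]) + rng.normal(
                0.0, spec.contact_noise, size=3
            )
            cur = rng.uniform(*spec.current_range_mA)
            contact = ContactRecord(
                patient_id=f"pat-{p + 1:03d}",
                side=side,
                position=tuple(pos),
                current_mA=float(cur),
            )
            act = float(activation_fn(contact))
            raw = intercept + slope * act + rng.normal(0.0, noise_sd)
            cgi = int(np.clip(np.ceil(raw - 0.5), 1, 7))  # ties to lower grade
            rows.append(
                {
                    "patient_id": contact.patient_id,
                    "side": side,
                    "x_mm": pos[0],
                    "y_mm": pos[1],
                    "z_mm": pos[2],
                    "current_mA": float(cur),
                    "activation": act,
                    "cgi_raw": raw,
                    "cgi": cgi,
                }
            )
    return pd.DataFrame(rows)
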