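# Methods

## Coordinate and grid conventions

All analysis happens in MNI RAS millimetre space. A `VoxelGrid` couples a 3-D
scalar lattice to an invertible voxel-index → mm affine; NIfTI volumes are
reoriented to the closest RAS canonical axes on load. Voxel centers sit at
integer indices; a mm point belongs to the voxel whose continuous index rounds
to it, with half-integer ties rounded away from zero — this single convention
makes sphere rasterization and voxel-visit tests deterministic and exactly
reproducible by brute-force enumeration. The default analysis grid is a 1 mm
isotropic box, x ∈ [−40, 40], y ∈ [−80, 20], z ∈ [−50, 30] mm, covering the
rubral wing (RW), red nucleus (RN), ventral intermediate nucleus (VIM), both
superior cerebellar peduncles (SCP), the decussation and a precentral-gyrus
(PCG) block.

Probability masks keep native float values throughout; nothing binarizes
implicitly. Group averages of delineations are plain voxel-wise means of the
values as loaded (no interpolation or Jacobian modulation), recorded as
probability masks.

## Streamline maps

Visitation density counts each streamline at most once per voxel, making the
map a streamline-count measure; a flag switches to per-point counting for
comparison. Before binning, streamlines are resampled at half the minimum
voxel spacing so straight segments cannot skip voxels. The resampler inserts
points along the polyline at most `step` apart while retaining the original
vertices, so output points lie exactly on the input polyline and arc length is
preserved to machine precision. Terminal maps bin only the two endpoints of
each streamline (total mass 2 × streamline count when all endpoints are
inside the grid; outside endpoints are dropped with a counted warning).
Ratio maps are voxel-wise (a + ε)/(b + ε), optionally in log2 units.

## Bundle selection

Two selection families:

* **RW-DRT** — a streamline is kept iff any resampled point lies in a voxel
  whose RW probability is ≥ the threshold (inclusive; default 0.6). Kept
  streamlines are labelled *crossed* if they visit the SCP sphere
  contralateral to the RW side ((±7, −41, −26) mm, r = 4 mm; laterality is
  the sign of the center's x), *uncrossed* if ipsilateral, and *unresolved*
  if neither or both. Unresolved streamlines are excluded from both bundles
  by default; a flag reassigns them by whichever sphere is visited first
  along the streamline.
* **Classical DRT** — `drt_pcg_scp` requires a streamline *endpoint* inside
  the PCG mask dilated by one voxel plus the SCP visit (contralateral for the
  crossed bundle); passage through the gyrus does not count, which keeps
  u-fibers out. `drt_rn_scp` drops the cortical constraint and requires a
  red-nucleus visit plus the SCP visit.

The RW visit test can use the probability values directly (as above) or a
pre-binarized mask; both give the same result at a fixed threshold because
the comparison is ≥ on voxel values.

## Slice profiles

For each axial slice of a density volume, the slice is normalized to total
mass 1 and its Shannon entropy H = −Σ p ln p (nats, 0·ln 0 := 0) computed.
The **inverse diversity** exp(−H) is exactly the reciprocal perplexity: 1 for
a single-voxel bottleneck, 1/n for uniform spread over n voxels. Natural
logarithm is the only base self-consistent with the exponential. Empty slices
get inverse diversity 0 (not 1) and NaN entropy, so support gaps never
masquerade as bottlenecks. Bottlenecks are local maxima of the profile with
prominence ≥ 0.05 (absolute) and mutual separation ≥ 5 mm; the underlying
study identified its peaks visually, so these two defaults are this package's
own choice — small enough to keep all three anatomical funnels, large enough
to suppress sampling noise in slice entropies.

Slice-wise cosine similarity scales the density slice and the reference slice
each to unit Euclidean norm and sums their pointwise product: 1 for
proportional non-zero slices, 0 for disjoint support. Slices where either
vector vanishes are undefined and reported as NaN (callers comparing
structures at a plane may treat an absent structure as zero agreement).

## Inter-rater agreement

DICE = 2|A∩B|/(|A|+|B|) on a common grid; two empty masks are defined to agree
(DICE 1) with an explicit warning. COG distances are Euclidean distances of
mass-weighted centroid coordinates in mm. Volumes are voxel count × voxel
volume with no Jacobian correction. Pearson correlation of per-subject volumes
between raters requires ≥ 3 subjects and non-constant volumes.

## VAT and outcome model

The volume of activated tissue of a DBS contact is a sphere of radius
r(I) = 2·(I / 1 mA)^q mm. The calibration point r(1 mA) = 2 mm holds exactly
for every exponent; the default q = 0.5 is a square-root falloff heuristic for
a point source and is configurable. Zero current yields an empty VAT by
convention.

Per-contact activation measures: the mean crossed/uncrossed bundle density
over VAT voxels, and the **RW overlap** = (RW probability mass inside the
VAT) / (total RW probability mass) — i.e. the fraction of the structure
activated. The alternative normalization by VAT volume is available behind
`normalize='vat'`; the choice is logged in pipeline output. RW overlap is
monotone non-decreasing in current.

Outcomes are analysed per hemisphere by univariate OLS of CGI on one
activation measure (statsmodels), reporting slope, intercept, two-sided
t-test p, R², and the slope's 95% CI. A constant outcome has no variance to
explain and gets R² = 0. No multiple-testing correction is applied (raw
p-values, noted in output metadata). Bilateral clinical scores attach to both
sides' contacts, a known confounder of per-side regressions.

## Synthetic phantom

The generator produces the statistical structure the analysis assumes, at
desk scale, deterministic under a fixed seed (independent child RNG streams
per sub-generator, so each output is reproducible on its own).

**Atlas.** The RW is an anisotropic Gaussian probability blob, semi-axes
(3.5, 2.5, 1.5) mm, zeroed below 0.15, centered at (±12, −17.5, −5) mm — a
flat wing lateral to the RN ellipsoid and beneath the VIM. PCG is a cortical
block, SCP spheres sit at the study coordinates (±7, −41, −26), r = 4 mm.

**Bundles.** Streamlines are cubic splines through per-streamline jittered
waypoints, resampled at 0.5 mm. The crossed bundle runs PCG → thalamus/VIM →
RW funnel (z = −6) → decussation (z = −15) → contralateral SCP funnel
(z = −25) → cerebellum; the uncrossed bundle takes a posterior thalamic route
to the ipsilateral SCP and never enters the RW funnel; distractors (30% of
the tractogram) avoid all waypoints. Funnel waypoints jitter uniformly in a
transverse disk of the funnel radius (RW 0.7, decussation 1.0, SCP 1.2 mm),
so every streamline pierces the funnel plane at its z — that bounded support
is what makes the construction guarantees exact (every crossed streamline
visits the RW at threshold 0.6; no uncrossed streamline does). Loose
waypoints jitter with transverse Gaussian noise (sd 2–3 mm) clipped at
2.5 sd, and terminal waypoints jitter transversely only, so no sparse end
slice can mimic a bottleneck. A `noise_scale` multiplier of 0 gives the
noise-free construction (each bundle collapses to one curve).

**Raters.** Rater masks perturb the binarized RW truth predominantly at its
anterior/posterior (y) borders: per-rater rounded Gaussian shifts of the run
ends (sd 1.5 mm, clipped at ±3 voxels) plus 20% per-column single-voxel
flicker at the borders. A column whose run would vanish keeps its central
voxel — raters always mark at least the structure's core slice. This
reproduces the characteristic dissociation of moderate DICE with sub-2-mm COG
distances; symmetric end jitter erodes overlap while barely moving the
centroid.

**Cohort.** Contacts are the per-side cluster anchors (−10.5, −18.5, −5.7)
and (10.0, −17.8, −5.9) mm plus isotropic Gaussian noise (sd 1 mm); currents
are uniform on [1, 4] mA. The continuous outcome is
intercept + slope·activation + N(0, sd) with defaults (4, −6, 1) on the RW
overlap — more activation, better (lower) score, with an explained-variance
fraction around 0.3. The ordinal CGI is the clip-round of that value to 1..7,
half-grade ties going to the better grade (an arbitrary, documented
convention). CI-coverage simulations use the continuous outcome: the 95%
interval of a correctly specified OLS covers the planted slope at the nominal
rate, whereas clip-rounding is deliberate model misspecification and would
not. Sign-recovery and pipeline regressions use the ordinal CGI as a real
analysis would.

**What the phantom does not emulate.** Diffusion signal formation and
tractography errors (false-positive/negative streamlines with realistic
geometry), inter-subject anatomical variability and warping residuals,
partial-volume and SNR characteristics of FLAWS/FGATIR contrast, electrode
trajectories and non-spherical activation volumes. Passing tests therefore
demonstrate the correctness and stability of the *analysis* under the stated
generative assumptions, not the empirical findings on clinical or HCP data;
headline clinical values (median DICE, peak z-positions, regression p/R²)
are data-bound and only their qualitative signatures are checked.

## Problem sizes

Recovery and profile analyses run on 2,000 phantom streamlines (700 per
bundle plus 600 distractors) on the 1 mm analysis grid; inter-rater medians
on 20 subjects × 3 raters; outcome regressions on 28 patients per side;
CI coverage on 1,000 cohort replicates; the end-to-end determinism check on a
120-streamline-per-bundle pipeline, all chosen as the package's default desk-
scale study conditions.

## Known limitations

- The visitation-count convention (once per streamline per voxel) is a
  documented choice; per-point counting changes absolute densities but not
  bottleneck locations.
- Slice statistics require axis-aligned volumes; oblique affines are rejected
  rather than resampled.
- The VAT is a sphere; field anisotropy and electrode geometry are out of
  scope.
- `select_classical_drt` operationalizes "connectivity" with the PCG as an
  endpoint-in-dilated-mask test; tractograms whose streamlines stop short of
  cortex need a more permissive criterion.
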