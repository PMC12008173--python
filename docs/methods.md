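# Methods

## The surface pipeline (cortex-based mapping)

The statistic of interest is a vertex-wise z-score of a patient's
surface-sampled SUVR against a healthy cohort:
z_v = (x_v − μ_v)/σ_v, where μ_v and σ_v are the mean and n−1 sample SD
of the smoothed control fields at vertex v. The candidate focus is the
global minimum 0.5% of vertices. Assumptions worth making explicit:

- **Vertex correspondence is given.** On real data this is the job of
  surface registration; our phantoms share one mesh across subjects, so
  correspondence is exact by construction and the pipeline's behavior
  is measured free of registration error (the artifact study
  re-introduces it deliberately; see below).
- **The z-transform is the plain one-vs-group form.** A one-vs-group
  comparison could inflate σ by √(1 + 1/n) to account for the test
  subject's own sampling variance; the implemented transform does not,
  matching the method as defined. At n = 23 the difference is ~2%.
- **The threshold is rank-based, not value-based.** Exactly
  ⌈0.005·N⌉ vertices are flagged whatever the data; ties at the cut are
  broken by ascending vertex index so the flagged set is deterministic.
  A consequence: the threshold is invariant to any monotone
  transformation of the z-map, including global shifts from a subject's
  overall metabolic level. The fraction is applied jointly across the
  analyzed surface (a per-hemisphere mode would apply it to each
  connected component; with the phantom's single sphere the two
  coincide, and the joint reading follows from "global" minimum).

### Surface smoothing

Smoothing uses iterative neighbor diffusion:
x ← (1−λ)x + λ·Wx with λ = 0.5 and W the row-normalized
inverse-edge-length adjacency. The step count is calibrated once per
mesh by measuring the geodesic radial second moment of a smoothed
impulse: variance grows linearly per step, and the count is chosen so
the accumulated E[r²] equals 2σ² (the radial second moment of a 2-D
Gaussian with per-axis σ = FWHM/2.3548 — the factor 2 matters: matching
E[r²] to σ² produces a kernel whose FWHM is √2 too small). On a
10242-vertex sphere of radius 85 mm the empirical FWHM of the smoothed
impulse is 18.5 mm for a 20 mm target (7.6% low; the diffusion kernel
is slightly heavy-tailed relative to a true Gaussian). Constant fields
are exact fixed points; isolated vertices are returned unchanged with a
warning.

### Template SD floor

σ_v is floored at `sd_floor_fraction` (default 0.05) × the median
vertex SD, so z stays finite at near-constant vertices; floored
vertices are flagged in the template. A degenerate cohort whose median
SD is zero falls back to an absolute floor of 1e-6. The default
fraction is small enough that no vertex is floored under the phantom's
study conditions.

## The voxel pipeline (single-case t-maps)

t = (x − m̄)/(s·√(1 + 1/n)) with df = n − 1, algebraically the pooled
two-sample t with group sizes 1 and n (verified against the explicit
pooled formula to 1e-10). Thresholding is one-sided (lower tail;
hypometabolism is a directional question), with 18-connectivity for
voxel clusters and "conclusive" formalized as at least one surviving
cluster — the ladder then proceeds p < 0.001 (k = 20), p < 0.05
(k = 20), global-minimum voxel. No multiple-comparison correction is
applied at any rung, matching the thresholds as printed. Voxels with
zero control SD are excluded and logged.

## Preprocessing

- `fwhm_to_sigma`: σ = FWHM/(2√(2 ln 2)).
- Gaussian blur: separable, σ converted mm → voxels per axis, `reflect`
  (half-sample symmetric) boundaries — these conserve the global sum to
  float accuracy, which the tests rely on.
- van Cittert PVC: x₀ = y; x_{k+1} = x_k + α(y − blur(x_k)); defaults
  K = 10, α = 1.0, non-negativity clamp on. The method's source names
  no iteration count or relaxation, so defaults follow common practice
  and are config-exposed; exact numeric parity with any particular
  external binary is not claimed. Divergence (residual growing three
  iterations running) triggers early stop at the best iterate with a
  warning — on noisy inputs the non-negativity clamp makes the
  iteration slightly non-monotone, so early stopping doubles as
  regularization. On a noiseless two-level phantom the corrected image
  reaches ~0.44 of the blurred image's RMSE to truth.
- SUVR: division by the arithmetic mean over all cerebellum-reference
  voxels (mean rather than median is the standard SUVR convention);
  the output's reference mean is exactly 1 and the operation is
  invariant to global intensity scaling.

## Phantoms: what they emulate and what they do not

One icosphere models one hemisphere (two disjoint icospheres model a
brain when hemisphere-aware behavior is tested). The default radius is
85 mm so the sphere's area (~91,000 mm²) matches a human cortical
hemisphere; the generator default is subdivision 4 (2562 vertices),
while the smoothing-dependent studies use subdivision 5 (10242
vertices, 2.8 mm edges) because the 20 mm kernel (σ 8.5 mm) needs edges
a few times shorter than σ to be represented faithfully.

Healthy SUVR fields are: per-region means (geodesic-Voronoi
parcellation, 12 regions, defaults patterned on the healthy regional
pattern — limbic/anterior-temporal regions near 0.44–0.64, neocortex
1.05–1.30) + a global subject offset (SD 0.005) + a spatially coherent
intersubject field (per-vertex SD 0.05, correlation FWHM 20 mm). The
structure of the noise matters more than its size: ratio normalization
to the cerebellum removes most of the global uptake level (hence the
small offset), and intersubject metabolic topography is smooth at the
gyral scale — iid vertex noise would be annihilated by the 20 mm
analysis kernel and leave z-maps offset-dominated. Under this model a
held-out control's z-map has mean ≈ 0 and SD ≈ 1 across vertices.

Lesions are geodesic disks (graph geodesic over edge lengths — an
overestimate of the surface geodesic, so study drivers size the disk
from the empirical distance quantile when a target vertex fraction is
requested) scaled by a hypometabolism factor f ∈ (0, 1]. Surgical
fields are geodesic disks as well, letting tests construct concordant
and discordant geometries deliberately.

The volume phantom voxelizes the sphere into a gray ribbon
(±3.5 mm of the surface, activity 1.2), white interior (0.7), CSF
exterior (0.05), plus a disjoint cerebellum ball (1.0) below the
cortex — off the analyzed surface, mirroring its role as a pure
reference region. PET measurement is emulated as a 3 mm Gaussian blur
plus additive Gaussian noise (SD 0.03); scanner physics beyond that
(attenuation, scatter, Poisson statistics, reconstruction artifacts)
is out of scope, as is realistic gyral/sulcal geometry. Passing tests
therefore demonstrate the statistical machinery, not robustness to
anatomical complexity.

Registration jitter is a smooth random displacement field (white noise
Gaussian-filtered at 20 mm, scaled to a 2 mm RMS magnitude), rejected
if its displacement gradient reaches 1 anywhere (folding), with a
fixed-point numeric inverse verified to 0.1 voxel everywhere.

## The artifact study

All subjects share the canonical anatomy; each carries one residual
warp. The volume pipeline sees the warp fully: group-space volumes are
the subject volumes resampled through it, so the t-test across subjects
picks up boundary misalignment. The surface pipeline sees only the
warp's tangential component: surface registration keeps each vertex on
the subject's cortical ribbon, so its residual error slides along the
surface instead of crossing tissue boundaries. This one-warp-two-
projections construction is what makes the comparison fair — both
pipelines are driven by the same misalignment field.

Two phantom-specific safeguards: (1) subject volumes carry intersubject
metabolic variability (global offset + smooth gray-matter modulation,
reusing the surface noise SDs) — without it, alignment texture is the
only variance source and both correlations are inflated; (2) the
artifact t-maps floor the control SD at 5% of the in-mask median and
zero out voxels whose SD sits at floating-point epsilon (deep constant
tissue that no warp moves), mirroring the surface template's SD floor.
Subjects whose artifact map is identically constant (zero jitter) get
r = 0 with a degeneracy flag: an identically-zero artifact map carries
no association, and Pearson's r itself stays undefined on zero
variance. Correlations are computed over the gray+white mask for the
volume pipeline and over all vertices for the surface pipeline —
including empty background would deflate r artificially.

At 2 mm jitter the study yields mean r ≈ 0.42 (volume) vs ≈ 0.09
(surface), ordering stable across all study seeds; at zero jitter both
are ~0. These are computed quantities, re-derived by
`scripts/acceptance.py` on every run.

## Evaluation statistics

Only CC (top cluster's peak inside the surgical field, no secondary
modality needed) counts as "PET result surgically removed" in the 2×2
table; PC maps to not-removed. This reading is self-consistent: with
31 seizure-free patients, a sensitivity of 0.871 equals 27/31, the CC
count. Engel IA maps to seizure-free; IB–ID are treated as not
seizure-free and flagged in the output, since the IA definition
excludes them. CIs use Clopper–Pearson; the CI method behind the
published tables is not identifiable from the printed intervals, so
CIs are reported but never asserted against them. Cohen's κ uses the
standard large-sample null SE (two-sided z-test). McNemar is the exact
two-sided binomial for b + c < 25 and the continuity-corrected χ²
otherwise; b = c = 0 returns p = 1 by convention.
`recover_confusion_from_rates` exhaustively searches integer tables
matching printed group sizes and rates, refusing ambiguous inputs.

## Known limitations

- **Dice against the 0.5% flag set is capped.** The threshold flags
  exactly 0.5% of vertices; against a lesion covering ~2%, Dice of the
  top cluster cannot exceed 2·0.005/0.025 ≈ 0.41 even when every
  flagged vertex is inside the lesion (the phantom studies reach
  precision 1.0 at Dice ≈ 0.40). Top-cluster precision is the
  uncapped localization measure and is reported alongside.
- **Null flagged sets concentrate.** On a held-out healthy subject the
  bottom 0.5% of a z-map tends to form one cluster around the global
  minimum rather than scatter: the pipeline's own 20 mm smoothing
  guarantees a smooth z-field, and any intersubject variation that
  survives the kernel is correlated at or above the kernel scale. The
  largest null cluster is typically 0.2–0.5% of vertices. Cluster size
  alone therefore separates lesioned from healthy subjects only
  weakly; cluster depth (mean z ≈ −10 for the injected lesions vs
  ≈ −2.5 for null minima at phantom scale) is the discriminating
  quantity.
- Graph geodesics overestimate surface distance by ~10–15% at phantom
  resolution; distance-quantile calibration absorbs this where a
  target area fraction matters.
- The phantom's clinical outcome labels are generated by construction
  (concordant surgical field ⇒ seizure-free), so evaluation statistics
  on phantom cohorts exercise the bookkeeping, not clinical reality.
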