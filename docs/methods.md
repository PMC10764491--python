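# Methods

`swemap` implements three-dimensional, anatomically referenced mapping of
skeletal-muscle shear wave velocity (SWV): freehand 3D compounding of
pose-tracked 2D elastography frames into a voxel volume, a standardized
(slice, angular, radial) cell representation of the masked muscle, and a
test-retest reliability and regional-statistics layer. Because no public
dataset accompanies this measurement concept, the package ships a
synthetic phantom and scan simulator that define the study conditions for
every quantitative check.

## Coordinate and sampling conventions

World coordinates are right-handed, in millimetres. Voxels are isotropic,
0-based, and own the half-open cube `[c - s/2, c + s/2)` around their
centre `c`. A frame pose maps in-plane coordinates `(u, v, 0)` — `u`
along the transducer face, `v` into the tissue — to world millimetres.
These conventions are fixed once in `geometry.py` and used everywhere,
which is what makes the bit-exact IO and order-independence tests
meaningful.

## Phantom and scan simulation

The phantom is an elongated solid with a superellipse cross-section
(default order 2.5, semi-axes 25 x 18 mm), length 200 mm, linearly
tapered to 40% scale over the last 15% of each end — a rough
vastus-lateralis-scale geometry without anatomical meshes. Its SWV field
is

    v(x) = a + b_r * r_rel + b_phi * r_rel * cos(theta) + b_z * z_rel + texture(x)

with `r_rel` the relative superellipse radius (0 on the axis, 1 on the
surface, taper included), `theta` the cross-sectional angle and `z_rel`
the normalized longitudinal position. Defaults (a = 1.6 m/s, b_r = 0.3,
b_phi = 0.1, b_z = 0.15, texture amplitude 0.05 m/s) emulate resting
muscle: superficial regions stiffer than deep ones, a mild angular and
longitudinal modulation, and smooth heterogeneity. The angular term is
scaled by `r_rel` so the field stays differentiable on the axis. The
texture is a low-order 3D cosine series with seeded coefficients
(band-limited, cheap, differentiable); `Phantom.lipschitz_bound()`
reports a conservative numerical bound on the field gradient (sampled
central differences inflated by 1.3) used by the reconstruction-accuracy
checks. Parameter validation rejects any setting whose field lower bound
is non-positive, since SWV is a physical speed.

The scan simulator sweeps a linear-transducer image plane (default
50 x 40 mm, 1 mm pixels) along the muscle axis in several laterally
offset swipes; one frame every `frame_spacing_mm` stands for the sweep
speed divided by the device's ~2 Hz measurement rate. The sweep direction
of each swipe is randomized. The paper behind this design does not report
a sweep speed, so frame spacing is a free protocol parameter. Two
distinct randomness channels matter:

* `lateral_wobble_mm` — true, correctly tracked hand motion. Without it a
  simulated scan samples only a few discrete lateral planes, which no
  freehand acquisition does.
* `pose_jitter_*` — tracking error. The field is sampled at the true
  pose; the *recorded* pose is perturbed (independent per frame, pivoting
  on the frame centre). A perturbation applied to both sampling and
  record would be unobservable and could not degrade test-retest
  reliability, which is its purpose.

Measurement noise is i.i.d. Gaussian on the SWV samples. All randomness
derives from one integer seed through fixed sub-streams
(`numpy.random.SeedSequence([seed, stream])`), so identical seeds
reproduce phantoms and frame sets bit for bit.

The cohort generator is a deliberate shortcut past image formation: map
cells are drawn from `base + region + subject + session + error`, all
Gaussian. Under this model the expected ICC(2,1) is
`sigma_subject^2 / (sigma_subject^2 + sigma_error^2)` (no session
effect), which gives the reliability layer a closed-form truth to
recover. The error term is drawn per subject, session *and cell*;
recovery checks therefore use single-cell maps so the whole-muscle scalar
is exactly the modelled quantity.

## Reconstruction

Each valid pixel is transformed by its frame's recorded pose and
accumulated into the containing voxel; the voxel value is the arithmetic
mean of its samples. Mean compounding is order-independent (any frame
permutation yields the identical volume) and keeps every voxel value
inside the range of its contributing samples. Voxels without samples stay
undefined (NaN sentinel plus a zero count) — gaps are never invented
silently. One-voxel holes can be filled with the mean of their defined
6-neighbours behind an explicit flag, off by default; filled voxels are
recorded in a separate mask and keep count zero. The default voxel
spacing is 1 mm (roughly the elevational resolution scale of a linear
probe), configurable everywhere.

With noiseless data, the worst voxel error is bounded by the field's
Lipschitz constant times the voxel diagonal (every sample lies within the
voxel); with noise SD 0.1 m/s and the several-fold frame overlap a 2 Hz
sweep produces, per-voxel RMSE lands around 0.02-0.03 m/s in the shipped
configurations.

## Parameterization

The masked point set is aligned along its distal-proximal axis by PCA
(dominant eigenvector of the coordinate covariance; an isotropic cloud is
rejected). Axis sign comes from an orientation hint; the in-slice x axis
(angular zero) comes from a secondary hint, by default the world axis
most orthogonal to the principal axis. Supplying transformed hints makes
the whole parameterization rigid-motion invariant, which is tested to
1e-6 on cell means.

Slices are uniform half-open bins over the aligned longitudinal extent
(ties go to the higher slice; the extreme point to the last slice). Each
slice gets a polar origin:

* `circle_fit` (vastus lateralis archetype): the centre of the algebraic
  (Kasa) least-squares circle fitted to the slice's outer boundary — the
  per-angular-ray outermost points about the slice centroid. The angular
  coordinate is normalized over the mask's angular span, located as the
  complement of the largest angular gap.
* `centroid` (biceps femoris long head archetype): the coordinate
  centroid, with the angular coordinate spanning the full circle. (The
  source description says "geometric mean" of the mask; a literal
  geometric mean of signed coordinates is ill-defined, so the coordinate
  centroid is used.)

Radii are normalized per angular sector to the local mask extent,
`r_rel = (rho - rho_min) / (rho_max - rho_min)`, so cells have uniform
*relative* radial extent for non-circular sections. Three numerical
choices matter here:

1. The sector resolution is a fixed internal constant (64), not the
   configured angular bin count. Because `r_rel` and `phi_rel` are then
   independent of the output resolution, a (S, 2A, 2R) map merges
   *exactly* (count-weighted) into the (S, A, R) map.
2. Each point contributes its radius to every sector inside its angular
   footprint `atan(spacing/2 / rho)`. Voxel centres near the origin
   subtend far more than one fine sector; treating them as angular point
   masses starves the inner sectors and inflates `rho_min` by several
   voxel widths, which compresses the recovered radial gradient by tens
   of percent even on ideal dense clouds.
3. When the sampling pitch is known (point sets emitted by `apply_mask`
   carry their grid spacing), sector bounds are extended by half a pitch:
   voxel centres stop half a voxel short of the true mask boundary. For
   point sets without a known pitch the raw empirical extremes are used,
   so exact clouds (e.g. annulus rims) normalize exactly to 0 and 1.

Sectors with zero radial extent assign `r_rel = 0.5` with a warning.
Every input point lands in exactly one (slice, angular, radial) cell;
cell means are arithmetic means, so conservation (sum of cell counts =
point count) is exact by construction. Cells also record the centroid of
their members' `r_rel`; `radial_gradient_slope` regresses cell means on
these centroids (count-weighted), which removes the bin-midpoint bias of
a naive profile fit. Residual slope bias at 1 mm voxels is ~6-8% for the
default geometry, dominated by slice-level normalization across the
tapered ends.

Across subjects, maps aggregate cell-wise with unweighted mean and SEM;
cells missing in a subset of subjects are aggregated over the rest and
flagged. Axis profiles collapse the two other axes voxel-count-weighted
within a subject and unweighted across subjects.

## Reliability and regional statistics

`icc_2_1` implements the two-way random-effects, absolute-agreement,
single-measure intraclass correlation from the ANOVA mean squares,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with the F-based McGraw & Wong confidence interval implemented from the
formulas (the degrees of freedom fall back to their MSE->0 limit for
perfect-agreement tables). It matches an independent brute-force ANOVA
oracle to 1e-12 on random tables and pingouin's ICC(A,1) on the estimate.
Exactly constant tables are reported with an explicit `undefined` status:
floating-point residue (~1e-30) in the sums of squares would otherwise
masquerade as signal. The standard error of measurement defaults to
`SD(all entries) * sqrt(1 - ICC)`; a `sqrt(MSE)` variant sits behind a
flag. Qualitative bands are poor (<= 0.2), fair (0.21-0.4), moderate
(0.41-0.6), good (0.61-0.8), very good (> 0.8).

Whole-muscle reliability uses the voxel-count-weighted whole-muscle mean
per subject and session. Regional reliability is computed in two domains:
inter-regional (one ICC per subject over cells — can a region be
re-identified within a muscle?) and inter-subject (one ICC per cell over
subjects — does a region rank subjects consistently?), summarized as
median and IQR over defined estimates; tables with fewer than two
complete rows are excluded with a log entry, and missing rows are dropped
listwise.

Contrasts are classical paired t-tests (two-sided) on subject scalars or
per-bin axis profiles; zero-variance differences yield an explicit
`degenerate` status (detected relative to the difference scale, since a
constant shift through the profile machinery leaves ~1e-16 residue).
P-values are reported unadjusted at alpha = 0.05; Benjamini-Hochberg
adjustment is available behind a flag, off by default. Spearman's rho is
Pearson on mid-ranks with a two-sided t-approximation p-value (verified
size 0.0507 at n = 16); an exact permutation p-value is available for
n <= 10. Regional association tests each profile bin against a covariate
across subjects; bins with fewer than four complete subjects are flagged
rather than tested. The normalized strength covariate is the median of
six per-repetition force maxima divided by body mass (N/kg).

## Pipeline and what the synthetic study does not show

The pipeline simulates a cohort end to end: per-subject phantoms (base
SWV varied between subjects), two rest scans, one post-contraction scan
(a uniform SWV increase whose magnitude is negatively coupled to the
subject's simulated eccentric strength, mirroring the direction of the
in-vivo observation), reconstruction, masking with the phantom's
ground-truth segmentation, parameterization and the full statistics
layer. Outputs (NIfTI volumes, long-format map CSV, statistics JSON,
figures, manifest with config hash) are byte-identical across runs with
the same config and seed. The bundled demo uses 16 subjects, a 120 mm
phantom, 2 mm voxels and ~5 s of simulated scanning per subject-session,
sizes chosen so the whole study runs in well under a minute on one CPU.

The simulator reproduces the *structure* of the measurement — pose
tracking error, finite sampling, probe-path coverage, test-retest
variability, between-subject spread — but not ultrasound physics: no
speckle, no anisotropy of SWV with respect to the fibre direction (a
known limitation of the measurement itself), no probe-pressure or
temperature effects, no segmentation error (masks are ground truth).
Passing tests therefore demonstrate correctness of the reconstruction,
parameterization and statistics under a known generative model, not
in-vivo validity of the acquisition.

## Known limitations

* Slice-level polar normalization flattens radial contrast where the
  cross-section changes within a slice (tapered ends); more slices reduce
  the mixing.
* The long-format map CSV (fixed schema) does not carry the origin mode;
  maps read back from CSV default to a centroid-mode config. Cell values,
  counts and shape round-trip exactly.
* The circle-fit origin uses the full outer boundary of the slice, which
  for strongly convex slices approaches the centroid origin; the two
  archetypes differ most for crescent-shaped sections.
* ICC confidence intervals assume the two-way normal model; under the
  cohort generator their empirical coverage is 0.946-0.957 at n = 200,
  k = 2.
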