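# swemap

Three-dimensional, anatomically referenced mapping of skeletal-muscle
shear wave velocity (SWV) from pose-tracked 2D ultrasound elastography.

2D shear wave elastography measures tissue stiffness as the propagation
speed (m/s) of induced shear waves, but a single image samples only a
small window of a large muscle. When the transducer pose is tracked
during a freehand sweep, the stream of 2D SWV frames can be compounded
into a volumetric SWV map, and that volume can be mapped into a
standardized representation of the muscle for within- and across-subject
comparison. `swemap` implements this chain for researchers in muscle
physiology, sports science and biomechanics:

* **Reconstruction** — each valid pixel is projected by its frame's
  rigid pose into a world-aligned isotropic voxel grid; voxel values are
  arithmetic means of their samples (order-independent), with undefined
  voxels kept explicit.
* **Parameterization** — the masked volume is aligned along its
  distal-proximal axis by PCA, cut into S longitudinal slices, and each
  slice is mapped to relative polar coordinates (φ, r) about either a
  least-squares circle centre (vastus lateralis archetype, 8 slices) or
  the slice centroid (biceps femoris long head archetype, 6 slices).
  Cells of uniform relative angular and radial extent hold mean SWV and
  voxel counts.
* **Statistics** — test-retest reliability as the two-way
  random-effects, absolute-agreement, single-measure intraclass
  correlation

      ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

  with F-based 95% CI, the standard error of measurement
  SEm = SD·√(1 − ICC), qualitative bands, whole-muscle and regional
  (inter-regional / inter-subject) variants, paired pre/post contrasts,
  and per-region Spearman association with a covariate such as
  normalized maximal eccentric hamstring strength (N/kg).
* **Synthetic data** — muscle-like phantoms with known SWV fields, a
  freehand-scan simulator (2 Hz frame rate, multi-swipe trajectories,
  tracking jitter, measurement noise) and a test-retest cohort generator
  with closed-form true ICC, so the entire pipeline is testable with no
  data download.

## Worked example

Run the bundled synthetic study — 16 simulated subjects, two rest scans,
one post-contraction scan and a strength covariate:

```bash
swemap demo --out demo_run --seed 7
```

prints

```
whole-muscle ICC(2,1) = 1.000 (95% CI 0.999, 1.000), SEm = 0.004 m/s [very_good]
pre vs post whole-muscle SWV: t = 6.56, p = 9.054e-06
outputs in demo_run
```

The first line is the test-retest reliability of the whole-muscle mean
SWV across the two rest scans: with only tracking jitter, measurement
noise and finite sampling separating the sessions, the subject ranking is
essentially perfectly reproducible and the measurement error is ~0.004
m/s. The second line is the paired t-test of the simulated contraction
effect (a ~0.2 m/s SWV increase), clearly detected across 16 subjects.
`demo_run/` contains the reconstructed volumes (NIfTI), the
parameterized maps (`maps.csv`, one row per cell), `statistics.json`
(regional reliability medians/IQRs, per-axis contrasts and associations),
and figures: per-slice mean-map panels, pre/post axis profiles with SEM
bands, and association curves with significant bins drawn solid.

The same steps are scriptable:

```python
import swemap

phantom = swemap.make_phantom(seed=1)                      # synthetic muscle
frames = swemap.simulate_scan(phantom, swemap.ScanProtocol(noise_sd_mps=0.1), seed=2)
grid = swemap.auto_grid(frames, spacing_mm=1.0)
volume = swemap.reconstruct(frames, grid)                  # freehand 3D compounding
from swemap.reconstruction import mask_from_phantom
points = swemap.apply_mask(volume, mask_from_phantom(phantom, grid))
vl_map = swemap.parameterize(points, swemap.VL_CONFIG)     # (slice, φ, r) cells
print(vl_map.whole_muscle_mean())
```

Individual stages are also exposed as CLI subcommands (`simulate`,
`reconstruct`, `parameterize`, `reliability`, `contrast`, `associate`,
`report`).

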