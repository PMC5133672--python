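# Methods

This note documents the physical model behind the synthetic event
generator, the definitions and numerical choices in the feature extractor
and analysis layer, and the known limitations. Units: lengths in µm, times
in µs, pixel coordinates in (row, col).

## Cell model

A cell is modeled as an incompressible, area-conserving ellipse. At rest it
is a disk of diameter `initial_diameter` with radius `r0`. Inside the
stretching junction the major-axis strain follows Kelvin–Voigt creep under
constant stress:

```
eps(t) = eps_max * (1 - exp(-t / tau))
```

with `tau = creep_time`. The semi-axes are `a = r0 * (1 + eps)` and
`b = r0^2 / a`, so the cross-sectional area `pi*a*b` is exactly conserved
and the axis ratio (deformability) is `(1 + eps)^2`. After the cell exits
the junction the strain relaxes exponentially toward a plastic residue:

```
eps(t) = eps_exit * [(1 - recovery_fraction) + recovery_fraction * exp(-t / recovery_time)]
```

Boundary texture is controlled by low-amplitude cosine modes: the radius
function is multiplied by `1 + sum_k amp_k * cos(k * theta)`. A k-lobed
mode produces a radial trace that crosses its moving average 2k times,
giving direct control over the morphology parameters. Amplitudes are capped
well below the values that would produce self-intersecting boundaries.

Ground truth attached to every event is measured on the *continuous*
perturbed boundary (dense polygon moments, 1440 vertices), using exactly
the same definitions the extractor applies to pixel data. This keeps
generator and extractor comparable even when boundary modes shift the
moment-equivalent ellipse away from the unperturbed `(1 + eps)^2`.

### Default parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| `initial_diameter` | per event | µm | typical mammalian cells 12–18 µm |
| `max_strain` | 0.5 | – | mid-range of soft phenotypes |
| `creep_time` (tau) | 2.0 | µs | microsecond-scale creep at junction stresses |
| `recovery_fraction` | 0.8 | – | mostly elastic recovery with a plastic residue |
| `recovery_time` | 2.0 | µs | recovery on the same time scale as creep |
| `pixel_size` | 0.5 | µm/px | a 15 µm cell spans ~30 px, enough for moment accuracy |
| `frame_interval` | 2.0 | µs | one frame per creep time constant |
| `n_junction_frames` | 5 | – | residence (n−1)·dt = 8 µs ≈ 4 tau |
| `n_pre_frames`, `n_post_frames` | 2, 2 | – | undeformed baseline and relaxation tail |
| `psf_sigma` | 1.0 | px | diffraction-like blur at this magnification |
| `noise_sd` | 0.02 | – | ~2% of full-scale intensity, dark cell on bright field (contrast 0.6) |
| `image_shape` | (96, 96) | px | fits an 18 µm cell at maximal strain with margin |

The junction residence of ~4 creep times is a deliberate compromise: the
strain reaches 98.2% of `eps_max`, while successive frames still change the
boundary by more than the rasterization resolution, so creep-timing
parameters (T1, T2) remain measurable at the default pixel size. Fully
saturating residence makes late junction frames indistinguishable on the
pixel grid. Conversely, recovering `eps_max` itself to tight tolerance
requires both longer residence and finer pixels, because the relative
strain error amplifies boundary error as `d(eps)/eps = (1 + 1/eps)·dl/l`.

### What the generator does and does not emulate

Emulated: creep and recovery kinetics, area conservation, boundary
morphology, PSF blur, additive sensor noise, size/strain population
variability, truncated-Gaussian feature-space populations with exact
largest-remainder mixture allocation.

Not emulated: fluid–structure interaction and actual flow fields, inertial
focusing (one centered cell per event is assumed), cell–cell interactions
and doublets, motion blur, illumination gradients, debris, out-of-focus
events, camera nonlinearity, and any dependence of tau on cell size. The
simulator's shapes are ellipses with small perturbations; strongly
non-elliptical deformation modes are out of scope.

## Feature extraction

Segmentation thresholds each frame (Otsu by default; cells are dark on a
bright background), keeps the largest connected component and fills holes.
The pixel mask is then refined to a sub-pixel boundary: a marching-squares
iso-contour at the half-maximum level, defined as the midpoint of the
median interior and median background intensities. This removes the
threshold-dependent bias of the raw mask boundary under PSF blur (about
+4% on deformability at default settings) at the cost of assuming a
monotone edge profile.

Deformability is the square root of the eigenvalue ratio of the polygon's
second central moment tensor (Green's-theorem evaluation on the sub-pixel
contour) — the axis ratio of the moment-equivalent ellipse. The boundary
trace r(theta) is obtained by casting 360 rays from the area centroid;
shapes whose centroid falls outside the polygon (non-star-convex) are
rejected as degenerate. Morphology roughness is the standard deviation of
the residual around a circular moving average (window 31 samples ≈ 31°,
odd so the average is centered; large enough to pass lobes of interest
into the residual, small enough to track ellipticity) divided by the mean
radius; the crossing count walks the closed residual sign sequence with
zeros compressed.

Per-event parameters: A is the diameter of the area-equivalent circle
median-pooled over pre-junction frames; the junction interval runs from the
annotated arrival index to the global deformability maximum; D3 is that
maximum and T1 its delay after arrival; T2 is the maximal frame-to-frame
strain rate; S1/S2 are strains at maximum and at exit; M1/M2 come from the
first pre-junction frame, M3/M4 from the D3 frame; AR1 is the area ratio of
the D3 frame to the pre-junction median. Events where more than 20% of
frames fail segmentation are rejected with a reason code rather than
guessed at.

## Analysis

- **Standardization**: features are z-scored with training-set statistics;
  constant columns are excluded with a warning.
- **EMGM**: k-means initialization (10 restarts), full covariances with a
  1e-6 diagonal ridge for invertibility, convergence when the
  log-likelihood changes by less than 1e-6·n. The log-likelihood trace is
  retained so monotonicity is checkable.
- **Clustering error**: within-class sum of squared distances to class
  means divided by `n * ||m1 - m2||^2`. The normalization makes the metric
  scale- and rotation-invariant and independent of sample size.
- **Feature elimination**: greedy backward removal of the feature whose
  deletion yields the best metric (clustering error, or 1 − CV accuracy of
  an SVM); ties resolve to the lowest feature index for determinism. Note
  that on perfectly separable data the SVM-mode metric is identically zero
  and the ordering degenerates to the tie-break.
- **SVM**: scikit-learn SVC, C = 1, linear or Gaussian kernel with the
  median heuristic `gamma = 1 / (2 * median(pairwise distance)^2)`;
  seeded stratified 5-fold cross-validation reports pooled accuracy;
  multiclass is one-vs-one.
- **ROC/AUC**: every distinct score is a threshold (ties grouped), AUC by
  the trapezoid rule — equal to the tie-corrected Mann–Whitney statistic
  up to float summation order.
- **Gating**: size gate `A < 15 µm` and diagonal gate `D3 > 1.4 and
  A < 15 µm` use strict inequalities. The quantile gate is the Mahalanobis
  ellipse of the reference population; its radius is the distance of the
  `ceil(containment * n)`-th closest reference point (default containment
  0.75), so the gate contains exactly that many reference points.
- **Mixtures and LOD**: mixture compositions use largest-remainder
  allocation (exact integer counts); the spike-response slope is ordinary
  least squares of predicted vs spiked fraction; the limit of detection is
  `sd_max / slope` with `sd_max` the largest replicate SD across ratios.
- **Projections**: PCA with a deterministic sign convention (largest
  loading positive); LDA solves the generalized eigenproblem
  `Sb v = lambda Sw v` with a 1e-6 ridge on `Sw`.
- **Stiffness calibration**: log-linear fit `log10(E) = alpha + beta * D`
  on ≥3 bead standards (supported range 0.2–40 kPa); mapping outside the
  fitted deformability range or a fit with R² < 0.5 raises a warning.
- **Reproducibility**: all pipeline stages derive their seeds as
  `sha256(f"{global_seed}:{stage}") mod 2^31-1`, so runs are bit-identical
  for a given seed and stages are independently re-runnable.

## Limitations

- Crossing counts (M2, M4) on rasterized data are resolution-sensitive:
  contour jitter near the moving average adds spurious crossings, so only
  relative comparisons at fixed imaging settings are meaningful; the
  simulator's analytic 2k-crossing property is exact only for the
  continuous boundary.
- T1 resolution equals the frame interval; once creep saturates below the
  pixel scale, the deformability maximum ties across late frames and the
  first occurrence is reported.
- The quantile gate assumes an approximately elliptical reference
  population; for singular covariance it falls back to a box gate with a
  warning.
- Clustering error and the EMGM defaults target two-component structure;
  k > 2 clustering works but the error metric is defined for two classes.
- The stiffness calibration inherits the bead standards' validity range;
  extrapolated moduli are flagged, not forbidden.
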