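# Methods

This note describes the models implemented in `cncorr`, their assumptions,
the default parameters and why they were chosen, what the synthetic data
does and does not emulate, and the numerical choices that matter for
reproducibility. It makes no empirical claims beyond what the test suite
and `scripts/acceptance.py` compute.

## 1. CN-correlation

### Model

A movie supplies, per frame, the centroid of the cell body and of the
nucleus (µm). For each frame-to-frame step:

- **CCD** — the magnitude of the cell-centroid displacement (µm/frame).
- **NCD<sub>∥</sub>** — the nucleus displacement projected onto the unit
  vector of the cell-centroid displacement (µm/frame, signed).
- **angle** = `atan2(CCD, NCD_par) · 180/π`, in [0°, 180°].

CCD is non-negative by construction, so the angle encodes the ratio of
cell-boundary motion to co-directional nucleus motion:

- rigid translation (nucleus moves exactly with the cell): CCD =
  NCD<sub>∥</sub> → **45° exactly**;
- cell-boundary motion with a stationary nucleus: NCD<sub>∥</sub> = 0 →
  **90° exactly**;
- nucleus moving against the cell direction: NCD<sub>∥</sub> < 0 →
  obtuse angles (e.g. CCD 1, NCD<sub>∥</sub> −0.5 → 116.565°).

The map is invariant to rotation and translation of the lab frame (the
test suite checks this to 10⁻⁶ over random rotations).

### Assumptions

- Centroids are available in physical units on a common clock; frames are
  equally spaced.
- Steps with CCD below a motion floor (`MOTION_FLOOR_UM = 1e-3` µm) carry
  no directional information and are excluded; they would otherwise
  contribute angles dominated by localization noise. The floor is far
  below any real per-frame displacement at typical magnifications, so it
  only removes numerically degenerate steps.
- Nucleus motion orthogonal to the cell direction is deliberately ignored
  (projected out): the analysis quantifies nucleus transport along the
  migration axis.

### Mask input

`CellMovie.from_masks` converts per-frame binary cell/nucleus masks to
centroids (intensity-free first moments) scaled by the pixel size, so the
same geometric identities hold for mask movies.

## 2. Unified normal-mixture (UNM) decomposition

Pooled step angles from one condition are fit with a k-component Gaussian
mixture by expectation–maximization, written directly (the mixture
structure — fixed widths, signature-anchored components — is the core of
the method, not an off-the-shelf fit; `sklearn.mixture.GaussianMixture`
is used only as an independent oracle in the tests).

- **Fixed component width** (`sd_mode="fixed"`, `fixed_sd = 8.0°`): each
  migratory activity produces a tight angle band whose spread reflects
  per-step heading jitter, not activity identity. Fixing the width makes
  weights comparable across conditions and prevents one broad component
  from absorbing its neighbours. `sd_mode="free"` is available for
  diagnostic comparison with a generic mixture fit.
- **Signature anchors**: components are initialised from, and labeled by,
  a set of signature angles — nucleus_forward 25°, trailing_edge_detachment
  45°, simultaneous_de_pro 65°, leading_edge_protrusion 90°,
  side_protrusion 115°, leading_edge_retraction 145°. For a k-component
  fit, every size-k subset of the anchors is used as an initialisation and
  the best log-likelihood wins; fitted components are assigned to anchors
  by minimum-cost matching (`scipy.optimize.linear_sum_assignment`), so
  labels are stable and the fit cannot silently relabel activities.
- **k selection**: if `k` is not given, k is chosen by BIC over the
  admissible range.
- **Sample-size guard**: fits require at least 50 angles with some
  distinct values; below that, mixture weights are not meaningful.

### CMPI

`cmpi(profile, cutoff=75.0)` summarises productive nucleus transport:
the hourly occurrence of steps with angle below the cutoff times the mean
NCD<sub>∥</sub> of those steps (µm/h). 75° sits between the rigid-motion
band (≈45°) and the protrusion band (≈90°), so it counts steps where the
nucleus genuinely advances. `relative_sem` and `convergence_check` report
how the standard error of a cohort mean shrinks with cohort size and the
smallest size at which it stays below a threshold.

## 3. Phenotype descriptors and period partitioning

### Descriptors

From a single-cell binary mask and pixel size:

- **area** — foreground pixel count × pixel_size² (µm²);
- **aspect ratio** — major/minor axis of the second-moment best-fit
  ellipse (dimensionless, ≥ 1);
- **circularity** — 4πA/P², where the perimeter P is measured on a
  simplified sub-pixel boundary polygon (below);
- **instantaneous speed** — displacement over non-overlapping 3-minute
  windows (µm/min); 3 minutes suppresses sub-interval wiggle while
  tracking genuine translocation.

**Perimeter estimation.** The marching-squares contour
(`skimage.measure.find_contours`) is simplified with Douglas–Peucker
(`approximate_polygon`, tolerance 1.0 px) before measuring its length.
The raw staircase contour overestimates oblique boundaries by up to ~8%
(a rasterized disk scores circularity ≈ 0.91 instead of 1); a 1-px
tolerance removes the staircase without rounding corners, giving a disk
circularity of ≈ 0.99 and a square exactly its analytic π/4 to within 2%.
Crofton-style perimeter estimates were rejected because they bias
axis-aligned polygons (square ≈ 0.88 vs π/4 ≈ 0.785).

### Three-period partition

`PeriodPartitioner` splits an (n_frames × n_params) time course into
three contiguous periods. Each parameter is z-scored (so the split is
invariant to per-parameter affine rescaling), and all boundary pairs are
searched exhaustively. The split is decided by least squares — the pair
maximizing the between-group sum of squares, equivalently minimizing the
pooled within-group residual. The decision statistic

P = (⟨Group2⟩ − ⟨Group1⟩)² · (⟨Group3⟩ − ⟨Group2⟩)²

summed over parameters is reported for the chosen split and breaks exact
least-squares ties. Exhaustive O(n²) search is exact and fast at realistic
frame counts, so no stochastic restarts are needed; a constant series is
reported as equal thirds with score 0.

### Cohort alignment

`align_timeframes` maps each movie's first detected division onto one of
two reference divisions (nearest by a pivot, default the reference
midpoint) and returns per-movie clock offsets; movies without a detected
division are excluded with a warning.

## 4. Cytoskeleton image analysis

### Foreground extraction

`extract_cell_and_nucleus_masks` fits a Gaussian background model by
sigma-clipping (seeded from the below-median half of the intensities),
thresholds at mean + 3σ, and keeps the largest connected component. A
minimum-area floor (25 px) rejects the ~0.1% of background pixels that
clear a 3σ threshold by chance; a blank image therefore raises instead of
returning a speck. The nucleus is segmented inside the cell mask at a
user-supplied threshold.

### Stress fibers

Oriented ridge filtering (12 orientations, σ = 1 px) → adaptive local
threshold (31-px block) with a global floor → skeletonization → fragment
graph. Skeleton fragments are **reconnected across gaps** only when all
criteria hold between endpoint pairs: distance ≤ 8 px, orientation
difference ≤ 18°, and intensity and width each within 1.2-fold. The tests
verify each criterion is individually necessary and that reconnection can
only reduce the fiber count.

### Focal adhesions

Background subtraction → Gaussian matched filter (σ = 1 px, matching the
adhesion spot scale) → Otsu threshold → opening/closing by reconstruction
→ distance-transform watershed to split touching adhesions. The matched
filter exists because at signal-to-noise ≈ 5 single noise pixels
otherwise survive morphology as spurious detections; a symmetric 1-px
Gaussian leaves noise-free centroids unchanged (sub-pixel symmetric blur)
while suppressing single-pixel excursions.

### Localization profile

`normalize_localization` maps each feature centroid to a normalized radial
coordinate in [0, 1] (0 = cell centroid, 1 = cell edge along that ray,
via the boundary distance in the centroid-to-feature direction) and
summarises angular anisotropy; the profile is rotation-invariant to within
raster error (checked at 5%).

## 5. DNA-content phase fitting

A 50-bin histogram of per-cell DNA content is fit in three sequential
stages: a Gaussian G1 peak, a Gaussian G2/M peak, and an S compartment
modeled as a **non-negative quadratic in Bernstein form** bridging the two
means (Bernstein coefficients ≥ 0 guarantee non-negativity without
inequality-constrained optimization). Bins are weighted by Poisson
counting error. `constrain_ratio=True` pins the G2/M mean at exactly twice
the G1 mean; unconstrained fits recover a ratio near 2 on well-formed
data. Phase fractions are the compartment areas over the histogram
support, normalized to 100%. Fits require ≥ 500 cells and a resolvable
bimodal structure; otherwise they raise. `pick_harvest_times` selects, per
phase, the time point maximizing that phase's fraction (ties go to the
earliest hour).

## 6. Synthetic data

Generators (`cncorr.simulate`) exist so every analysis has labeled ground
truth. All randomness flows from explicit integer seeds;
`child_seeds(master, n)` derives independent 31-bit child seeds via
`numpy.random.SeedSequence.spawn`, so stages never share a stream.

What the synthetic data **does** emulate:

- per-step migratory activities drawn from phase-specific mixtures of
  signature angles with 8° jitter, converted into consistent cell/nucleus
  centroid steps (so the analysis chain can be checked against exact step
  labels);
- raster rendering of cell/nucleus disks at 0.3 µm/px, with optional
  centroid noise;
- cytoskeleton images with known fiber segments (length, orientation,
  optional gaps of controlled size/contrast) and adhesion spots on
  Gaussian background noise;
- DNA-content populations: G1 ~ Normal(µ, cv·µ), G2/M ~ Normal(2µ, 2cv·µ),
  S uniform between µ and 2µ with the same relative noise;
- piecewise-constant phenotype series with known change points.

What it **does not** emulate: cell shape dynamics (cells are rendered as
disks), fluorescence photophysics (bleaching, shot-noise statistics beyond
additive Gaussian), cell–cell contact, mitotic rounding, debris/doublets
in DNA histograms, or stage drift. Conclusions about segmentation
robustness therefore transfer to real images only to the extent that the
additive-Gaussian noise model holds.

## 7. Numerical and reproducibility choices

- EM restarts over all signature subsets make the mixture fit
  deterministic given the data; where cohort statistics are reported, the
  median over a small set of fixed generator seeds is used to damp
  single-cohort sampling noise.
- Douglas–Peucker tolerance 1.0 px for perimeters (see §3).
- Rotation-invariance tests rasterize rotated shapes analytically rather
  than resampling images, because interpolation (nearest or linear)
  roughens boundaries by several percent and would test the resampler,
  not the descriptor.
- Pipeline runs (`cncorr run`) write SHA-256 digests of every artifact;
  reruns with an identical config are byte-identical.

## 8. Limitations

- The angle statistic ignores nucleus motion orthogonal to the migration
  axis; activities expressed mainly in that direction are invisible.
- Fixed 8° component widths assume the jitter scale is condition
  independent; strongly different imaging noise would bias weights.
- The three-period partition assumes exactly three contiguous regimes on
  one shared time axis.
- The DNA-content model has no sub-G1 (apoptotic) or >4N compartments.
- Fiber reconnection thresholds (8 px, 18°, 1.2-fold) are tuned for the
  synthetic point-spread scale; different optics may need different
  values via `FiberParams`.
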