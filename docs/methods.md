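# Methods

## Problem and model

High-speed biplanar videoradiography images a moving joint with two
synchronized X-ray chains (source, image intensifier, video camera).
Registering a 3D bone model — a point cloud segmented from MRI or CT —
to each synchronized radiograph pair recovers the six-degree-of-freedom
bone pose over time. `bipreg` implements a one-step *projection*
estimator for this problem: the model is transformed, projected into
both images through the calibrated collinearity model, and the
transformation parameters are estimated by directly minimizing the 2D
distances between projected model points ("slave" data) and extracted
image measurements ("master" data):

    sum_i || (x_i^p, y_i^p) - (x_i^m, y_i^m) ||^2  ->  min.

This avoids the intermediate 3D reconstruction of the classical
two-step approach (triangulate each marker, then fit a rigid transform
with Horn's closed-form absolute orientation), in which first-step
errors propagate into and bias the second step. The two-step method is
implemented as the comparison baseline (`rsa_register`).

### Coordinate systems and the camera model

Object space is metric (mm); image measurements and the principal
distance are in pixels. Each imaging chain is a lumped pinhole with
exterior orientation (perspective center `XC, YC, ZC`; object-to-image
rotation `M = R3(kappa) R2(phi) R1(omega)`, right-handed active
rotations, column-vector convention) and interior orientation
(principal point `xp, yp`; principal distance `c`). The collinearity
condition projects an object point `X` via `(U, V, W) = M (X - C)` and

    x = xp - c U / W + dx,    y = yp - c V / W + dy,

with `(dx, dy)` an optional distortion-correction provider (identity by
default; bivariate polynomial and bilinear lookup-grid providers can be
loaded from the calibration file). The negative sign is taken literally;
image `y` follows the image-space `v` axis, and any flip into raster row
order is an IO concern. Calibration files must declare units (mm / px)
and the angle unit; nothing is converted implicitly.

### Transform models

The rigid transform is `X = M(kappa_t, phi_t, omega_t) p + t` with the
same Euler factorization. The non-rigid variant adds a single scale
factor applied about the model centroid, `p -> p_bar + lam (p - p_bar)`,
*before* the rigid transform, so the centroid is invariant under the
scaling and `lam = 1` reduces exactly to the rigid model. The scale
factor exists to absorb a systematic radial offset between detected
radiograph edges and the true bone boundary (see "inward-edge
phenomenon" below); it is not a physical deformation, which is why 3D
marker accuracy reports (`accuracy_report`) apply only the rigid part of
a scaled result.

### The estimator

Rotations inside the solver are unit quaternions (scalar first),
avoiding gimbal lock and trigonometric Jacobians. The design matrix
contains the analytic derivatives of the projected coordinates with
respect to `(Xt, Yt, Zt, q0..q3[, lam])`, using the 9-term homogeneous
quaternion-to-matrix expansion; the unit-norm condition
`g = q0^2+q1^2+q2^2+q3^2 = 1` enters as an extra gradient row, handled
as a pseudo-observation with weight 1e6 relative to unit-weight pixel
observations, followed by renormalization of the updated quaternion.
Both cameras' residuals enter with equal unit weight.

Gauss-Newton steps are accepted only if the objective does not
increase; otherwise Levenberg-Marquardt damping (`mu diag(N)`, mu
growing from 1e-4 by factors of 10) is applied, which makes the
objective non-increasing over accepted steps. Convergence is declared
when the effective parameter update — measured *after* quaternion
renormalization, since the weighted constraint leaves a small radial
component that renormalization removes each step — falls below `tol`
(default 1e-8 in mm / quaternion units), with a stagnation exit when an
accepted step changes the objective by less than 1e-10 relatively.

The outer loop alternates: project the model, establish nearest-point
one-to-one correspondence (each master point claims its nearest
projection; contested projections keep the shortest claim), solve to
convergence, and reject outliers. A matching pair is flagged as a
mismatch when its residual distance exceeds the mean of the active
distances by more than `outlier_k = 3` standard deviations; the
centered form (rather than a raw `3 sigma` threshold) keeps an
all-equal residual set intact. Rejection is applied batchwise once per
outer round.

Per-parameter precisions come from the inverse normal matrix scaled by
the a-posteriori variance factor `sigma0^2 = r'r / (2 n_active -
n_params + 1)` (the constraint restores one degree of freedom);
quaternion covariance is propagated to Euler-angle standard deviations
in degrees by numeric differentiation of the conversion. A 100-replicate
Monte-Carlo check at 0.5 px noise shows the predicted standard
deviations within about 12% of the empirical scatter.

### Automatic initialization

Iterative registration has a limited rotational capture range, so a
coarse search runs a capped registration (10 re-matching rounds, loose
tolerance) from 64 starting poses — a 4x4x4 Euler grid with each angle
in {-135, -45, 45, 135} degrees, covering rotation space with a
geodesic radius of about 63 degrees — all sharing one translation guess
(default: the closest-approach midpoint of the two optical axes). The
start with the smallest registration RMSE wins, ties broken by lowest
index. During the coarse phase, correspondence uses a globally optimal
assignment (Hungarian algorithm) rather than greedy nearest-point
matching: with only 6-7 unlabeled beads and starts tens of degrees from
the truth, greedy matching reproducibly locks into near-flip
permutations that no start escapes, whereas optimal assignment recovers
all of 50 random orientations in the validation run. Full registration
from the winning start keeps the standard nearest-point rule.

### Marker extraction

Steel beads (3 mm diameter) appear as small dark elliptical footprints.
The pipeline is Canny edge detection (hysteresis thresholds as
fractions of the maximum gradient magnitude), 8-connected component
grouping, a direct least-squares conic fit constrained to an ellipse
per component, and a closed-interval gate on the semi-axis lengths
(defaults 2-10 px, the bead footprint over a plausible range of system
magnifications). Edge pixels are refined to sub-pixel positions by a
parabolic fit to the smoothed gradient magnitude along the local
gradient direction before the ellipse fit; this removes a grid
quantization bias that otherwise reaches 0.15 px on 8-px footprints,
bringing center recovery to better than 0.03 px on rendered fixtures.
Markers inside an under-exposed region can evade detection entirely
(their local contrast falls below the gradient thresholds); when fewer
than the expected number of targets are found, detection is retried
once on a linearly intensity-enhanced copy and the two sets are merged,
de-duplicating centers closer than the largest accepted semi-major
axis.

### Model-based (silhouette) registration

Without implanted beads the master data are bone edge points. Because
radiograph contrast is low and no single parameterization of the Canny
detector captures the whole boundary, a bank of 25 filters (smoothing
scales sigma in {4..8} px crossed with 5 hysteresis pairs spaced
geometrically from loose to strict) is applied and the union of
responses is thinned to one-pixel chains (morphological thinning;
provenance per filter is retained). Edges are pose-independent, so the
bank runs once per image.

The slave data are the outline points of the projected model cloud,
extracted on an occupancy grid: cell size defaults to the median
nearest-neighbor spacing of the projection; the grid is morphologically
closed (radius adapted to the uniform-coverage spacing, so rim-dense /
interior-sparse projections do not shed spurious interior cells, and
computed on a padded copy so the border is not eroded) and hole-filled;
cells with an empty 4-neighbor are boundary cells; each boundary cell
is represented by its most outward member point (outward estimated from
the occupancy of the 3x3 neighborhood), which keeps the outline on the
boundary of the projected set rather than half a cell inside it. Every
outline point carries its 3D model index.

Matching is the stated one-to-one rule (edge points claim nearest
outline points; contested outline points keep the shortest claim —
injective in outline points), followed by the same constrained solve.
Three loop-control choices differ from a naive transcription and exist
for convergence reasons:

- **Coarse-to-fine matching.** A short pass with a 4x outline cell
  precedes the fine pass. Discrete outline re-sampling makes the
  objective landscape rough at the sub-pixel scale; without the coarse
  pass, starts 3 mm / 3 degrees away reproducibly stall in local minima
  a few tenths of a millimeter off.
- **Persistent, bounded rejection.** An edge point flagged by the
  3-sigma rule stays excluded for the rest of the run, and new
  exclusions are only added during the first `reject_rounds = 5`
  re-matching rounds. Re-deriving rejections from scratch each round
  trims the residual tail forever (each trim shifts the pose, which
  reshuffles the tail) and the loop has no fixed point.
- **Outer convergence on parameter stability** (`outer_tol = 1e-5` mm /
  quaternion units across re-matching rounds) rather than exact
  correspondence-set equality, which flickers at machine-irrelevant
  amplitude with hundreds of edge points.

### Accuracy and precision metrics

`accuracy_report` gives parameter differences (mm, degrees) and the RMS
of per-bead coordinate differences along each object-space axis plus
the Euclidean-distance RMS, comparing two registrations of the same
cloud — typically model-based against the marker-based ground truth.

`precision_rms_3d` is the no-ground-truth precision measure: each
matched edge point is lifted into object space along its viewing ray at
the image-space depth (`W` coordinate) of its matched, registered model
point, and the RMS of the 3D distances to those model points is
reported, overall and per axis. On a noiseless, perfectly registered
fixture it is zero to machine precision; a 1 mm pose offset produces an
RMS equal to its direct recomputation (the metric reflects how the rig
geometry projects the offset, about 0.87 mm for the default 60-degree
rig).

## Synthetic study conditions

The real study data (a 3D-printed knee with implanted beads; an in vivo
knee) are not available, so the package generates equivalents whose
parameters follow the experimental description where one exists:

- **Phantom** — an elongated ellipsoidal shaft with two condyle-like
  lobes and one small off-axis lobe (femur- or tibia-like variants),
  sampled as a surface point cloud (default 1500 points; 4000 for
  silhouette work), with 6-7 surface beads at >= 25 mm mutual
  separation. The off-axis lobe guarantees no 180-degree flip symmetry,
  so all six pose parameters are identifiable.
- **Rig** — two cameras converging on the origin at 60 degrees, 1000 mm
  from the origin, principal distance 2800 px, 1008x1008 px images
  (half the real system's 2016 px resolution, to keep the default runs
  fast; image-space quantities in px are resolution-independent, mm
  errors scale with px size).
- **Marker images** — beads drawn as projected disks (4x supersampled)
  multiplying a gently textured bright background; an optional
  low-intensity circular region reproduces the under-exposed-corner
  failure mode of edge detection. Ground-truth centers are returned.
- **Silhouette images** — the projected cloud rasterized, closed,
  hole-filled, optionally eroded by `inward_offset_px`, then blurred.
  The erosion emulates the inward offset of edges detected at large
  smoothing scales; registering against such images drives the
  estimated scale factor below one, the phenomenon the non-rigid mode
  exists to absorb.
- **Trials** — per-epoch poses rotating about the vertical (Y) axis in
  fixed increments (turntable emulation), i.i.d. Gaussian pixel noise
  (default sigma 0.5 px, a free simulation parameter) added to the
  extracted 2D bead coordinates. Noise has two distinct injection
  points: coordinate-level (for estimator studies) and intensity-level
  (in the renderers, for image-pipeline studies).

What these fixtures do *not* emulate: X-ray attenuation physics (no
DRRs), scatter, intensifier distortion (the correction provider is
exercised with synthetic polynomial/grid terms, not a physical model),
overlapping anatomy, or frame-to-frame image correlation. Passing tests
therefore demonstrate the correctness and internal consistency of the
geometry, estimator, and pipelines under controlled conditions — not
detector robustness on clinical images.

## Numerical choices and degenerate inputs

- Termination: inner `tol` 1e-8 (mm / quaternion units), 100 iterations
  max; outer stability 1e-5; all configurable.
- Constraint weight 1e6; an internal Lagrange-elimination variant is
  not exposed.
- Projection raises on points in the principal plane (`|W| < 1e-12`,
  reporting the offending index) and at the perspective center;
  triangulation raises on parallel rays; Horn's method raises on
  collinear configurations; the solver raises on rank-deficient normal
  matrices, reporting the approximate null direction.
- A scale estimate outside [0.5, 2] emits a warning rather than an
  error (the registration may still be diagnostically useful).
- Semi-axis gates are closed intervals (boundary values kept).
- Trial-constant scale: per-epoch estimates are averaged and every
  epoch is re-registered with the scale frozen at the mean
  (`fit_constant_scale`); freezing is implemented by scaling the model
  once and solving the rigid problem.

## Known limitations

- The one-to-one matcher is order-free but resolution-limited: sub-cell
  pose wander (~5e-3 mm) is intrinsic to discrete outline re-sampling,
  and the reported `converged` flag can be False on rendered images
  even when the pose estimate is at its attainable accuracy; the
  `message` field says why.
- Rotation about the bone's long axis is weakly constrained by
  silhouettes (near-symmetric profiles), with errors several times
  larger than the other angles — visible in both the synthetic runs and
  the original experiments this package models.
- The coarse search assumes the model cloud is expressed about its
  centroid when deriving the default translation guess.
- PLY storage is single precision (trimesh writer); bead-to-cloud
  matching in the readers tolerates 1e-3 mm accordingly.
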