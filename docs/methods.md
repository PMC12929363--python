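# Methods

## Problem

`msmcal` estimates the external calibration (positions and orientations)
of a multi-camera rig observing a common floor, given known per-camera
intrinsics and lens distortion. The intended setting is 3D surgical scene
reconstruction in an operating room: a handful of cameras with wildly
different positions and optical zoom levels, little image texture, and no
time for an operator to wave a calibration board. Correspondences come
from *multi-scale markers* (MSMs): a ceiling projector displays square
fiducials on the floor, each marker repeated at several scales
λ ∈ Λ about a fixed center, so that every camera — from a wide overview
to a tightly zoomed close-up — can decode at least one scale of every
marker it looks at. Because all projected instances of one marker share an
exact common center, each marker yields one physical 3D point `X_k` with
image observations `x_{c,k}` across cameras.

## Marker model

A scale instance is the image of the base pattern under the planar scaling
`s(x) = λ(x − p) + p`, which fixes the center `p` exactly; that fixed
point is the entire trick. The fiducial family (`msq25`) is a 7×7-cell
square: one-cell black border, 5×5 payload carrying a 12-bit symbol id and
a 13-bit mixing checksum. Symbol ids are pre-filtered so that (a) no
payload is confusable with a valid codeword under 90° rotation and (b) no
payload is nearly solid black/white (5–20 white bits), which keeps every
marker detectable as a coded square. The default projection schedule is
100 arrays × 32 markers on an 8×4 base grid, each array offset by one cell
of a 10×10 sub-grid, giving 3200 distinct floor points; the default scale
set Λ = {1.0, 1.4, 2.0, 3.0, 4.0, 6.0, 8.0} spans 5 cm–40 cm markers at
the 5 cm base side, with a documented 3-scale preset {1, 2.8, 8} for fast
acquisition.

The marker center in an image is computed as the intersection of the
imaged diagonals of the outer quad. This is a projective invariant:
`center(H·corners) = H·center(corners)` for any homography `H`, so centers
measured at different scales, zoom levels and viewpoints all refer to the
same floor point. Per-scale centers of one (camera, marker) pair are fused
by a coordinate-wise median with MAD-based rejection (3.5 robust sigmas,
absolute gate 2 px).

One physical subtlety: a ceiling projector aimed down inverts its vertical
axis on the floor, and a camera above the floor inverts it again. The
default projector-to-floor map therefore reflects the v axis, so cameras
observe markers in canonical (unmirrored) orientation; the decoder
deliberately does not search mirrored payloads.

## Calibration algorithm

The objective is the bundle adjustment

    min over {P_c}, {X_k} of  Σ_c Σ_k v_{c,k} ‖π(K_c, P_c, X_k) − x_{c,k}‖²

with intrinsics `K_c` fixed and poses world-to-camera (`x_cam = R X + t`).
It is solved incrementally, as in structure-from-motion, with one decisive
difference: all points lie on the floor plane, which is a degenerate
configuration for essential/fundamental-matrix initialization. The initial
pair is instead recovered by estimating the inter-image homography with
RANSAC (3 px threshold applied in normalized coordinates, converted per
camera as `3 / sqrt(fx·fy)` using the longer-focal camera; one-sided
transfer error in the second image) and decomposing it analytically into
`{R, t/d, n}` candidates.

The candidate is selected by cheirality: triangulated correspondences must
have positive depth in both views and lie on the visible side of the
plane, ties broken by transfer error. A single homography occasionally
admits **two** exactly consistent decompositions (the classical
two-solution ambiguity of planar relative pose — unresolvable from the
pair alone). When the top two candidates are near-ties, a third camera
arbitrates: each hypothesis is triangulated and the third view is
registered by PnP; the hypothesis with more support wins.

Pairs are ranked by the pairwise *view score*: for levels l = 1…6 the
image is split into 2^l × 2^l cells and each occupied cell contributes
2^l, computed on the correspondences shared by the pair, taking
min(score_a, score_b). The same score (on observations of already
triangulated points) orders camera registration. Each registration is a
planarity-aware PnP RANSAC — near-planar point clouds (thickness < 10% of
spread) use a 4-point plane-homography minimal solver, general clouds a
6-point DLT, both refined by Levenberg–Marquardt — followed by
triangulation of newly covered tracks (min. triangulation angle 1°,
positive depths, reprojection < 4 px) and an intermediate bundle
adjustment; every third registration re-attempts previously failed
tracks. If the best-scoring camera cannot be registered yet, the next
candidates are tried; cameras that never register are reported, not
raised. After the loop: final BA, one residual-based outlier pass
(drop observations beyond 4 robust sigmas, then drop points left with
< 2 views), final BA again.

**Gauge.** The first initial-pair camera is frozen at identity and the
reconstruction is rescaled after every adjustment so the initial-pair
baseline is exactly 1. Metric scale is unobservable from image
measurements alone; accuracy is always evaluated after Sim(3) (Umeyama)
alignment on camera centers, with rotation errors as geodesic angles after
applying the fitted rotation.

**Coplanarity constraint.** Optionally the points are reparametrized as 2D
coordinates in a floor plane (initialized by total least squares, refined
jointly via 3 global parameters: two tilts and an offset). This is a hard
constraint, not a penalty: returned points satisfy the plane equation to
machine precision. On floor data the unconstrained and constrained
variants give closely comparable poses.

## Bundle adjustment engine

A purpose-built sparse Levenberg–Marquardt with Schur complement:
camera blocks (6 params, axis-angle increments composed onto the current
rotation), structure blocks of 3 (free points), 2 (+3 global plane
parameters), or 6 (rigid boards of known local geometry). The Schur cross
term factorizes through per-(block, camera) sums of the mixed Jacobian
products, so no observation-pair enumeration is needed; all heavy products
are batched BLAS calls, and a 10-camera / 3200-point / 26k-observation
iteration costs tens of milliseconds. Damping multiplies the normal-matrix
diagonals; steps that increase the objective are rejected (the returned
objective never exceeds the initial one). Termination: relative objective
change < 1e-12 or the iteration cap (25 intermediate, 100 final). The
plane's 3 global parameters use central-difference Jacobians; everything
else is analytic.

## Synthetic study

The simulator reproduces the acquisition geometry used for validation:
six far-field cameras on a circle of radius 2.8 m at height 2.8 m and
four near-field cameras at radius 1.2 m, height 1.4 m, azimuths uniform
per repeat, optical axes through the scene center, up-vector = world z
projected into the image plane (no roll). All simulated cameras are
1920×1080 with 915 px focal length (mild radial distortion k1 = −0.1,
k2 = 0.02, applied on projection and removed by the pipeline's
undistortion).

Three point distributions are compared at matched per-camera observation
counts (~3000 far / ~2000 near, subsampled uniformly per camera; counts
within 10% of target):

* **board_volume** — 1.20 × 0.85 m boards with a 12×8 inner corner grid,
  uniform random poses inside a cylinder (r = 3 m, h = 1.5 m), only
  front-facing boards observed; calibrated by the board-constrained
  (gold standard) adjustment where points are rigidly attached to 6-dof
  board poses. Initialization: per-(camera, board) planar pose keeping
  both flip hypotheses (the fronto-parallel two-fold ambiguity), an
  ambiguity-aware spanning tree of the camera–board graph, then a
  multi-view refit of every board pose that resolves the flips.
* **board_floor** — the same board slid flat on the floor inside a 3 m
  disc (z = 0, random planar pose), same calibration.
* **grid_floor** — 3200 points in a regular 80×40 grid over 4.0 × 2.25 m
  of floor (the area a ceiling projector covers), calibrated by the
  incremental marker pipeline *without* the coplanarity constraint.

Observations get isotropic zero-mean Gaussian pixel noise; the default
sweep is σ ∈ {0, 0.25, 0.5, 1.0} px (the σ grid is a config list — the
reference experiment reports a sweep without printing its exact values).
Per-repeat seeds derive deterministically from the master seed. The
headline finding this study checks: a planar floor distribution does not
degrade calibration relative to the moving-board gold standard (RMSEs of
the same order across scenarios), while board_volume has the shortest
mean track length because random board orientations limit visibility to
camera subsets.

The acceptance suite runs 20 repeats per scenario at σ = 0.5 px
(a scaled-down replicate of the 200-simulation reference experiment; the
acceptance script defaults to 8 repeats per scenario). Zero-noise
exactness is checked at rotation/translation RMSE < 1e-5 (deg / m).

## Rendered end-to-end fixture

A fully synthetic dataset exercising the image path: a reduced schedule
(9 arrays × 8 markers, scales {1, 2.8, 8}, 2.4 × 1.35 m floor patch at
800 px/m) rendered to projector frames (4×4 supersampled rasterization —
lower supersampling quantizes edge coverage and biases detected centers
by ~0.25 px), warped into five camera views by exact floor-plane inverse
mapping (bilinear, 2× supersampled, distortion honoured): two far-field
and two near-field 915 px cameras plus one 4000 px long-focal camera
giving a ~6x appearing-scale gap to the far-field views. The far cameras decode only large scales, the zoomed
camera loses the largest scale to clipping — the complementary-coverage
mechanism. Detection coverage is scored against geometric visibility
(center in view with margin 0.6× the smallest instance's projected size:
a marker whose every instance is clipped is not detectable in principle).
The fixture must calibrate fully with rotation RMSE < 0.1°.

What the synthetic paths do *not* model: photometric effects (projector
brightness falloff, floor reflectance, ambient light, sensor noise and
blur), rolling shutter, imperfect intrinsics, non-planar floors, and
real-image corner localization error beyond rasterization. Passing tests
therefore validate the geometry, the decoding logic and the optimization,
not photometric robustness.

## Numerical choices and conventions

* Pixel coordinates are 0-based pixel centers, x right, y down; CSV
  artifacts use one header row, comma separator, '.' decimal; pose files
  embed the world-to-camera convention string and the seed.
* Distortion model `[k1, k2, p1, p2, k3]`; detection and diagonal
  intersection run in raw (distorted) images, the fused center is
  undistorted once (Newton iteration to 1e-14) and all multi-view
  geometry operates on ideal pixels.
* RANSAC: adaptive iteration count at confidence 0.999, capped at 10 000,
  seeded generators everywhere; identical inputs + seed give bit-identical
  outputs.
* Triangulation: grouped linear DLT normal equations, Gauss–Newton
  refinement; ill-conditioned when the maximum pairwise baseline is
  below tolerance.
* Umeyama alignment includes the determinant correction, so reflected
  inputs still yield a proper rotation.
* Degenerate inputs raise typed exceptions (`CheiralityError`,
  `DegenerateGeometryError`, `IllConditionedError`, ...) rather than
  returning silent garbage.

## Known limitations

* The two-solution planar ambiguity is resolved only when a third camera
  shares enough correspondences; with exactly two cameras in an ambiguous
  geometry the cheirality tie-break can pick the wrong pose (~3–6% of
  random two-view scenes; rare for well-spread floor grids).
* The long-focal fixture camera uses a 4000 px focal length; a much
  longer lens sees too few of the reduced fixture's 72 points, which
  leaves its center depth nearly unobservable and (through the
  center-based Sim(3) alignment) inflates every camera's reported
  rotation error. The full 3200-point schedule supports far stronger
  zooms.
* The detector assumes dark markers on a bright projected background with
  reasonable contrast; it has no photometric normalization beyond Otsu
  thresholding and a fixed relative contrast floor.
* Marker rendering and the floor warp are geometric; no attempt is made
  at photorealism.
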