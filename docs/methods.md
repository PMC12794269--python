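# Methods

This note documents the models, numerical choices and limitations of the
package, in the order data flows through the pipeline.

## Coordinate and data conventions

All physical coordinates are micrometres. A `VoxelGrid` couples a 3D
scalar array to a per-axis `spacing` and an `origin` under the
voxel-centre convention: index `(i, j, k)` sits at
`origin + (i, j, k) · spacing`, indices 0-based. `spacing[i]` is the step
of array axis `i` (array order, not microscope order); a TIFF stack is
read page-major as `(z, y, x)` with an axis-permutation flag for other
layouts. Meshes are triangle soups in physical coordinates with optional
per-vertex scalars.

The experiment ledger (`pipeline.log`) is an append-only text file with
one `ISO-8601 timestamp<TAB>key<TAB>JSON value` line per recorded
parameter; reads are last-write-wins. The paper trail makes every stage
replayable: re-running a stage with the recorded parameters reproduces its
output byte-for-byte (timestamps aside). Non-linear transforms are too
large to inline, so they are persisted as sidecar `*.transform.json` files
referenced from the ledger by path.

## Volume cleaning

Order of operations: spacing calibration → intensity window → mirroring →
Gaussian smoothing → low-pass → optional resampling.

* **Intensity window (v0, v1)** — values below v0 are set to 0, values
  above v1 clamped to v1, in-window values kept on their original scale.
  The interactive tool this replaces maps intensities through a display
  colormap; we deliberately keep the quantitative scale and leave display
  mapping to the analysis layer, so gene-expression levels remain
  meaningful downstream.
* **Mirroring** — left limbs are flipped about the first stored array axis
  (overridable) so every sample lives in the right-handed reference frame.
  The flip is an exact index reversal, hence an involution.
* **Gaussian smoothing** — separable, σ in voxels, default (6, 6, 6),
  reflect padding at boundaries. The default is validated in the tests by
  its impulse response: per-axis intensity-weighted std 6 ± 0.05 voxels.
* **Low-pass** — an ideal (hard) radial mask in normalized frequency,
  cycles/voxel, default cutoff 0.05; bins at exactly the cutoff are kept,
  the DC bin always survives, and the output is the real part of the
  inverse FFT. Frequencies are per-voxel rather than per-µm: the
  artifacts this step removes (acquisition texture) live on the voxel
  lattice, not on the physical scale. The unit is part of the config.
* **Resampling** — trilinear, at target voxel centres placed so the
  physical extent is preserved (spacing rescaled by the shape ratio).
  Trilinear interpolation is exact on affine intensity fields, which the
  tests exploit. There is no default target shape; resampling is off
  unless requested.

Degenerate inputs: an all-zero volume passes through cleaning unchanged;
a window with v0 ≥ v1 is a parameter error raised before anything is
written.

## Surface extraction

* **Isovalue** — manual, or automatic as the arithmetic mean of strictly
  positive voxels. Zeros are excluded because the cleaning stage maps
  sub-threshold voxels to exactly 0; a flag restores the plain mean.
* **Marching cubes** — scikit-image's implementation (Lewiner case
  table), linear interpolation along cell edges, vertices mapped to
  physical coordinates. For fields fully interior to the grid the surface
  is watertight; accuracy is validated against analytic spheres (area and
  enclosed volume within 2%, error halving as spacing halves).
* **Component cleanup** — the connected component with the most
  triangles is kept (ties broken by larger area), discarding residual
  fragments.
* **Decimation** — iterative quadric edge collapse to
  `round((1 − target_reduction) · N)` triangles, default
  target_reduction 0.995 (0.5% retained). Candidate positions minimize
  the summed vertex quadrics (area-weighted fundamental quadrics; 3×3
  normal-equation solve, falling back to best-of-endpoints/midpoint when
  near-singular). With `preserve_volume` (default) the position is then
  projected onto the plane of positions that keep the enclosed volume of
  the local triangle fan exactly unchanged — volume preservation is
  enforced by construction rather than by a tuned soft penalty — and any
  collapse that would flip or degenerate a surviving triangle, or create a
  duplicate face, is rejected. Priorities are lazily updated (stale heap
  entries are detected by per-vertex version counters) and ties break by
  insertion order, making the algorithm deterministic. On closed
  manifolds every collapse removes exactly two triangles, so the target
  count is reached exactly; a sphere decimated from 10⁵ to 500 triangles
  keeps its volume to well under 1%.

A note on the retention default: the operation is described equivalently
as "removing 99.5%" or "a target factor of 0.005 retained"; this package
canonicalizes on the removed fraction (0.995).

## Staging geometry

The AER curve is interpolated by a cubic spline through the ordered
landmarks with chord-length parameterization (the parameterization is a
free choice; chord length behaves well for unevenly picked points) and
resampled uniformly in parameter. The staging plane is fitted by total
least squares (smallest principal direction of the centred covariance)
with a deterministic sign convention (non-negative z, then y, then x).
The minimal rotation carrying the fitted normal onto (0, 0, −1) is built
from the Rodrigues formula; the antiparallel case rotates 180° about the
x-axis by convention. The staged outline is the reoriented, centred point
set with z dropped.

The staging service itself is external prior work reached over HTTP; its
exact JSON schema is configurable. The package ships a deterministic mock
(fixture lookup keyed by a hash of the submitted points, with a smooth
size-based fallback in the published 249–290 stage window) so workflows
and tests run offline. A service failure raises; the pipeline never
records a default stage.

## Registration

* **Similarity estimation** — Umeyama's closed-form least squares via SVD
  of the cross-covariance with determinant correction, so the rotation is
  always proper even for reflection-like correspondences. Scale is
  optional (default on: the reference alignment in practice needs
  rotation + translation + uniform scale, even though it is often loosely
  called 6-DOF).
* **Closest points** — exact point-to-triangle distances (Ericson's
  region classification, fully vectorized), with candidate triangles taken
  from the faces incident to the 8 nearest vertices of a k-d tree. For the
  well-shaped meshes the pipeline produces this candidate set contains the
  true nearest triangle.
* **ICP** — alternates closest-point correspondence and similarity
  estimation (rigid update by default), rejecting pairs beyond 3× the
  median distance. Updates that would increase the mean distance are
  discarded, so the recorded trace is non-increasing; iteration stops on
  a < tol change (default 10⁻⁶ µm) or max_iter. Registration runs on
  decimated surfaces, as the pipeline intends; ICP cost is linear in
  source vertex count.
* **Pair augmentation** — extra correspondences are farthest-point
  samples of the source vertices (seeded by the user's picks) paired with
  their closest points on the target surface, appended after the seeds.
* **TPS** — the 3D thin-plate spline with kernel U(r) = r (the 3D
  biharmonic fundamental solution; the familiar r² log r kernel is the 2D
  case and is not appropriate for 3D landmarks). The linear system
  enforces orthogonality of the kernel weights to the affine monomials;
  λ = 0 interpolates landmarks exactly, λ > 0 adds a ridge on the kernel
  block. Bending energy is the quadratic form −Σ_d w_dᵀ K w_d, clamped at
  zero against rounding; it vanishes identically for affine landmark
  relations. Coplanar landmarks at λ = 0 are rejected with a pointer to
  regularization.
* **Volume warping** — inverse-mapped trilinear resampling onto a
  reference geometry; out-of-domain samples are 0. The affine inverse is
  exact. The TPS inverse is approximated by fitting the
  reverse-direction spline (exact only for affine warps, adequate for the
  smooth morphs the tool produces); a per-voxel damped fixed-point
  inversion is available behind a flag for stronger warps.
* **Distance maps** — per-source-vertex distance to the nearest point on
  any target triangle, with mean/max/rms summaries.
* **Reference registry** — one mesh per integer stage over an inclusive
  range (the published atlas spans stages 249–290, i.e. 42 entries);
  lookup rounds half-up and clamps to the range. The real atlas meshes are
  not shipped; the phantom module generates synthetic stand-ins whose
  volume grows monotonically with stage.

## Analysis operators

All operators are pure functions of their inputs. Slabs reduce a
half-open index range `[lo, hi)` (the GUI this replaces exposes sliders
with no stated convention; half-open ranges compose cleanly) by mean or
max and carry `{axis, range, operation}` metadata. Oblique slices build a
deterministic orthonormal in-plane basis from the normal and sample every
channel at bitwise-identical coordinates. Probes sample evenly spaced
points on a segment with trilinear interpolation, identical across
channels. Isosurface families are linearly spaced over the requested
interval (a quantile option exists) and hard-capped at 10 surfaces for
display legibility; levels outside the data range are skipped with a
warning because interior levels of a clamped volume may be genuinely
empty.

## The phantom generator

The phantom emulates what the pipeline sees after acquisition: a
half-ellipsoid "paddle" indicator (semi-axes a, b, c; analytic volume
(2/3)·π·a·b·c) at intensity 100, with boundary voxels holding the interior
volume fraction (2× supersampling) so marching cubes lands sub-voxel
accurately, multiplied by speckle `1 + ε`, ε ~ N(0, noise²), default
noise 0.05 — multiplicative, mimicking cleared-tissue light-sheet texture.
Expression channels share the grid: a proximodistal linear ramp masked by
the paddle, a bilobed double Gaussian, and a Gaussian tube around a ring
(torus) whose isosurface has genus 1 and whose in-plane probe shows two
flanks with a deep central dip. AER landmarks lie exactly on the analytic
distal rim. All outputs keep a one-voxel zero margin so extracted surfaces
are closed, and all randomness flows through a single seed.

What the phantom does **not** emulate: point-spread functions,
attenuation and stripe artifacts, bleaching, anisotropic noise, real
anatomical shape variation, or the real staged reference atlas. Tests
passing on phantoms therefore validate the numerics and the contracts of
the pipeline, not its robustness to real microscope pathology.

The phantom "stage series" used for the reference registry scales
semi-axes linearly with stage — a geometric stand-in, not biology.

## Problem sizes and determinism

The test suite runs desk-scale: phantoms on 48×72×36 grids, analytic
spheres on ≤ 97³ grids, registration on decimated (≈ 500–1500 triangle)
surfaces, and one ≈ 10⁵-triangle sphere for the decimation-default check.
All stochastic tests use fixed seeds; the generator and the decimator are
fully deterministic, so repeated runs are bitwise-identical.

## Known limitations

* Marching cubes uses linear interpolation without an asymptotic decider;
  vertex positions differ in detail from other implementations, so
  guarantees are stated on measures (area, volume, topology), not vertex
  coordinates.
* The decimator assumes (near-)manifold input; it repairs nothing beyond
  rejecting fin-creating collapses, and non-manifold input may stop early
  with more triangles than requested.
* The TPS inverse used for volume warping is approximate for non-affine
  warps; strong folds of the forward warp are not detected.
* The mock staging client reproduces the service contract, not the
  staging science; real stages require the live endpoint.
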