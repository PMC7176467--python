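# Methods

This note records the modelling choices behind `eitshape`, in the spirit of
a model-description appendix: what is simulated, with which defaults and
why, what the synthetic data do and do not emulate, and where the numerics
need care.

## Shape representation and smoothing

A body cross section is an ordered, simple, counter-clockwise polygon. Raw
coordinates are normalized by a similarity transform only (translation of
the bounding-box center to the origin plus one uniform scale so the larger
extent equals 2): a rigid transform alone cannot fit an arbitrary shape
into a fixed square, and preserving the aspect ratio is what matters for
shape studies. The starting vertex is rolled to the point of maximum x so
that Fourier descriptors of equivalent contours are comparable.

The descriptor is the unnormalized DFT of `x + iy`. Smoothing retains the
symmetric frequency set {0, ±1, …, ±(k−1)/2}; k counts all retained
coefficients including the DC term and is therefore odd. The truncated
spectrum is zero-padded (amplitude-preserving) to `m` output points —
48 by default, configurable, and deliberately decoupled from the input
count: the limiting k = 1 member keeps only the dominant first-harmonic
coefficient, which is an origin-centered circle, and measuring its radius
to 1e-6 requires rendering it with a few thousand vertices because an
m-gon rescaled to area π has vertex radius `1 + (2π/m)²/12`.

Every family member is rescaled to polygon area π about its centroid
(the center of scaling is otherwise arbitrary; the centroid keeps
off-center intermediate shapes where the truncation put them). The
mismatch ΔS between two shapes is the area of their symmetric difference
divided by π, computed with exact polygon boolean operations (shapely) and
cross-checked in the tests against a 2048² rasterization oracle.

## Forward model

The forward domain is two-dimensional. Real chests are 3-D, and the
reference study extrudes its contours; this package keeps the entire
analysis in the electrode plane because the object of study — mismatch of
the in-plane boundary shape — lives there, and a 2-D complete electrode
model keeps every experiment desk-scale. Absolute voltages therefore
differ from any 3-D model; all conclusions are about *differences* between
reconstruction models, which is also why only difference imaging is
implemented.

The CEM uses first-order triangles, per-electrode contact impedance
(default 0.01 in normalized units — low enough that electrodes shunt
realistically, high enough for good conditioning), 16 electrodes covering
50% of the perimeter, and an adjacent-adjacent stimulation pattern
excluding driven electrodes (208 channels). The pattern, coverage and
impedance are configurable; results that depend on them are asserted in
the tests only as properties (reciprocity, convergence, symmetry), not as
values.

Meshing is done in-package: the boundary is subdivided with electrode-arc
endpoints as mandatory vertices (arcs get at least two edges at half the
global target size, gaps are filled with a geometric grading), an inner
offset ring plus a hexagonal lattice fill the interior, scipy's Delaunay
triangulates, and triangles whose centroid falls outside the boundary
polygon are dropped. Two non-obvious details: the inner offset ring
guarantees an interior point near every boundary chord, and collinear
boundary triples (several nodes on one straight polygon segment) can still
appear as near-zero-area Delaunay triangles — these are detected and
repaired by a local edge flip. The mesh conforms exactly to the electrode
arcs, which the assembly relies on.

The solver assembles the standard CEM system (stiffness + electrode
boundary mass + coupling + electrode self terms) with a Lagrange
multiplier enforcing zero-mean electrode potential. Reciprocity holds to
solver precision (~1e-14) because the system is symmetric; the tests
verify the homogeneous-disc solution against the analytic Fourier series
for uniform-density arc electrodes (sinc² factors for finite arc width)
to 1%.

The Jacobian is computed by the adjoint method: with adjacent drive and
adjacent measurement, the measurement fields are the drive fields, so one
factorization per conductivity yields all 208 × n_elements sensitivities.
Rows are normalized by the reference voltages and columns multiplied by
the reference conductivity, matching element-wise normalized difference
data with fractional conductivity change as the unknown. Central finite
differences confirm the Jacobian to 1e-7.

Small-target simulation assigns elements to a target disc by centroid
membership (no partial-volume weighting); this converges under mesh
refinement and keeps the conductivity perturbation exactly representable
on the mesh. If a disc captures no centroid, the nearest element is used
so that no lattice position silently produces a zero signal.

## Reconstruction

All four algorithms share the dual model: the element Jacobian is
aggregated onto a 32×32 pixel grid over `[-1, 1]²`, masked to pixels whose
center lies inside the reconstruction contour. Aggregation subdivides each
element into 16 equal-area subtriangles and assigns each share to the
pixel containing its centroid — an approximate area-weighted overlap that
leaves no covered pixel empty (plain centroid assignment would, because
elements and pixels are of comparable size). Pixels the mesh cannot reach
(slack between the polygon and the mesh boundary) are removed from the
mask.

GREIT training uses 1500 uniformly distributed interior targets of radius
0.05 with conductivity factor 1.1, desired images of radius 0.2 with unit
amplitude, and identity noise/image covariances; all seeded. The training
count was chosen so the trained matrix is smooth enough for the image
maximum of a central target to be a stable location (at a few hundred
targets the argmax wanders by 2–4 pixels between seeds; the blob's center
of gravity is stable much earlier). The defining product is evaluated as
`X̃ Yᵀ (J Σx Jᵀ + λ Σn)⁻¹` — with the concatenated training matrices this
is the only dimensionally consistent reading.

The NOSER exponent defaults to 0.5 (reference implementations vary
between 0.5 and 1; it is a parameter).

**Noise figure.** The NF of a matrix R is computed in closed form: the
signal is the simulated normalized difference of a small central disc
(radius 0.1, factor 1.1), the image-noise standard deviation under
unit-variance channel noise is `sqrt(mean diag(R Rᵀ))`, and
`NF = mean|y| · sqrt(mean diag(R Rᵀ)) / mean|R y|`. This is deterministic,
invariant to rescaling R or the data, and agrees with a Monte-Carlo
estimate to better than 2%. A sampling estimator is kept in the tests as
an oracle only.

**Calibration.** Gauss–Newton and GREIT hyperparameters are bisected on a
log scale (NF is monotone decreasing in λ over the bracket) until
|NF − 0.5| ≤ 1e-3. TSVD needs care on two counts. First, the hard
threshold of the truncated pseudoinverse makes NF a step function of t, so
no threshold generally achieves a target to 1e-3; calibration therefore
uses a continuous *effective component count* in which the marginal
singular triplet enters with fractional weight, making NF continuous. The
`tsvd_matrix` builder itself remains the pure hard threshold. Second, the
TSVD noise figure is not monotone over the full range: it first falls as
the leading singular vectors sharpen the central target, reaches a
minimum (typically around 15–20 components on these models), then rises
as noisy components enter. Calibration locates the minimum by an integer
scan and bisects on the rising branch, which is the physically meaningful
one (less truncation = more noise amplification).

## Figures of merit

All five metrics derive from the quarter-amplitude set of the
sign-oriented image (resistive targets are flipped so the expected effect
is positive). AR sums the quarter-set amplitude (times pixel area) per
unit of true target strength; PE is the radial distance of the true
center minus that of the amplitude-weighted center of gravity (positive =
reconstructed too centrally); RES is `sqrt(A_q/A_0)`; SD is the fraction
of quarter-set amplitude outside the equal-area circle around the CoG;
RNG is the opposite-sign amplitude outside that circle relative to the
quarter-set amplitude. Pixelation tolerances: one pixel pitch (2/32) for
PE and 0.05 absolute for SD of circular sets. A degenerate (all-zero or
non-finite) image yields an invalid record, not an exception, so sweeps
continue.

## Sweep design

The target lattice has spacing 0.125, radius 0.05 and conductive factor
1.1 (≈180 interior positions on a thorax of area π); the true-shape
simulation model carries the lung contrast (ratio 0.1875) by default, so
that heterogeneous measurements are reconstructed on homogeneous models,
while the reconstruction models are homogeneous with the smoothed shapes.
Target measurements are simulated once and reused across all
(shape, algorithm) pairs. Maps are cached per (shape, algorithm) under a
content hash when a cache directory is given, which makes interrupted
sweeps resumable. Absolute map values depend on the target size and
contrast (which the reference study does not fix); only the structure of
the maps and their trends versus ΔS are meaningful.

A full acceptance-scale sweep (3-member family × 4 algorithms × ~180
targets on ~1000-element meshes) takes about half a minute on one core;
the problem sizes were chosen so the whole test suite stays interactive.

## Synthetic data

Thorax presets are stylized star-shaped radius functions: the human preset
has a lateral/anteroposterior extent ratio ≈1.4 with mild sternal
flattening, the pig preset is rounder (≈1.15) with dorsal flattening, plus
a pure-ellipse preset; a seeded low-amplitude perturbation on harmonics
5–8 varies individuals. Lungs are two mirrored super-ellipses jointly
covering 30–50% of the body area. Breathing follows a raised-cosine lung
conductivity ratio between end-expiration 0.25 and end-inspiration 0.125
(averaging 0.1875, the value the simulation uses for static frames);
measurement noise is white Gaussian at a configurable SNR.

What this emulates: the geometry-driven part of the shape-mismatch
problem — eccentric, mildly irregular boundaries, laterally placed
low-conductivity regions, tidal contrast changes. What it does not:
anatomical detail (ribs, heart, posture), 3-D current spreading,
electrode movement and boundary change with breathing, correlated
electronics noise. Passing tests therefore show that the *pipeline*
behaves correctly and that the qualitative mismatch effects appear under
controlled conditions; they do not certify error magnitudes on real
patients.

## Known limitations

- The 2-D forward model understates out-of-plane current effects;
  absolute amplitude response values are not comparable to 3-D studies.
- The map means weight all lattice positions equally; with an irregular
  true boundary and a circular reconstruction mask, peripheral targets
  can dominate a metric's mean and even move it opposite to the (clear)
  central degradation — TSVD's shape-deformation mean behaves this way.
- The noise-figure landscape of TSVD constrains calibration to the rising
  branch; on very coarse meshes the target NF may fall below the
  achievable minimum, which raises a bracketing error rather than
  silently extrapolating.
- Mesh quality is adequate for first-order elements but the mesher is not
  a general-purpose generator: extremely concave contours or electrode
  coverages near 0 or 1 may require tuning `max_area`.
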