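# Methods

## Problem and model

Electron cryotomography records 2D projections of a frozen specimen at a
series of tilt angles about a single axis. The angular range is limited
(typically ±60°), leaving a wedge of Fourier space unsampled, and the
electron dose per image is small, so projections are dominated by Poisson
counting noise. Weighted back-projection (WBP), the standard linear
reconstruction, transfers this noise directly into the tomogram.

`cstomo` reconstructs by regularized inversion instead:

    f* = argmin_{f >= 0}  || P f - g ||_2^2  +  lambda * TV2(f)

where `P` is the parallel-beam projection operator, `g` the measured tilt
series, and `TV2` the second-order total variation — the aggregated
magnitude of all second finite differences. TV² vanishes exactly on
piece-wise *linear* images, which suits dense biological density maps with
smoothly varying interiors far better than first-order TV (whose
piece-wise-constant prior flattens or staircases them). Non-negativity is
part of the model: correctly preprocessed cryo-EM densities are
non-negative, and the constraint suppresses the oscillating negative
streaks that plain least squares produces in the missing wedge.

## Geometry conventions

Volumes are indexed `(z, y, x)` (2D: `(z, x)`), with `y` the tilt axis and
`z` the beam direction at zero tilt. Projections are indexed `(y, u)` with
`u` perpendicular to the tilt axis. Positive tilt rotates the specimen so
that `+x` moves toward `+z`; under this convention a particle at `(x, z)`
relative to the tilt axis projects to detector position
`u = x cos(theta) - z sin(theta)`. Indexing is 0-based; all ranges are
half-open.

## Projector

The forward operator is ray-driven: for every angle and detector bin the
line integral is approximated by sampling the volume at unit-spaced points
along the beam with bilinear interpolation. The weights are assembled into
a sparse matrix once per geometry, so the back-projector is the literal
matrix transpose and the adjoint identity holds to float rounding — a
precondition for the primal-dual solver's convergence guarantees, and the
property the test suite verifies against dense loop-built oracles. A 3D
single-axis acquisition factorizes into independent 2D problems per
tilt-axis row; the implementation exploits this but exposes the full 3D
operator.

Rays integrate over whatever support they cross — no field-of-view mask is
imposed; edge artifacts are cropped after reconstruction instead. One
caveat of the unit-step bilinear kernel: the weights a single grid-point
source receives, summed over a rotated sample lattice, oscillate by up to
~34% (worst at 45°). The effect averages to below 0.5% for extended smooth
objects and is irrelevant for reconstruction quality, but point-mass tests
must budget for it.

## WBP baseline

Each projection row is filtered along `u` in Fourier space with |k|
(normalized to 1 at Nyquist; exact zero at DC), optionally tapered by a
Hamming window, then back-projected and scaled by `pi / (2 n_angles)`.
With this normalization a densely sampled full-range reconstruction
approximates the inverse Radon transform in amplitude (a noiseless disk
reconstructs to interior values within ~5% of truth when wrap-around bias
is small). Filtering is deliberately unpadded so that discrete cosines are
exact eigenfunctions of the filter; the resulting circular-convolution
bias is visible only for objects filling most of the box.

## TV² operator and proximal maps

The Hessian operator stacks `d(d+1)/2` unique second differences: central
`[1, -2, 1]` stencils per axis and forward-of-forward mixed differences
per axis pair. Every stencil is evaluated only where fully supported and
edge samples carry zeros (a Neumann-type boundary rule). Consequences:
affine volumes are annihilated *exactly*, interior and boundary, so the
global intensity offset and any linear trend are never penalized; and the
adjoint is an exact transpose (validated against dense materialization).
Zero padding was rejected because it penalizes the volume boundary and
creates halos.

Grouping of the components is configurable:

* `iso` (default): per-voxel Frobenius norm of the Hessian with mixed
  terms weighted sqrt(2) — rotation-invariant;
* `aniso`: plain l1 with mixed terms counted twice.

The corresponding dual-ball projections (`prox_l1_dual`) are the
componentwise clamp to `[-lambda, lambda]` or the per-voxel rescaling to
Frobenius radius lambda. The data term's dual resolvent is
`(p - sigma g) / (1 + sigma)`, the closed form for a quadratic misfit.
(The objective value reported by `objective()` is the un-halved
`||Pf - g||^2 + lambda TV2(f)`; the resolvent corresponds to the halved
data term, so quoting lambda against the reported objective doubles it —
a pure reparametrization.)

First-order TV (forward-difference gradient, l-inf dual ball) is included
as a negative control only: on the smooth phantoms it demonstrably
staircases (its reconstructions carry several-fold higher second-order
roughness than the TV² ones at matched weight).

## PDHG solver

Chambolle–Pock iterations on the saddle-point form, with duals for the
data term and the regularizer:

1. `p <- prox_data_dual(p + sigma P f_bar)`
2. `q <- prox_l1_dual(q + sigma H f_bar, lambda)`
3. `f <- max(0, f - tau (P^T p + H^T q))` (projection onto f >= 0)
4. `f_bar <- f + theta (f - f_prev)`, `theta = 1`

Defaults: `tau = sigma = 0.99 / ||K||` with `||K||` of the stacked
`K = [P; H]` estimated by 50 seeded power iterations; initialization at
zero (WBP warm start available but off by default); a fixed iteration
budget of 200 with no early exit, so runs are bit-reproducible. The
condition `tau sigma ||K||^2 <= 1` is validated and violation is an error.

lambda is applied against the data term exactly as written — no internal
normalization by data size — so useful values scale with image size and
intensity; a weight tuned on one dataset geometry does not transfer
numerically to another.

Step-size balance: equal tau and sigma suit the ordinary operating regime.
In the extreme strong-regularization regime (lambda orders of magnitude
above the data scale) the dual variable of the fourth-order operator must
grow very large and equal steps converge impractically slowly; there the
package's own runs use a dual-weighted pair
(`tau = 0.99/(gamma ||K||)`, `sigma = 0.99 gamma/||K||`, gamma ~ 300),
which still satisfies the step condition and reaches the TV²-null-space
limit within ~50k iterations. This is a step-size choice, not an
algorithmic variant.

Iteration sufficiency: on the standard noisy fixture the RMSE against
ground truth changes by well under 1% between 200 and 2000 iterations,
which is why 200 is the default budget.

## Choosing lambda by half-map self-consistency

`select_lambda_by_halfmap_fsc` reconstructs two independent-noise
realizations of the same tilt geometry at each candidate weight and scores
the area under the FSC between the two reconstructions, mirroring the
practice of selecting the weight with the highest gold-standard half-map
agreement. An important caveat this package documents and tests around:
the criterion is meaningful only under the fixed-iteration protocol. At
exact convergence, half-map agreement is monotone non-decreasing in lambda
— heavily over-regularized half-maps converge to near-identical smooth
limits and correlate almost perfectly — so an unconstrained sweep would
select unbounded smoothing. With the 200-iteration budget of the standard
protocol, over-weighted runs remain truncation-limited and noisy, and the
sweep exhibits a genuine interior optimum (lambda = 1 on the pinned
fixture, which is the fixture's pinned reconstruction weight).

## Preprocessing

Raw cryo-EM projections show particles dark on a bright background; the
solver wants inverted, background-free, non-negative data.

* Flat background: mean intensity of a particle-free rectangle, measured
  per tilt.
* Slab background: measured at the (nearest-to) 0° image only and
  extrapolated as `b(theta) = b0 / cos(theta)` — the path length through a
  constant-thickness ice slab — in the linearized mass-thickness domain. A
  Beer–Lambert variant `b0^(1/cos theta)` on normalized counts is provided
  behind a flag; the two agree to first order for thin slabs.
* Inversion: `(background - intensity)`, then one global scale so the
  series maximum is 1; background maps to ~0, dense objects to positive
  values.
* Centering: the particle's predicted projected position is shifted to
  the detector center at every tilt by Fourier phase ramps (subpixel,
  exactly invertible, periodic wrap — wrapped content must fall outside
  the retained box), then cropped to the reconstruction box.

## Chunked reconstruction

Volumes too large for one solve are reconstructed in overlapping chunks
along the tilt axis — the only axis along which the projector is
block-separable, so chunking changes nothing but the TV² coupling range.
Chunk starts advance by `chunk_extent - 2*overlap` (default overlap 25
rows); each chunk discards `overlap` rows per shared edge, the outer edges
of the first and last chunks are retained, and the retained ranges tile
the axis exactly once — every output voxel is written by exactly one chunk
(asserted at run time), never averaged. The last chunk is shifted left to
keep all chunks equally sized. On the test conditions chunked CS-TV²
agrees with monolithic to ~1% of the dynamic range; chunked WBP is
voxel-identical.

## Metrics

FSC/FRC uses the standard convention: shells by rounded integer Fourier
radius, correlation `Re{sum F_a conj(F_b)} / sqrt(sum|F_a|^2 sum|F_b|^2)`,
DC in shell 0 and excluded from resolution estimation. Resolution is read
at the *first* downward crossing of the threshold (0.143 for half-maps,
0.5 against a trusted reference), linearly interpolated between shells;
a curve that never crosses reports the Nyquist bound with a flag. No
masking or phase-randomization correction is applied, so values are not
comparable with masked-FSC numbers from averaging pipelines. Radial
averaging bins voxels by rounded Euclidean distance from a chosen center.

## Synthetic data

The phantom module generates all test inputs:

* `capsid_shell` — a thin high-density shell with low interior density and
  a seeded smooth angular modulation (pseudo-capsomers), standing in for a
  virus-capsid density map; its radial profile peaks at the shell radius.
* `piecewise_linear` — superpositions of pyramids with integer centers and
  dyadic slopes, so faces are exactly affine in floating point and TV² is
  identically zero off the crease sets.
* `disk`, `affine_plus_bumps` — analytic cases for the WBP oracle and the
  regularization-limit tests.

Simulation projects the phantom, adds a background offset, and draws
Poisson counts at a configurable dose (optionally plus Gaussian read
noise); the result can be returned as raw counts, linearized back to
projection units, or with experiment-like inverted contrast to exercise
the preprocessing path.

The pinned study case (`make_fixture("standard_noisy_phantom")`) is a 64²
capsid shell imaged over ±60° in 3° steps at dose 2 counts per unit mass
over a background of 1 — chosen so that the WBP reconstruction visibly
degrades (its FRC against truth falls below 0.143 before half Nyquist) —
with reconstruction weight lambda = 1, the optimum of the half-map sweep
on this fixture. Chunking and 3D checks use a 32³ analogue. These sizes
keep every end-to-end run at seconds on one CPU while leaving all the
qualitative contrasts (CS-TV² vs WBP, TV² vs TV¹, 200 vs 2000 iterations)
clearly resolved.

What the generator does *not* emulate: the contrast transfer function and
detector MTF, dose fractionation and per-tilt damage weighting, alignment
errors, or crowded cellular context. Passing tests therefore demonstrate
the correctness and qualitative behavior of the reconstruction machinery,
not experimental resolution figures; resolution numbers from real
subtomogram-averaging pipelines additionally involve CTF correction,
alignment, and masked FSC, all out of scope here.

## Known limitations

* lambda does not transfer across image sizes or intensity scalings (by
  design, documented above).
* The unpadded ramp filter biases WBP amplitudes for objects that fill
  most of the box.
* The half-map lambda selection is protocol-bound (see above).
* Extreme regularization weights need the dual-weighted step pair; the
  default equal steps converge too slowly in that regime.
* FSC requires a square/cubic box and equal pixel sizes.
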