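# Methods

## Physical model

The membrane is modelled as a thin, incompressible fluid elastic sheet
whose shape is governed by the Helfrich bending energy per unit area

    W = kappa(a) [H − C(a)]² + kappa_G K,

where `H` is the mean curvature, `K` the Gaussian curvature, `C` the
spontaneous (preferred) curvature and `kappa` the bending rigidity.
Areal incompressibility is imposed through a Lagrange-multiplier field
`lambda`, interpreted as membrane tension. Microparticle budding is
emulated by a mechanically distinct circular patch at the centre of an
axisymmetric domain: inside the patch the rigidity is rescaled by a
multiplier `delta`, a spontaneous curvature `C` is imposed, and an
outward normal pressure `p` may act; outside, the membrane is bare.

Force balance normal to the surface (with `kappa_G` uniform, so its
terms drop out by Gauss–Bonnet) reads

    p + 2 lambda H = Delta[kappa (H − C)]
                     + 2 kappa (H − C)(2H² − K) − 2 kappa H (H − C)²,

and the tangential balance is the explicit-gradient part of the energy,

    lambda' = −kappa' (H − C)² + 2 kappa (H − C) C'.

The sign of the `kappa'` term deserves a note: variationally the
tangential balance is `lambda,α = −(∂W/∂θα)|explicit`, which fixes the
minus sign used here. The two heterogeneous terms act only across the
patch/base transition annulus.

### Axisymmetric reduction

With cumulative membrane area `a` as the independent coordinate
(`ds = da / (2 pi r)`; the mesh then samples the membrane by area rather
than arclength, concentrating resolution where the patch sits), the
equilibrium conditions reduce to six first-order ODEs for
`(r, z, psi, H, L, lambda)`, where `psi` is the tangent angle and
`L = r d[kappa(H−C)]/ds` the bending-moment flux:

    r'      = cos psi / (2 pi r)
    z'      = sin psi / (2 pi r)
    psi'    = (2H − sin psi / r) / (2 pi r)
    H'      = L / (2 pi r² kappa) − (kappa'/kappa)(H − C) + C'
    L'      = [p + 2 lambda H − 2 kappa (H−C)(2H² − K)
               + 2 kappa H (H−C)²] / (2 pi)
    lambda' = −kappa' (H − C)² + 2 kappa (H − C) C'

with `K = (sin psi / r)(2H − sin psi / r)`. Boundary conditions are a
clamped outer edge (`z = 0`, `psi = 0`, `lambda = lambda0`) and
regularity at the pole (`psi = 0`, `L = 0`, `r = sqrt(a0/pi)` at the
first mesh node `a0`; the singular point `a = 0` itself is excluded).
Correctness of the reduction is not taken on trust: the test suite
substitutes converged solutions into an independent centred-difference
evaluation of the normal balance, checks the flat disc is reproduced
exactly, and compares small-deflection solves against the closed-form
clamped circular membrane under uniform pressure,
`(kappa/2) ∇⁴z − lambda0 ∇²z = p`, whose regular solution is a quadratic
plus a modified-Bessel boundary layer (the factor kappa/2 follows from
`W = kappa H²` with `H = ∇²z / 2`).

Flipping the signs of `z`, `C` and `p` maps any solution to its mirror
image with identical bending energy, so inward and outward budding are
energetically equivalent; the convention here is that `z ≥ 0` is the
budding direction and positive `p` pushes toward `+z`.

### Spatial profiles

`kappa(a)`, `C(a)` and `p(a)` are logistic (sigmoidal) plateau
functions of the area coordinate, centred at the patch area
`A_patch = 4 pi r_patch²` with width `0.05 · A_patch`. The width is the
one genuinely free regularization in the model — sharp enough that the
patch is well defined, smooth enough for the collocation solver — and is
exposed in `SolverConfig.transition_width_frac`. Prevalence statistics
are sensitive to it (see Limitations). The domain area is
`A_total = 4 pi (3 r_patch)² = 9 A_patch`, i.e. the patch holds exactly
the membrane area of a sphere of the nominal bud radius, embedded in a
nine-fold larger reservoir.

## Numerical solution

Each equilibrium is found with `scipy.integrate.solve_bvp` (collocation,
RK 5(4)) at tolerance `1e-2` on a squared mesh: a uniform mesh on
[0, 1] is squared and scaled to `A_total`, concentrating nodes near the
pole. Default mesh size is 2000 nodes with the node budget capped at
1000× the mesh size. Inside the solver's right-hand side the radial
coordinate is floored at 1e-9 nm — Newton iterates may wander through
r ≤ 0 even when the converged shape is strictly positive. Solver failure
is an ordinary value (`NonConvergence`), never an exception: the
continuation protocol treats it as the natural end of a branch.

### Curvature continuation

Sweeps start from the exact flat solution at `C = 0` and raise `C` in
steps of 0.0007 nm⁻¹ up to 0.07 nm⁻¹ (at most 100 steps), each solve
warm-started from the previous converged state; the ascent stops at the
first failure. Because the model shows snapthrough, the last ascending
state then seeds a descending sweep with the same step back to `C = 0`
(or its own first failure). Ascending and descending records at the same
`C` may differ (hysteresis) and both are kept, undeduplicated. Converged
solutions are re-evaluated on the fixed base mesh before being used as
the next warm start, so chained solves cannot inherit an ever-growing
adaptive mesh.

## Dataset generation

Two four-dimensional parameter spaces are sampled uniformly and
independently per sweep:

| parameter            | range            | units   | note                      |
|----------------------|------------------|---------|---------------------------|
| edge tension lambda0 | 0.003 – 0.15     | pN/nm   | both spaces               |
| patch radius         | 25 – 500         | nm      | both spaces               |
| patch pressure p     | 0 – 3·10⁻⁴       | pN/nm²  | pressure space (delta = 1)|
| rigidity multiplier  | 0.125 – 1.25     | —       | rigidity space (p = 0)    |
| base rigidity        | 320 (fixed)      | pN·nm   | patch rigidity = delta·320|
| spontaneous curvature| 0 – 0.07 (swept) | nm⁻¹    | continuation variable     |

Every converged record becomes one dataset row: the four features, a
binary label — *omega* if the tangent angle exceeds 90° anywhere along
the profile (a neck has formed), *hill* otherwise (strict inequality;
the flat `C = 0` records are rows too) — and the profile curve
downsampled to 50 points at equal arclength fractions. Tables are CSV
with a JSON metadata sidecar (space, ranges, seed, class counts, config
hash); generation is a pure function of (config, seed). Train/test
splits are seeded uniform row partitions with a default withheld
fraction of 0.15.

## Surrogate models

All classifiers consume the four features and output the probability of
the omega class (the rare positive).

- **1-NN baseline**: single nearest neighbour under the normalized L1
  metric (each feature mapped onto [0,1] by its sampling range, then
  Manhattan distance); ties resolve to the lowest training-row index.
- **Boosted trees** (xgboost): binary logistic objective, learning rate
  0.01, max depth 100, min child weight 10, gamma 1, subsample 0.2,
  column subsample 0.9, 700 estimators, seed 23, and positive-class
  weight equal to the hill/omega count ratio of the training set.
- **Classifier network**: dense ReLU stack 10/100/100/(50 % dropout)/
  10/1 with sigmoid head, trained with batch size 32 on a training set
  re-sampled to a 7:1 majority:minority ratio (majority down-sampled
  without replacement, seeded; minority kept whole). Features are
  standardized on the training fold. Training runs up to 4000 epochs
  with early stopping at patience 200 monitoring the area under the
  precision-recall curve on a seeded 20 % validation fold of the
  resampled set, restoring the best checkpoint (ties between
  equal-scoring checkpoints keep the most trained one; patience still
  runs from the last strict improvement, so a saturated monitor stops).
- **Shape regressor**: dense ReLU stack 20/20/100/(25 % dropout)/100/
  (25 % dropout)/100/20 with a 100-wide linear head (50 radii then 50
  heights, raw nm — targets are not normalized), Adam at learning rate
  0.001, batch size 64, mean-absolute-error loss, same early-stopping
  protocol monitoring validation MAE.

The networks run on a small in-package trainer (`membud.nn`): plain
numpy dense layers, inverted dropout, Adam, and patience-based
best-checkpoint early stopping. At these problem sizes (4 inputs, ≤100
outputs, 10³–10⁴ rows) a full deep-learning framework buys nothing.

### Evaluation

Confusion matrices use threshold 0.5 with omega positive. The
precision-recall curve is evaluated at every distinct score and its area
by the step-wise rule `Σ (R_i − R_{i−1}) P_i` (no linear interpolation,
which biases PR areas upward); the implementation is cross-checked
against `sklearn.metrics.average_precision_score` in the tests. Phase
maps are dense curvature × tension prediction grids at a fixed
normalized patch radius (radius / 500 nm; display slices 0.15, 0.4,
0.7), with the fourth feature pinned at its range midpoint unless
overridden; grids may extrapolate beyond the convex hull of converged
training data — predictions there are surrogate guesses, not mechanics.

The regressor reports, per test curve: MAE over the 100 coordinates; a
scale-normalized error — both curves scaled per axis by the true curve's
maxima (|z| maximum; a flat true curve falls back to the radial
maximum), then the mean over the 50 predicted points of the minimum
Euclidean distance to the true point set (the mean, rather than the sum,
keeps values comparable across curves); and the normalized L1 distance
to the nearest training point, with an OLS of each error metric on that
distance (R² = squared correlation). Predictions crossing into negative
radii are counted and reported, not clipped.

## Problem sizes

The test suite regenerates reduced datasets (50 sweeps per space on a
150-node mesh) and the acceptance script runs the full pipeline at 100
sweeps per space on a 200-node mesh — sizes chosen so a complete run
stays in the minutes range on one CPU while leaving several thousand
rows per dataset and a three-digit minority class. The residual
verification solves on a 1600-node mesh at tolerance 1e-3: the oracle
differentiates the discrete solution twice, so the state must be tight
enough for finite differences to see the equations rather than
collocation noise.

## What the generator does and does not emulate

The synthetic data are exact equilibria of the stated continuum model:
axisymmetric, static, single-patch, with uniform Gaussian rigidity and
all heterogeneity carried by three smooth plateau profiles. Passing
tests therefore certify the pipeline — equations, continuation,
labeling, training, metrics — not biological fidelity: real membranes
have cortex attachment, lipid/protein transport, thermal fluctuations,
non-axisymmetric modes and dynamics, none of which are represented.
Surrogates trained here interpolate this model, not cells.

## Known limitations

- **Prevalence is protocol-dependent.** The omega fraction of a
  generated dataset is governed by where the warm-started Newton
  continuation loses its branch and by the transition width of the
  profiles; measured omega prevalence in the pressure space ranges from
  under 1 % to over 25 % as the transition width varies across
  plausible values (0.45 down to 0.01 × A_patch) with all physical
  ranges held fixed. Absolute prevalence figures should be read as
  properties of (model + solver + width), not of the membrane.
- The continuation tracks branches deep into strongly deformed,
  near-pearling shapes (tangent angles past 180°); no shape-validity
  filter is applied, matching the labeling rule's indifference to
  anything beyond the 90° criterion.
- Descending sweeps frequently fail immediately after a snapthrough;
  an empty or short descending phase is a normal outcome.
- 1-NN probabilities are hard 0/1, so its precision-recall curve has a
  single interior operating point.
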