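# Methods

## Model

The package implements an ideal observer performing binary-contact
prediction under Bayesian decision theory. At time T an object is at
distance `x_T` from the body surface (cm, body at 0) moving with constant
velocity `v_T` (cm/s, negative toward the body). The observer must output a
continuous prediction `y_pred ∈ [0, 1]` of the binary event *y* = "the
object touches the body at or before T + ΔT".

Stages:

1. **Noisy perception.** Point estimates are drawn independently,
   `x̂ ~ N(x_T, σ_x)`, `v̂ ~ N(v_T, σ_v)`. A raw position sample inside the
   body (x̂ < 0) is relocated to 0.1 cm — the observer never perceives the
   object behind its own surface; samples in [0, 0.1) are kept as drawn.
   Velocity is never clamped. The estimates are encoded together with their
   generating uncertainties (no cue combination, no priors).
2. **Future-position belief.** With constant velocity over ΔT the
   displacement belief is `N(ΔT·v̂, ΔT·σ_v)`, so the future position belief
   is `N(x̂ + ΔT·v̂, √(σ_x² + (ΔT·σ_v)²))`. Note σ_x and σ_v enter only
   through this combined variance: scaling one into the other (with a ΔT
   factor) leaves the hit probability unchanged.
3. **Hit probability.** `p = Φ((0 − μ)/σ)`, the belief mass at or behind
   the surface, evaluated with the exact Gaussian CDF in 1D. In the
   noiseless limit σ = 0 this degenerates to a step function (1 iff μ ≤ 0),
   the pointwise limit of the CDF.
4. **Decision.** The reported prediction minimises expected loss
   `p·FN·(1 − y)^r + (1 − p)·FP·y^r` over the candidate grid
   {0, grid_step, …, 1}. Ties take the smallest candidate (they are
   measure-zero for valid loss factors). For r = 2 the analytic optimum
   `y* = p·FN/(p·FN + (1 − p)·FP)` is exposed separately and is used as a
   test oracle for the grid rule; the grid rule is the production path
   because the simulated experiments are defined on the grid.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| σ_x | position-estimation noise SD | cm | 2.5 |
| σ_v | velocity-estimation noise SD | cm/s | 20 |
| FN | loss weight of unpredicted contact | — | 5 |
| FP | loss weight of predicted non-contact | — | 1 |
| r | loss exponent | — | 2 |
| ΔT | prediction horizon (time to execute a defence) | s | 0.5 |
| grid_step | candidate-prediction spacing | — | 0.05 |

The defaults are the baseline configuration of the simulation experiments.
FN > FP encodes the precautionary principle of defensive PPS; FN = FP makes
the decision pure probability matching (`y* = p`); FN < FP (an appetitive
regime) is accepted by the API but no experiment presets use it.

## 3D extension

Position and velocity become 3-vectors (axis 1 = depth, axes 2/3 =
horizontal/vertical) with independent per-axis Gaussian noise; the future
belief is multivariate normal with diagonal covariance. The body part is
reduced to its collision plane: a rectangle with half-extents (r1, r2)
centred at the origin of the plane x1 = 0. Presets: face 25 × 25 cm,
torso 50 × 50 cm. Body depth is ignored, as is body-part orientation.

**Hit region.** A sampled future position f counts as a hit when f1 ≤ 0 and
the straight segment from the perceived current position p to f crosses the
plane at lateral coordinates inside the rectangle (crossing point
`c = p + t(f − p)`, `t = p1/(p1 − f1)`). Equivalently, the admissible
lateral region at depth x1 is bounded by lines linear in x1 that pass
through the rectangle edges at the plane — a cone with apex at the percept.
The production estimator is plain Monte Carlo: 10 000 samples from the
belief, hit rate = sample fraction in the region (this also handles the
degenerate zero-lateral-noise case where a density-based quadrature would
need special casing). The test suite cross-checks it against a
deterministic 1D quadrature over the depth axis with closed-form Gaussian
lateral band masses. Only the depth-axis percept is clamped at 0.1 cm;
clamping lateral axes would have no geometric meaning.

The depth axis of the 3D model with zero lateral uncertainty is exactly the
1D model; this reduction is enforced by tests within binomial Monte-Carlo
error.

## Sweep experiments

A sweep draws `n_reps` independent pipeline runs at every distance of a
grid. Distances are simulated independently with fresh noise — predictions
depend only on the current state, not the previous trajectory. Summaries
per distance: mean and 25th/75th percentiles (numpy linear interpolation
between order statistics). Default problem sizes: 1000 repetitions per
distance on 1 cm grids spanning 0–100 cm (baseline 1D settings) or
0–120 cm (fast-looming, long-horizon and 3D settings, where the boundary
would otherwise sit near the grid edge). The dense-grid illustration preset
uses 20 repetitions and grid_step 0.001, matching its published protocol.

Reproducibility: one seeded `numpy.random.Generator` per sweep. The 1D
path consumes, per distance, `n_reps` position draws then `n_reps` velocity
draws; the 3D path processes repetitions in chunks of 250 and consumes, per
chunk, the position matrix, the velocity matrix, then one standard-normal
block per axis of the future samples. The chunk size is therefore part of
the stream layout; it is fixed by default. Reruns of an identical config
are bit-for-bit identical.

The 3D inner loop runs on preallocated buffers with a division-free form of
the crossing test (multiply both sides by `d = p1 − f1 > 0`), which keeps a
full 121-distance × 1000-rep × 10 000-sample sweep around a minute on one
core.

## Boundary metrics

* **Threshold rule** — farthest swept distance with mean prediction
  > 0.01. The two published phrasings ("first value", scanning from far
  space, and "farthest distance") coincide on monotone curves; the farthest
  grid distance is implemented. Returns "no boundary" when the curve never
  exceeds the threshold and warns when it always does (grid too short).
* **Sigmoid midpoint** — least-squares fit of `A/(1 + exp(k(d − d0)))`,
  initialised at the interpolated half-maximum crossing. The lower
  asymptote is fixed at 0 (the model's far-field prediction is exactly 0);
  the amplitude is free because 3D curves saturate below 1 when lateral
  uncertainty lets the object miss the body part. Flat curves and
  non-convergent fits raise a fit error rather than returning a number.
* **Slope** — absolute finite-difference gradient (central stencil,
  one-sided at the ends) of the mean curve at the grid point nearest the
  midpoint of its range. This pointwise estimate inherits the sampling
  noise of the mean at a single distance; at 1000 repetitions it reliably
  separates sharp from shallow boundaries but not neighbouring
  uncertainty levels.

Under the σ_v sweep with FN = FP = 1 the sigmoid midpoint is nearly
invariant (analytically, the distance at which the *expected* hit
probability is ½ equals ΔT·|v| regardless of σ_v) while the threshold
boundary moves by tens of centimetres — the two operationalizations measure
different things. The residual midpoint drift of a few centimetres comes
from the free amplitude interacting with the near-body clamp.

## What the simulations do and do not show

The generator *is* the model under study — there is no external data. The
simulated curves show the model's qualitative signatures (graded boundary,
speed- and value-driven expansion, looming/receding asymmetry, body-part
scaling) under Gaussian, constant-velocity, single-cue assumptions. They do
not establish anything about non-Gaussian perceptual noise, time-varying
trajectories, cue combination, or empirical reaction-time data, and
passing tests certify numerical and statistical correctness of the
implementation, not biological validity.

## Known limitations and open choices

* The threshold-rule boundary estimator is an extreme statistic of a noisy
  tail: at 1000 repetitions it carries a few centimetres of seed-to-seed
  spread and a slight outward bias on shallow tails. This is inherent to
  the published operationalization, not smoothed away here.
* In the enlarged-uncertainty 3D setting the torso boundary sits ~6 cm
  below the 1D boundary with the same depth-axis parameters (the lateral
  miss probability is strictly positive), so the torso cannot exceed its 1D
  ceiling of ≈72 cm; the simulated torso and face boundaries land near
  65 cm and 57 cm, bracketing the published rough fits.
* Lateral bounds of the hit region follow the percept-apex cone described
  above; a variant that tests the sample's own lateral coordinates (a
  cylinder) changes boundaries by ≤ 1 cm at these parameter values, so the
  choice is not empirically critical.
* Logistic is the chosen sigmoid family; the literature it operationalizes
  does not fix one.
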