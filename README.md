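# ppspace

A normative Bayesian model of **peripersonal space (PPS)** as impact
prediction, for computational neuroscientists studying how the brain encodes
the space immediately surrounding the body.

Multisensory neurons respond to visual or auditory stimuli near the body,
delineating PPS. This package implements an ideal observer that explains that
encoding as a statistically optimal computation: predicting whether an object
will contact the body within a short horizon, given noisy percepts of its
position and velocity, and given that a missed contact is costlier than a
false alarm.

## The model

An object at distance `x_T` (cm, body surface at 0) moves with velocity `v_T`
(cm/s, negative = looming). The observer receives noisy estimates
`x̂ ~ N(x_T, σ_x)` and `v̂ ~ N(v_T, σ_v)` (a position estimate inside the body
is relocated to 0.1 cm), and propagates them over the prediction horizon ΔT:

    X̂_{T+ΔT} ~ N( x̂ + ΔT·v̂ ,  √(σ_x² + (ΔT·σ_v)²) )

The hit probability is the mass of this belief at or behind the body,
`p = P(X̂_{T+ΔT} ≤ 0)`. The reported prediction `y*_pred ∈ [0, 1]` minimises
the expected asymmetric loss

    loss(y, y_pred) = FP·max(0, y_pred − y)^r + FN·max(0, y − y_pred)^r

over a discrete candidate grid; for r = 2 the analytic optimum is
`y* = p·FN / (p·FN + (1−p)·FP)`. With FN > FP (default 5 : 1) predictions are
inflated relative to the hit probability — the precautionary principle.

In 3D, position and velocity become per-axis Gaussian percepts and the body
part becomes a collision rectangle of half-extents (r1, r2) in the plane
x1 = 0. A sampled future position counts as a hit when the straight path from
the perceived position crosses that plane inside the rectangle; the hit
probability is estimated from 10 000 Monte-Carlo samples.

Sweeping the object distance and repeating the stochastic pipeline yields
PPS curves: mean prediction vs distance, with a graded boundary whose
location and steepness respond separately to sensory uncertainty (σ_v),
object value (FN), and the action horizon (ΔT).

## Worked example

```python
import numpy as np
from ppspace import (ModelParams, SweepConfig, run_sweep,
                     boundary_threshold, boundary_sigmoid)

params = ModelParams()                      # baseline: sigma_x=2.5, sigma_v=20,
                                            # fn=5, fp=1, delta_t=0.5
config = SweepConfig(np.arange(0.0, 101.0), velocity=-25.0,
                     params=params, n_reps=1000, seed=1)
curve = run_sweep(config)
print("mean prediction at contact:", round(curve.mean[0], 3))
print("threshold boundary (cm):   ", boundary_threshold(curve))
print("sigmoid midpoint (cm):     ", round(boundary_sigmoid(curve).boundary, 1))
```

prints

```
mean prediction at contact: 0.922
threshold boundary (cm):    52.0
sigmoid midpoint (cm):      22.5
```

At contact the observer predicts impact almost surely; the mean prediction
decays with distance and last exceeds 0.01 at 52 cm — the threshold-rule PPS
boundary, close to empirical estimates around the face for a 25 cm/s looming
stimulus. The sigmoid midpoint is a different, more conservative
operationalization of the same curve.

The same experiments are available from the shell:

```sh
ppspace predict --x 30 --n 1000 --seed 1
ppspace sweep --preset fig5 --out-dir out/fig5
ppspace report out/fig5/*_curve.csv
```

Presets (`fig2`, `fig4a`, `fig4b`, `fig5`, `fig6`, `fig8`, `fig9_left`,
`fig9_right`, `s6`, `s7`) encode the published parameter grids; the
`--twin-unbiased` flag runs the FN = FP = 1 variant of any preset.

## Layout

- `ppspace.core1d` — 1D percept sampling, hit probability, loss, optimal
  prediction (grid and closed form).
- `ppspace.model3d` — 3D kinematics, body rectangles, Monte-Carlo hit rates.
- `ppspace.experiments` — distance-sweep harness, presets, curve CSV I/O.
- `ppspace.boundaries` — threshold and sigmoid-midpoint boundaries, slope
  metrics, parameter-surface tables.
- `ppspace.cli` — `ppspace predict / sweep / report`.

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
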