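"""One-dimensional normative model of impact prediction under perceptual noise.

An observer watches an object at distance ``x`` from the body surface
(cm, body at 0, positive = in front of the body) moving with signed velocity
``v`` (cm/s, negative = looming toward the body).  The task is to report a
continuous prediction ``y_pred`` in [0, 1] of whether the object will contact
the body within the prediction horizon ``delta_t``.

The generative chain is:

1. *Perception with noise* — the observer receives point estimates
   ``x_hat ~ N(x, sigma_x)`` and ``v_hat ~ N(v, sigma_v)``, and encodes them
   together with their uncertainties.  A position estimate inside the body
   (``x_hat < 0``) is relocated to 0.1 cm, immediately in front of it.
2. *Future-position belief* — assuming constant velocity over ``delta_t``,
   the future position is Gaussian with mean ``x_hat + delta_t * v_hat`` and
   SD ``sqrt(sigma_x**2 + (delta_t * sigma_v)**2)``.
3. *Hit probability* — the probability that the future position is at or
   behind the body surface, i.e. the Gaussian lower-tail mass at 0.
4. *Bayesian decision* — the reported prediction minimises the expected
   asymmetric loss ``fp * max(0, y_pred - y)**r + fn * max(0, y - y_pred)**r``
   over a discrete candidate grid.  With ``fn > fp`` missed contacts are
   costlier than false alarms, which inflates predictions for uncertain
   percepts (the precautionary regime).

All functions accept scalars; the probability/decision stage also broadcasts
over numpy arrays, which the sweep harness in :mod:`ppspace.experiments`
relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "POSITION_CLAMP_CM",
    "ModelParams",
    "WorldState1D",
    "Percept1D",
    "FutureBelief1D",
    "prediction_grid",
    "sample_percept",
    "future_belief",
    "hit_probability",
    "loss",
    "expected_loss",
    "optimal_prediction_grid",
    "optimal_prediction_closed_form",
    "predict_impact",
]

#: Position (cm) assigned to percepts whose raw sample fell inside the body.
POSITION_CLAMP_CM = 0.1


def prediction_grid(grid_step: float) -> np.ndarray:
    """Candidate-prediction grid {0, grid_step, 2*grid_step, ..., 1}.

    ``grid_step`` must divide 1 so the grid ends exactly at 1.
    """
    if not 0.0 < grid_step <= 1.0:
        raise ValueError(f"grid_step must be in (0, 1], got {grid_step}")
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step {grid_step} does not evenly divide [0, 1]")
    return np.linspace(0.0, 1.0, n + 1)


@dataclass(frozen=True)
class ModelParams:
    """Observer parameters.

    Defaults are the baseline configuration used throughout the simulation
    experiments: moderate position noise, large velocity noise, and a 5:1
    penalty for missed contact relative to a false alarm.

    Parameters
    ----------
    sigma_x : float
        Position-estimation noise SD (cm, >= 0).
    sigma_v : float
        Velocity-estimation noise SD (cm/s, >= 0).
    fn : float
        False-negative loss factor (penalty for unpredicted contact).
    fp : float
        False-positive loss factor (penalty for predicted non-contact).
    r : float
        Loss exponent; the decision stage's closed form requires r = 2.
    delta_t : float
        Prediction horizon (s, > 0), interpretable as the time needed to
        execute a defensive action.
    grid_step : float
        Spacing of the candidate-prediction grid (must divide 1).
    """

    sigma_x: float = 2.5
    sigma_v: float = 20.0
    fn: float = 5.0
    fp: float = 1.0
    r: float = 2.0
    delta_t: float = 0.5
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_v < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.fn < 0 or self.fp < 0:
            raise ValueError("loss factors must be >= 0")
        if self.fn + self.fp == 0:
            raise ValueError("fn + fp must be > 0 (loss must depend on the prediction)")
        if self.r <= 0:
            raise ValueError("loss exponent r must be > 0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        prediction_grid(self.grid_step)  # validates grid_step

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    @property
    def future_sigma(self) -> float:
        """SD of the future-position belief implied by the noise parameters."""
        return float(np.hypot(self.sigma_x, self.delta_t * self.sigma_v))


@dataclass(frozen=True)
class WorldState1D:
    """True object kinematics: distance from the body surface and velocity."""

    x: float
    v: float

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("object position must be at or in front of the body (x >= 0)")


@dataclass(frozen=True)
class Percept1D:
    """Noisy point estimates together with their encoded uncertainties."""

    x_hat: float
    v_hat: float
    sigma_x: float
    sigma_v: float

    def __post_init__(self) -> None:
        if self.x_hat < 0:
            raise ValueError("percept position must be in front of the body")
        if self.sigma_x < 0 or self.sigma_v < 0:
            raise ValueError("encoded uncertainties must be >= 0")


@dataclass(frozen=True)
class FutureBelief1D:
    """Gaussian belief over the object's position at the end of the horizon."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("belief SD must be >= 0")


def sample_percept(
    state: WorldState1D, params: ModelParams, rng: np.random.Generator
) -> Percept1D:
    """Draw one noisy percept of the object.

    Position and velocity are sampled independently; a raw position sample
    inside the body (< 0) is relocated to ``POSITION_CLAMP_CM``.  Velocity is
    never clamped.  Exactly two normal draws are consumed, position first.
    """
    x_raw = rng.normal(state.x, params.sigma_x)
    v_hat = rng.normal(state.v, params.sigma_v)
    x_hat = POSITION_CLAMP_CM if x_raw < 0 else float(x_raw)
    return Percept1D(x_hat=x_hat, v_hat=float(v_hat), sigma_x=params.sigma_x, sigma_v=params.sigma_v)


def future_belief(percept: Percept1D, params: ModelParams) -> FutureBelief1D:
    """Propagate a percept through constant-velocity motion over ``delta_t``."""
    mu = percept.x_hat + params.delta_t * percept.v_hat
    sigma = np.hypot(percept.sigma_x, params.delta_t * percept.sigma_v)
    return FutureBelief1D(mu=float(mu), sigma=float(sigma))


def hit_probability(belief: FutureBelief1D) -> float:
    """P(contact within the horizon) = Gaussian lower-tail mass at 0.

    The degenerate noiseless belief (sigma = 0) is the CDF limit: a step
    function, 1 if the predicted position is at or behind the body.
    """
    if belief.sigma == 0:
        return 1.0 if belief.mu <= 0 else 0.0
    return float(ndtr(-belief.mu / belief.sigma))


def _check_unit_interval(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def loss(y: int, y_pred: float, params: ModelParams) -> float:
    """Asymmetric prediction loss.

    ``fp * max(0, y_pred - y)**r`` penalises over-prediction (false positive
    side) and ``fn * max(0, y - y_pred)**r`` penalises under-prediction
    (false negative side); exactly one term is nonzero.
    """
    if y not in (0, 1):
        raise ValueError("actual outcome y must be 0 or 1")
    _check_unit_interval(y_pred, "y_pred")
    over = max(0.0, y_pred - y)
    under = max(0.0, y - y_pred)
    return params.fp * over**params.r + params.fn * under**params.r


def expected_loss(p_hit: float, y_pred: float, params: ModelParams) -> float:
    """Expected loss of prediction ``y_pred`` given hit probability ``p_hit``."""
    _check_unit_interval(p_hit, "p_hit")
    return p_hit * loss(1, y_pred, params) + (1.0 - p_hit) * loss(0, y_pred, params)


def _expected_loss_on_grid(p_hit: np.ndarray, grid: np.ndarray, params: ModelParams) -> np.ndarray:
    """Expected loss for every grid candidate; shape ``p_hit.shape + grid.shape``."""
    p = p_hit[..., None]
    return p * params.fn * (1.0 - grid) ** params.r + (1.0 - p) * params.fp * grid**params.r


def optimal_prediction_grid(p_hit, params: ModelParams, grid_step: float | None = None):
    """Grid argmin of the expected loss (the production decision rule).

    Evaluates the expected loss on the candidate grid and returns the
    minimiser; ties go to the smallest candidate (``argmin`` returns the
    first minimum on the ascending grid).  Broadcasts over ``p_hit``.
    """
    grid = prediction_grid(params.grid_step if grid_step is None else grid_step)
    p = _check_unit_interval(p_hit, "p_hit")
    idx = np.argmin(_expected_loss_on_grid(p, grid, params), axis=-1)
    out = grid[idx]
    return float(out) if np.ndim(p_hit) == 0 else out


def optimal_prediction_closed_form(p_hit, params: ModelParams):
    """Analytic argmin of the r = 2 expected loss on [0, 1].

    Setting the derivative of ``p*fn*(1-y)**2 + (1-p)*fp*y**2`` to zero gives
    ``y* = p*fn / (p*fn + (1-p)*fp)``.  Used as an exact oracle for the grid
    rule; rejected for any other loss exponent.
    """
    if params.r != 2:
        raise ValueError("closed-form optimum is only valid for r = 2")
    p = _check_unit_interval(p_hit, "p_hit")
    num = p * params.fn
    den = num + (1.0 - p) * params.fp
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(p > 0, 1.0, 0.0))
    return float(out) if np.ndim(p_hit) == 0 else out


def predict_impact(
    state: WorldState1D,
    params: ModelParams,
    rng: np.random.Generator,
    grid_step: float | None = None,
) -> float:
    """One stochastic draw of the full pipeline: percept -> belief -> decision."""
    percept = sample_percept(state, params, rng)
    belief = future_belief(percept, params)
    return optimal_prediction_grid(hit_probability(belief), params, grid_step=grid_step)


def _predict_many(
    x: float,
    v: float,
    params: ModelParams,
    rng: np.random.Generator,
    n_reps: int,
    grid_step: float | None = None,
) -> np.ndarray:
    """Vectorised batch of independent pipeline draws at one world state.

    Consumes ``n_reps`` position draws followed by ``n_reps`` velocity draws
    from ``rng`` (the documented stream order for reproducibility).
    """
    xs = rng.normal(x, params.sigma_x, size=n_reps)
    vs = rng.normal(v, params.sigma_v, size=n_reps)
    xs = np.where(xs < 0, POSITION_CLAMP_CM, xs)
    mu = xs + params.delta_t * vs
    sigma = params.future_sigma
    if sigma == 0:
        p_hit = (mu <= 0).astype(float)
    else:
        p_hit = ndtr(-mu / sigma)
    return optimal_prediction_grid(p_hit, params, grid_step=grid_step)
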