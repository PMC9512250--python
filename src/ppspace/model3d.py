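"""Three-dimensional extension: body-part rectangles and Monte-Carlo hit rates.

Position and velocity become 3-vectors (axis 1 = depth toward the body,
axes 2/3 = horizontal/vertical), each axis perceived independently with its
own Gaussian noise.  The body part is reduced to its collision plane: a
rectangle of half-extents ``(r1, r2)`` centred at the origin in the plane
``x1 = 0``; body depth is ignored.  Unlike the 1D model, the object can now
*miss* the body part, so the hit probability is the mass of the multivariate
future-position belief whose straight-line path from the perceived current
position crosses the plane inside the rectangle.  That integral has no
printed closed form and is estimated by Monte Carlo (default 10 000 samples
per percept); the decision stage is shared with the 1D model, operating on
the scalar hit probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core1d import POSITION_CLAMP_CM, optimal_prediction_grid, prediction_grid

__all__ = [
    "Params3D",
    "WorldState3D",
    "Percept3D",
    "FutureBelief3D",
    "BodyRect",
    "FACE",
    "TORSO",
    "sample_percept_3d",
    "future_belief_3d",
    "hit_test",
    "hit_probability_3d",
    "predict_impact_3d",
]


def _vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 components, got shape {arr.shape}")
    return arr


@dataclass(frozen=True, eq=False)
class Params3D:
    """Per-axis observer parameters for the 3D model.

    ``sigma_x`` / ``sigma_v`` are 3-vectors of per-axis noise SDs; the
    decision parameters (``fn``, ``fp``, ``r``, ``grid_step``) and the
    horizon ``delta_t`` keep their 1D meaning.  ``n_mc`` is the number of
    Monte-Carlo future-position samples per hit-probability estimate.
    """

    sigma_x: np.ndarray
    sigma_v: np.ndarray
    fn: float = 5.0
    fp: float = 1.0
    r: float = 2.0
    delta_t: float = 0.5
    grid_step: float = 0.05
    n_mc: int = 10_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_x", _vec3(self.sigma_x, "sigma_x"))
        object.__setattr__(self, "sigma_v", _vec3(self.sigma_v, "sigma_v"))
        if np.any(self.sigma_x < 0) or np.any(self.sigma_v < 0):
            raise ValueError("noise SDs must be >= 0")
        if self.fn < 0 or self.fp < 0 or self.fn + self.fp == 0:
            raise ValueError("loss factors must be >= 0 with fn + fp > 0")
        if self.r <= 0:
            raise ValueError("loss exponent r must be > 0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        prediction_grid(self.grid_step)

    def replace(self, **changes) -> "Params3D":
        return dataclasses.replace(self, **changes)

    @property
    def future_sigma(self) -> np.ndarray:
        """Per-axis SD of the future-position belief (diagonal covariance)."""
        return np.hypot(self.sigma_x, self.delta_t * self.sigma_v)


@dataclass(frozen=True, eq=False)
class WorldState3D:
    """True object kinematics; the depth coordinate must be in front of the body."""

    x: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _vec3(self.x, "x"))
        object.__setattr__(self, "v", _vec3(self.v, "v"))
        if self.x[0] < 0:
            raise ValueError("depth coordinate x[0] must be >= 0")


@dataclass(frozen=True, eq=False)
class Percept3D:
    """Per-axis noisy point estimates with their encoded uncertainties."""

    x_hat: np.ndarray
    v_hat: np.ndarray
    sigma_x: np.ndarray
    sigma_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_hat", "v_hat", "sigma_x", "sigma_v"):
            object.__setattr__(self, name, _vec3(getattr(self, name), name))


@dataclass(frozen=True, eq=False)
class FutureBelief3D:
    """Multivariate normal belief over the future position (diagonal covariance)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _vec3(self.mu, "mu"))
        object.__setattr__(self, "sigma", _vec3(self.sigma, "sigma"))


@dataclass(frozen=True)
class BodyRect:
    """Collision rectangle of a body part: half-width ``r1``, half-height ``r2``."""

    r1: float
    r2: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("body rectangle half-extents must be > 0")

    @classmethod
    def from_size(cls, width: float, height: float) -> "BodyRect":
        """Build from full side lengths, e.g. ``from_size(25, 25)`` for the face."""
        return cls(r1=width / 2.0, r2=height / 2.0)


#: Face approximated by a 25 cm x 25 cm rectangle.
FACE = BodyRect.from_size(25.0, 25.0)
#: Torso approximated by a 50 cm x 50 cm rectangle.
TORSO = BodyRect.from_size(50.0, 50.0)


def sample_percept_3d(
    state: WorldState3D, params: Params3D, rng: np.random.Generator
) -> Percept3D:
    """Draw one 3D percept: axes sampled independently, depth clamped like 1D.

    Only the depth-axis position sample is clamped to 0.1 cm when negative;
    lateral axes and all velocity axes are unclamped.  Consumes one 3-vector
    of position draws then one of velocity draws.
    """
    x_raw = rng.normal(state.x, params.sigma_x)
    v_hat = rng.normal(state.v, params.sigma_v)
    if x_raw[0] < 0:
        x_raw = x_raw.copy()
        x_raw[0] = POSITION_CLAMP_CM
    return Percept3D(x_hat=x_raw, v_hat=v_hat, sigma_x=params.sigma_x, sigma_v=params.sigma_v)


def future_belief_3d(percept: Percept3D, params: Params3D) -> FutureBelief3D:
    """Per-axis constant-velocity propagation; covariance stays diagonal."""
    mu = percept.x_hat + params.delta_t * percept.v_hat
    sigma = np.hypot(percept.sigma_x, params.delta_t * percept.sigma_v)
    return FutureBelief3D(mu=mu, sigma=sigma)


def hit_test(future_point, percept_position, body: BodyRect) -> bool:
    """Does the straight path from the percept to a future point hit the body?

    True iff the future point lies at or behind the collision plane
    (``f[0] <= 0``) and the segment from the perceived current position to it
    crosses the plane ``x1 = 0`` at lateral coordinates inside the rectangle.
    The crossing point is ``c = p + t * (f - p)`` with ``t = p1 / (p1 - f1)``.
    """
    f = _vec3(future_point, "future_point")
    p = _vec3(percept_position, "percept_position")
    if p[0] <= 0:
        raise ValueError("percept position must be strictly in front of the body plane")
    if f[0] > 0:
        return False
    t = p[0] / (p[0] - f[0])
    c2 = p[1] + t * (f[1] - p[1])
    c3 = p[2] + t * (f[2] - p[2])
    return bool(abs(c2) <= body.r1 and abs(c3) <= body.r2)


def _hit_fraction(
    percept_pos: np.ndarray, future: np.ndarray, body: BodyRect
) -> np.ndarray:
    """Vectorised hit rate.

    percept_pos: (n, 3) perceived current positions; future: (n, m, 3)
    sampled future positions. Returns the per-percept fraction of samples
    whose crossing point lands inside the rectangle.
    """
    p1 = percept_pos[:, 0][:, None]
    f1 = future[..., 0]
    behind = f1 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p1 / (p1 - f1)
        c2 = percept_pos[:, 1][:, None] + t * (future[..., 1] - percept_pos[:, 1][:, None])
        c3 = percept_pos[:, 2][:, None] + t * (future[..., 2] - percept_pos[:, 2][:, None])
    hits = behind & (np.abs(c2) <= body.r1) & (np.abs(c3) <= body.r2)
    return hits.mean(axis=1)


def hit_probability_3d(
    percept: Percept3D, body: BodyRect, params: Params3D, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of the hit probability for one percept.

    Draws ``n_mc`` future positions from the diagonal-normal belief and
    returns the fraction that pass :func:`hit_test`.
    """
    belief = future_belief_3d(percept, params)
    z = rng.standard_normal((params.n_mc, 3))
    future = belief.mu + belief.sigma * z
    return float(_hit_fraction(percept.x_hat[None, :], future[None, :, :], body)[0])


def predict_impact_3d(
    state: WorldState3D,
    body: BodyRect,
    params: Params3D,
    rng: np.random.Generator,
    grid_step: float | None = None,
) -> float:
    """One stochastic draw of the 3D pipeline, reusing the 1D decision rule."""
    percept = sample_percept_3d(state, params, rng)
    p_hit = hit_probability_3d(percept, body, params, rng)
    return optimal_prediction_grid(p_hit, params, grid_step=grid_step)


class _McWorkspace:
    """Preallocated buffers for the chunked Monte-Carlo hit-rate kernel.

    Reusing buffers across distances of a sweep avoids repeated large
    allocations, which dominate the runtime of the naive vectorised path.
    """

    def __init__(self, chunk: int, n_mc: int) -> None:
        self.chunk = chunk
        shape = (chunk, n_mc)
        self.z1 = np.empty(shape)
        self.z2 = np.empty(shape)
        self.z3 = np.empty(shape)
        self.tmp = np.empty(shape)
        self.hits = np.empty(shape, dtype=bool)
        self.aux = np.empty(shape, dtype=bool)


def _hit_rate_chunk(
    px: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    body: BodyRect,
    ws: _McWorkspace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hit rate for one chunk of percepts, drawing ``n_mc`` samples each.

    Implements the crossing test of :func:`hit_test` in a division-free
    form: with ``d = p1 - f1 > 0`` on the mask ``f1 <= 0``, the condition
    ``|p_i + t (f_i - p_i)| <= r`` with ``t = p1 / d`` is equivalent to
    ``|p_i d + p1 (f_i - p_i)| <= r d``.
    """
    c = px.shape[0]
    z1, z2, z3 = ws.z1[:c], ws.z2[:c], ws.z3[:c]
    tmp, hits, aux = ws.tmp[:c], ws.hits[:c], ws.aux[:c]
    rng.standard_normal(out=z1)
    rng.standard_normal(out=z2)
    rng.standard_normal(out=z3)
    p1 = px[:, 0][:, None]
    # future depth samples, then d = p1 - f1 (in place in z1)
    z1 *= sigma[0]
    z1 += mu[:, 0][:, None]
    np.less_equal(z1, 0.0, out=hits)
    np.subtract(p1, z1, out=z1)
    for z, axis, half in ((z2, 1, body.r1), (z3, 2, body.r2)):
        p_lat = px[:, axis][:, None]
        z *= sigma[axis]
        z += mu[:, axis][:, None]
        z -= p_lat
        z *= p1
        np.multiply(z1, p_lat, out=tmp)
        z += tmp
        np.abs(z, out=z)
        np.multiply(z1, half, out=tmp)
        np.less_equal(z, tmp, out=aux)
        hits &= aux
    return hits.mean(axis=1)


def _predict_many_3d(
    x: np.ndarray,
    v: np.ndarray,
    body: BodyRect,
    params: Params3D,
    rng: np.random.Generator,
    n_reps: int,
    grid_step: float | None = None,
    chunk_size: int = 250,
    workspace: _McWorkspace | None = None,
) -> np.ndarray:
    """Vectorised batch of independent 3D pipeline draws at one world state.

    Repetitions are processed in chunks of ``chunk_size`` to bound memory.
    Per chunk the stream order is: position matrix, velocity matrix, then
    one standard-normal block per axis of the future samples; ``chunk_size``
    is therefore part of the reproducible stream layout.
    """
    x = _vec3(x, "x")
    v = _vec3(v, "v")
    sigma_future = params.future_sigma
    chunk = min(chunk_size, n_reps)
    ws = workspace if workspace is not None and workspace.chunk >= chunk else _McWorkspace(
        chunk, params.n_mc
    )
    p_hit = np.empty(n_reps)
    for start in range(0, n_reps, chunk):
        stop = min(start + chunk, n_reps)
        px = rng.normal(x, params.sigma_x, size=(stop - start, 3))
        pv = rng.normal(v, params.sigma_v, size=(stop - start, 3))
        px[:, 0] = np.where(px[:, 0] < 0, POSITION_CLAMP_CM, px[:, 0])
        mu = px + params.delta_t * pv
        p_hit[start:stop] = _hit_rate_chunk(px, mu, sigma_future, body, ws, rng)
    return optimal_prediction_grid(p_hit, params, grid_step=grid_step)
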