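"""Operationalizations of the peripersonal-space boundary from sweep curves.

Two boundary definitions from the experimental literature are provided:

* **threshold** — the farthest swept distance at which the mean prediction
  still exceeds a small threshold (default 0.01).  Sensitive to the far
  tail of the curve, hence to both perceptual uncertainty and the loss
  asymmetry.
* **sigmoid midpoint** — the midpoint ``d0`` of a logistic
  ``A / (1 + exp(k * (d - d0)))`` least-squares-fitted to the mean curve.
  The lower asymptote is fixed at 0 (the model's far-field prediction is 0
  by construction) while the amplitude ``A`` is free, because 3D curves can
  saturate below 1 when the object may miss the body part.

A slope metric quantifies the gradient (steepness) of the boundary: the
absolute finite-difference gradient of the mean curve at the distance where
it is closest to the midpoint of its range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core1d import ModelParams
from .experiments import PredictionCurve, SweepConfig, run_sweep

__all__ = [
    "BoundaryEstimate",
    "BoundaryFitError",
    "boundary_threshold",
    "boundary_sigmoid",
    "boundary_slope",
    "size_and_slope_surface",
]


class BoundaryFitError(RuntimeError):
    """Raised when a boundary cannot be estimated from a curve."""


@dataclass(frozen=True)
class BoundaryEstimate:
    """A boundary location plus fit diagnostics (sigmoid method only)."""

    method: str
    boundary: float
    slope: float
    amplitude: float | None = None
    steepness: float | None = None
    residual: float | None = None


def boundary_threshold(curve: PredictionCurve, threshold: float = 0.01) -> float | None:
    """Farthest swept distance whose mean prediction exceeds ``threshold``.

    Returns ``None`` when no distance exceeds the threshold (no boundary in
    the swept range).  If *every* distance exceeds it, the sweep was too
    short to contain the boundary; the largest distance is returned with a
    warning.
    """
    if curve.distances.size == 0:
        raise ValueError("empty curve")
    above = curve.mean > threshold
    if not above.any():
        return None
    if above.all():
        warnings.warn(
            "mean prediction exceeds the threshold at every swept distance; "
            "the distance grid may be too short to contain the boundary",
            stacklevel=2,
        )
    return float(curve.distances[np.nonzero(above)[0][-1]])


def _logistic(d, amplitude, steepness, midpoint):
    return amplitude / (1.0 + np.exp(steepness * (d - midpoint)))


def boundary_sigmoid(curve: PredictionCurve) -> BoundaryEstimate:
    """Fit a decreasing logistic to the mean curve; boundary = its midpoint.

    Initialisation: amplitude from the curve maximum, midpoint from the
    half-maximum crossing (linear interpolation).  Degenerate (near-flat)
    curves and non-convergent fits raise :class:`BoundaryFitError`.
    """
    d = curve.distances
    mean = curve.mean
    span = float(mean.max() - mean.min())
    if d.size < 4 or span < 0.05:
        raise BoundaryFitError("curve is too flat or too short for a sigmoid fit")
    a0 = float(mean.max())
    half = a0 / 2.0
    below = np.nonzero(mean <= half)[0]
    if below.size == 0 or below[0] == 0:
        raise BoundaryFitError("mean curve has no decreasing half-maximum crossing")
    j = below[0]
    # interpolate the half-max crossing between grid points j-1 and j
    frac = (mean[j - 1] - half) / (mean[j - 1] - mean[j])
    d0_init = float(d[j - 1] + frac * (d[j] - d[j - 1]))
    span_d = float(d[-1] - d[0])
    try:
        popt, _ = curve_fit(
            _logistic,
            d,
            mean,
            p0=[a0, 0.1, d0_init],
            bounds=([1e-6, 1e-6, d[0] - span_d], [1.5, 100.0, d[-1] + span_d]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise BoundaryFitError(f"sigmoid fit failed: {exc}") from exc
    amplitude, steepness, midpoint = (float(v) for v in popt)
    residual = float(np.linalg.norm(_logistic(d, *popt) - mean))
    return BoundaryEstimate(
        method="sigmoid_midpoint",
        boundary=midpoint,
        # logistic derivative magnitude at the midpoint
        slope=amplitude * steepness / 4.0,
        amplitude=amplitude,
        steepness=steepness,
        residual=residual,
    )


def boundary_slope(curve: PredictionCurve) -> float:
    """Absolute gradient of the mean curve around its central value.

    The central value is the midpoint between the curve's minimum and
    maximum; the gradient is a central finite difference on the distance
    grid (one-sided at the ends), evaluated at the grid point whose mean is
    nearest the central value.
    """
    mean = curve.mean
    if curve.distances.size < 2:
        raise ValueError("slope requires at least two distances")
    if float(mean.max() - mean.min()) == 0.0:
        raise ValueError("slope of a constant curve is undefined")
    central = (mean.min() + mean.max()) / 2.0
    idx = int(np.argmin(np.abs(mean - central)))
    gradient = np.gradient(mean, curve.distances)
    return float(abs(gradient[idx]))


def size_and_slope_surface(
    sigma_v_values,
    fn_values,
    delta_t_values,
    *,
    sigma_x: float = 0.0,
    velocity: float = -25.0,
    distances=None,
    n_reps: int = 1000,
    threshold: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate threshold boundary and slope over a (sigma_v, fn, delta_t) grid.

    Runs one sweep per grid point (full cross product) and returns a frame
    with columns ``sigma_v, fn, delta_t, boundary, slope``.  The default
    ``sigma_x = 0`` isolates the velocity-uncertainty contribution.
    """
    if distances is None:
        distances = np.arange(0.0, 121.0)
    rows = []
    index = 0
    for sv in sigma_v_values:
        for fn in fn_values:
            for dt in delta_t_values:
                params = ModelParams(sigma_x=sigma_x, sigma_v=sv, fn=fn, delta_t=dt)
                child = int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))
                curve = run_sweep(
                    SweepConfig(distances, velocity, params, n_reps=n_reps, seed=child)
                )
                bound = boundary_threshold(curve, threshold=threshold)
                rows.append(
                    {
                        "sigma_v": sv,
                        "fn": fn,
                        "delta_t": dt,
                        "boundary": np.nan if bound is None else bound,
                        "slope": boundary_slope(curve),
                    }
                )
                index += 1
    return pd.DataFrame(rows)
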