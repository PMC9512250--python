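"""Distance-sweep simulation harness and presets for the figure experiments.

A sweep fixes the observer parameters and the object's velocity, and for
each distance on a grid draws ``n_reps`` independent runs of the full
perception -> belief -> decision pipeline.  Predictions at each distance
depend only on the current position and velocity, never on the previous
trajectory, so distances are simulated independently with fresh noise.
The per-distance samples are summarised by their mean and 25th/75th
percentiles (linear interpolation between order statistics), mirroring how
psychophysics experiments summarise per-distance response distributions.

Presets encode the parameter grids of the published simulation experiments
(velocity, uncertainty, loss and horizon sweeps, and the 3D face/torso
comparisons); every parameter a preset does not set explicitly stays at the
baseline configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .core1d import ModelParams, _predict_many
from .model3d import FACE, TORSO, BodyRect, Params3D, _McWorkspace, _predict_many_3d

__all__ = [
    "SweepConfig",
    "PredictionCurve",
    "VariabilityProfile",
    "run_sweep",
    "variability_profile",
    "preset",
    "preset_names",
]


@dataclass(frozen=True, eq=False)
class SweepConfig:
    """Specification of one distance sweep.

    ``velocity`` is a scalar for the 1D model or a 3-vector for the 3D model
    (in which case ``body`` must be set and ``params`` must be
    :class:`~ppspace.model3d.Params3D`).  In 3D the swept distance is the
    depth coordinate; the object starts on the body-part axis.
    """

    distances: np.ndarray
    velocity: Union[float, tuple, np.ndarray]
    params: Union[ModelParams, Params3D]
    body: BodyRect | None = None
    n_reps: int = 1000
    seed: int = 0
    grid_step: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("distances must be a non-empty 1D grid")
        if np.any(d < 0) or (d.size > 1 and np.any(np.diff(d) <= 0)):
            raise ValueError("distances must be strictly increasing and >= 0")
        object.__setattr__(self, "distances", d)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.body is not None and not isinstance(self.params, Params3D):
            raise TypeError("a body rectangle requires Params3D")
        if self.body is None and isinstance(self.params, Params3D):
            raise TypeError("Params3D requires a body rectangle")

    @property
    def is_3d(self) -> bool:
        return self.body is not None

    def replace(self, **changes) -> "SweepConfig":
        return replace(self, **changes)


@dataclass(frozen=True, eq=False)
class PredictionCurve:
    """Per-distance prediction samples and their summaries.

    ``samples`` has shape ``(n_distances, n_reps)``; it is ``None`` for
    curves re-loaded from a summary CSV.
    """

    distances: np.ndarray
    mean: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    samples: np.ndarray | None = None
    label: str = ""

    @classmethod
    def from_samples(
        cls, distances: np.ndarray, samples: np.ndarray, label: str = ""
    ) -> "PredictionCurve":
        samples = np.asarray(samples, dtype=float)
        q25, q75 = np.percentile(samples, [25, 75], axis=1)
        return cls(
            distances=np.asarray(distances, dtype=float),
            mean=samples.mean(axis=1),
            q25=q25,
            q75=q75,
            samples=samples,
            label=label,
        )

    @property
    def n_reps(self) -> int | None:
        return None if self.samples is None else self.samples.shape[1]

    @property
    def iqr(self) -> np.ndarray:
        """Per-distance interquartile range of the prediction samples."""
        return self.q75 - self.q25

    # ---- serialization -------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the summary curve (distance, mean, q25, q75)."""
        self.summary_frame().to_csv(path, index=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.distances, "mean": self.mean, "q25": self.q25, "q75": self.q75}
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "PredictionCurve":
        # round_trip parsing so written summaries reload bit-for-bit
        frame = pd.read_csv(path, float_precision="round_trip")
        missing = {"distance", "mean", "q25", "q75"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for column in ("distance", "mean", "q25", "q75"):
            values = pd.to_numeric(frame[column], errors="coerce")
            if values.isna().any():
                row = int(values.isna().idxmax())
                raise ValueError(
                    f"{path}: non-numeric value in column '{column}' at data row {row}"
                )
            frame[column] = values
        return cls(
            distances=frame["distance"].to_numpy(),
            mean=frame["mean"].to_numpy(),
            q25=frame["q25"].to_numpy(),
            q75=frame["q75"].to_numpy(),
            samples=None,
            label=label or str(path),
        )

    def samples_to_csv(self, path) -> None:
        """Write raw samples in long format (distance, rep, y_pred)."""
        if self.samples is None:
            raise ValueError("curve carries no raw samples")
        n_d, n_r = self.samples.shape
        frame = pd.DataFrame(
            {
                "distance": np.repeat(self.distances, n_r),
                "rep": np.tile(np.arange(n_r), n_d),
                "y_pred": self.samples.ravel(),
            }
        )
        frame.to_csv(path, index=False)


@dataclass(frozen=True)
class VariabilityProfile:
    """Interquartile range per distance and the distance where it peaks."""

    distances: np.ndarray
    iqr: np.ndarray
    peak_distance: float


def run_sweep(config: SweepConfig) -> PredictionCurve:
    """Run one distance sweep; deterministic given ``config.seed``.

    Distances are processed in grid order with a single seeded generator, so
    a rerun with an identical config reproduces every sample bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    samples = np.empty((config.distances.size, config.n_reps))
    workspace = None
    if config.is_3d:
        workspace = _McWorkspace(min(250, config.n_reps), config.params.n_mc)
    for i, distance in enumerate(config.distances):
        if config.is_3d:
            velocity = np.asarray(config.velocity, dtype=float)
            samples[i] = _predict_many_3d(
                np.array([distance, 0.0, 0.0]),
                velocity,
                config.body,
                config.params,
                rng,
                config.n_reps,
                grid_step=config.grid_step,
                workspace=workspace,
            )
        else:
            samples[i] = _predict_many(
                float(distance),
                float(config.velocity),
                config.params,
                rng,
                config.n_reps,
                grid_step=config.grid_step,
            )
    return PredictionCurve.from_samples(config.distances, samples, label=config.label)


def variability_profile(curve: PredictionCurve) -> VariabilityProfile:
    """Per-distance IQR of the prediction samples and its argmax distance.

    Within-run variability is largest where single draws flip between
    near-zero and near-one predictions, i.e. in the transition region of the
    mean curve — the graded boundary.
    """
    if curve.samples is not None and curve.samples.shape[1] < 2:
        raise ValueError("variability profile requires at least 2 repetitions per distance")
    iqr = curve.iqr
    return VariabilityProfile(
        distances=curve.distances,
        iqr=iqr,
        peak_distance=float(curve.distances[int(np.argmax(iqr))]),
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_GRID_100 = np.arange(0.0, 101.0)
_GRID_120 = np.arange(0.0, 121.0)
_BASELINE_V = -25.0


def _sub_seed(seed: int, index: int) -> int:
    """Stable per-config child seed below 2**31."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def _params3d(sigma_v1: float, lat_x: float, lat_v: float, **kw) -> Params3D:
    return Params3D(
        sigma_x=(2.5, lat_x, lat_x), sigma_v=(sigma_v1, lat_v, lat_v), **kw
    )


def _build_fig2(seed):
    return SweepConfig(
        _GRID_100,
        _BASELINE_V,
        ModelParams(grid_step=0.001),
        n_reps=20,
        seed=_sub_seed(seed, 0),
        label="fig2",
    )


def _build_fig4a(seed):
    return [
        SweepConfig(
            _GRID_100,
            _BASELINE_V,
            ModelParams(sigma_v=sv),
            seed=_sub_seed(seed, i),
            label=f"fig4a_sigma_v={sv:g}",
        )
        for i, sv in enumerate((5.0, 20.0, 35.0))
    ]


def _build_fig4b(seed):
    return [
        SweepConfig(
            _GRID_100,
            _BASELINE_V,
            ModelParams(fn=fn),
            seed=_sub_seed(seed, i),
            label=f"fig4b_fn={fn:g}",
        )
        for i, fn in enumerate((1.0, 5.0, 100.0))
    ]


def _build_fig5(seed):
    return [
        SweepConfig(
            _GRID_120,
            v,
            ModelParams(),
            seed=_sub_seed(seed, i),
            label=f"fig5_v={v:g}",
        )
        for i, v in enumerate((-25.0, -75.0))
    ]


def _build_fig6(seed):
    configs = []
    for i, (speed, direction, sv) in enumerate(
        itertools.product((12.5, 25.0), (-1.0, 1.0), (5.0, 20.0, 35.0))
    ):
        v = direction * speed
        configs.append(
            SweepConfig(
                _GRID_100,
                v,
                ModelParams(sigma_v=sv),
                seed=_sub_seed(seed, i),
                label=f"fig6_v={v:g}_sigma_v={sv:g}",
            )
        )
    return configs


_FIG8_LATERAL = ((0.0, 0.0), (5.0, 40.0), (10.0, 40.0))


def _build_fig8(seed):
    configs = []
    for i, (sv1, (lat_x, lat_v), (body_name, body)) in enumerate(
        itertools.product((20.0, 30.0), _FIG8_LATERAL, (("face", FACE), ("torso", TORSO)))
    ):
        configs.append(
            SweepConfig(
                _GRID_120,
                (_BASELINE_V, 0.0, 0.0),
                _params3d(sv1, lat_x, lat_v),
                body=body,
                seed=_sub_seed(seed, i),
                label=f"fig8_sigma_v1={sv1:g}_lat=({lat_x:g},{lat_v:g})_{body_name}",
            )
        )
    return configs


def _build_fig9(seed, torso_delta_t):
    configs = []
    for i, (body_name, body, dt) in enumerate(
        (("face", FACE, 0.5), ("torso", TORSO, torso_delta_t))
    ):
        configs.append(
            SweepConfig(
                _GRID_120,
                (_BASELINE_V, 0.0, 0.0),
                _params3d(20.0, 5.0, 5.0, delta_t=dt),
                body=body,
                seed=_sub_seed(seed, i),
                label=f"fig9_{body_name}_dt={dt:g}",
            )
        )
    return configs


def _build_s7(seed):
    return [
        SweepConfig(
            _GRID_120,
            _BASELINE_V,
            ModelParams(delta_t=dt),
            seed=_sub_seed(seed, i),
            label=f"s7_delta_t={dt:g}",
        )
        for i, dt in enumerate((0.25, 0.5, 1.0))
    ]


def _build_s6(seed):
    configs = []
    for i, (sv, dt, fn) in enumerate(
        itertools.product((5.0, 20.0, 35.0), (0.25, 0.5, 1.0), (1.0, 5.0, 100.0))
    ):
        configs.append(
            SweepConfig(
                _GRID_120,
                _BASELINE_V,
                ModelParams(sigma_x=0.0, sigma_v=sv, delta_t=dt, fn=fn),
                seed=_sub_seed(seed, i),
                label=f"s6_sigma_v={sv:g}_dt={dt:g}_fn={fn:g}",
            )
        )
    return configs


_PRESET_BUILDERS = {
    "fig2": _build_fig2,
    "fig4a": _build_fig4a,
    "fig4b": _build_fig4b,
    "fig5": _build_fig5,
    "fig6": _build_fig6,
    "fig8": _build_fig8,
    "fig9_left": lambda seed: _build_fig9(seed, torso_delta_t=0.5),
    "fig9_right": lambda seed: _build_fig9(seed, torso_delta_t=0.75),
    "s6": _build_s6,
    "s7": _build_s7,
}


def preset_names() -> list[str]:
    return sorted(_PRESET_BUILDERS)


def _unbias(config: SweepConfig) -> SweepConfig:
    return config.replace(
        params=config.params.replace(fn=1.0, fp=1.0),
        label=config.label + "_unbiased",
    )


def preset(name: str, *, unbiased: bool = False, seed: int = 0):
    """Return the fully specified sweep config(s) for a named experiment.

    ``unbiased=True`` yields the twin variant with ``fn = fp = 1`` (pure
    probability matching), used to separate loss-driven from
    uncertainty-driven effects on the boundary.
    """
    try:
        builder = _PRESET_BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
    built = builder(seed)
    if unbiased:
        built = _unbias(built) if isinstance(built, SweepConfig) else [_unbias(c) for c in built]
    return built
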