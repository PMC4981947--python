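"""Population projection and resting-egg recruitment inference.

During a bloom onset the observed density trajectory is compared with
exponential projections N(t+Δ) = N(t)·exp(Δ·(b(t) − d)) driven by the
egg-ratio birth-rate series and scenario death rates. The canonical
scenario set is d = 0 (maximal intrinsic growth), d = 0.11 d⁻¹ (age-related
losses only, from a 9.5 d mean lifespan) and d = 0.43 d⁻¹ (mean field
mortality including predation). The shortfall of the observed density
relative to the projection's upper 95% confidence bound is a conservative
estimate of external recruitment — individuals hatched from the sediment
egg bank plus the offspring they produced before the observation, which
cannot be separated from weekly count data.

Confidence envelopes come from Poisson resampling of the raw egg and
female counts per sampling date (counts are small-integer-like densities;
Poisson is the natural conservative resampling model), with the birth-rate
series recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DevelopmentTimeModel, birth_rate

__all__ = [
    "ScenarioConfig",
    "TrajectoryEnsemble",
    "RecruitmentEstimate",
    "CANONICAL_DEATH_RATES",
    "project_population",
    "piecewise_constant_rates",
    "bootstrap_trajectory",
    "external_recruitment",
]

#: d = 0 (no losses), 0.11 d⁻¹ (age-related), 0.43 d⁻¹ (field mean).
CANONICAL_DEATH_RATES = (0.0, 0.11, 0.43)


class CoverageError(ValueError):
    """Requested time not covered by the rate series or ensemble."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One projection scenario.

    ``d`` may be negative: a negative death rate mimics net recruitment of
    resting eggs from the seed bank.
    """

    n0: float
    d: float
    horizon_days: float = 7.0
    step_days: float = 1.0
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.horizon_days <= 0 or self.step_days <= 0:
            raise ValueError("horizon and step must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class TrajectoryEnsemble:
    """Bootstrap envelope of projected densities."""

    times: np.ndarray
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    d: float
    reps: int
    trajectories: np.ndarray | None = field(default=None, repr=False)

    def at(self, t: float, which: str = "upper95") -> float:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise CoverageError(
                f"time {t} outside ensemble horizon [{self.times[0]}, {self.times[-1]}]"
            )
        return float(np.interp(t, self.times, getattr(self, which)))


@dataclass(frozen=True)
class RecruitmentEstimate:
    """Observed-minus-modelled recruitment deficit at the horizon."""

    observed: float
    modelled_upper: float
    external_count: float
    external_fraction: float


def piecewise_constant_rates(times: np.ndarray, values: np.ndarray):
    """A step function holding each observed rate until the next sample.

    Weekly egg data drive a daily projection: b between sampling dates is
    held at the last observed value.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values) or len(times) == 0:
        raise ValueError("times and values must be equal-length, non-empty")

    def f(t):
        idx = np.clip(np.searchsorted(times, np.asarray(t, float), side="right") - 1,
                      0, len(values) - 1)
        return values[idx]

    return f


def project_population(scenario: ScenarioConfig, b_of_t) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic projection N(t+Δ) = N(t)·exp(Δ·(b(t) − d)).

    ``b_of_t`` is either a callable of time (days) or an array of per-step
    rates covering the horizon. Returns (times, densities).
    """
    n_steps = int(round(scenario.horizon_days / scenario.step_days))
    times = np.arange(n_steps + 1) * scenario.step_days
    if callable(b_of_t):
        b = np.asarray(b_of_t(times[:-1]), dtype=float)
    else:
        b = np.asarray(b_of_t, dtype=float)
        if len(b) < n_steps:
            raise CoverageError(
                f"b series has {len(b)} steps, horizon needs {n_steps}")
        b = b[:n_steps]
    log_n = np.concatenate([
        [np.log(scenario.n0)],
        np.log(scenario.n0) + np.cumsum(scenario.step_days * (b - scenario.d)),
    ])
    return times, np.exp(log_n)


def bootstrap_trajectory(
    egg_data: pd.DataFrame,
    scenario: ScenarioConfig,
    dev_model: DevelopmentTimeModel | None = None,
    correction: float = 1.0,
    keep_trajectories: bool = False,
) -> TrajectoryEnsemble:
    """Projection ensemble from Poisson-resampled egg and female counts.

    ``egg_data`` needs columns ``day, eggs, females, temp_c`` (one row per
    sampling occasion, days ascending from 0). Per replicate, egg and
    female counts are redrawn Poisson around the observed values, the
    birth-rate series is recomputed, and the population projected; the
    envelope is the 2.5/97.5 percentile band across replicates.
    """
    if scenario.reps < 2:
        raise ValueError("need reps >= 2 for a confidence envelope")
    dev_model = dev_model or DevelopmentTimeModel()
    need = {"day", "eggs", "females", "temp_c"}
    if not need.issubset(egg_data.columns):
        raise KeyError(f"egg_data needs columns {sorted(need)}")
    obs = egg_data.sort_values("day")
    days = obs["day"].to_numpy(dtype=float)
    if days[0] > 0:
        raise CoverageError("egg data must start at day 0")
    eggs = obs["eggs"].to_numpy(dtype=float)
    fems = obs["females"].to_numpy(dtype=float)
    d_e = np.asarray(dev_model(np.clip(obs["temp_c"].to_numpy(),
                                       *dev_model.valid_range)))

    rng = np.random.default_rng(scenario.seed)
    reps = scenario.reps
    eggs_star = rng.poisson(eggs, size=(reps, len(eggs))).astype(float)
    fems_star = np.maximum(
        rng.poisson(fems, size=(reps, len(fems))), 1).astype(float)
    b_obs = np.log1p(correction * eggs_star / (d_e[None, :] * fems_star))

    n_steps = int(round(scenario.horizon_days / scenario.step_days))
    times = np.arange(n_steps + 1) * scenario.step_days
    # piecewise-constant b: index of the last observation at or before t
    step_idx = np.clip(
        np.searchsorted(days, times[:-1], side="right") - 1, 0, len(days) - 1)
    b_steps = b_obs[:, step_idx]                       # (reps, n_steps)
    log_n = np.log(scenario.n0) + np.concatenate([
        np.zeros((reps, 1)),
        np.cumsum(scenario.step_days * (b_steps - scenario.d), axis=1),
    ], axis=1)
    traj = np.exp(log_n)                               # (reps, n_steps+1)

    return TrajectoryEnsemble(
        times=times,
        median=np.median(traj, axis=0),
        lower95=np.percentile(traj, 2.5, axis=0),
        upper95=np.percentile(traj, 97.5, axis=0),
        d=scenario.d,
        reps=reps,
        trajectories=traj if keep_trajectories else None,
    )


def external_recruitment(
    observed: float, ensemble_or_upper, at_time: float | None = None,
) -> RecruitmentEstimate:
    """Conservative external-recruitment estimate at the horizon.

    ``external = max(0, observed − upper95)``; the fraction is relative to
    the observed density. Accepts a :class:`TrajectoryEnsemble` (evaluated
    at ``at_time``, default the horizon end) or a plain upper-bound number.
    """
    if observed <= 0:
        raise ValueError("observed density must be positive")
    if isinstance(ensemble_or_upper, TrajectoryEnsemble):
        t = ensemble_or_upper.times[-1] if at_time is None else at_time
        upper = ensemble_or_upper.at(t, "upper95")
    else:
        upper = float(ensemble_or_upper)
    external = max(0.0, observed - upper)
    return RecruitmentEstimate(
        observed=float(observed),
        modelled_upper=upper,
        external_count=external,
        external_fraction=external / observed,
    )
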