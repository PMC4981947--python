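"""Egg-ratio demography for rotifer populations.

Per-interval instantaneous rates from paired density samples:

* growth rate      ``r = (ln N2 - ln N1) / (t2 - t1)``
* birth rate       ``b = ln(1 + c_E * N_E / (D_E * N_female))``
* death rate       ``d = b - r``

All rates are per day regardless of the sampling interval; interval lengths
are taken from timestamps. Negative death rates are permitted and flagged:
they indicate population gains that pelagic reproduction cannot explain,
i.e. external recruitment (hatching from the sediment resting-egg bank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DevelopmentTimeModel",
    "EggObservation",
    "UndefinedRateError",
    "InsufficientDataError",
    "growth_rate",
    "egg_development_time",
    "birth_rate",
    "death_rate",
    "lifespan_death_rate",
    "demographic_series",
]


class UndefinedRateError(ValueError):
    """A rate is undefined for the given inputs (zero density, zero females)."""


class InsufficientDataError(ValueError):
    """Fewer usable samples than the operation requires."""


@dataclass(frozen=True)
class DevelopmentTimeModel:
    """Temperature-dependent egg development time, anchored Q10 form.

    ``D_E(T) = d_ref * q10 ** ((t_ref - T) / 10)``

    Strictly decreasing in temperature for ``q10 > 1``: eggs develop faster
    when warmer, the only qualitative constraint the egg-ratio method needs.
    Any user-supplied monotone callable may be used in its place.

    Parameters
    ----------
    d_ref : reference development time (days) at ``t_ref``.
    t_ref : anchor temperature (°C).
    q10 : fold-change in development time per 10 °C cooling.
    valid_range : (min, max) temperature (°C) outside which evaluation raises.
    """

    d_ref: float = 1.0
    t_ref: float = 25.0
    q10: float = 2.5
    valid_range: tuple[float, float] = (10.0, 35.0)

    def __call__(self, temperature):
        lo, hi = self.valid_range
        t = np.asarray(temperature, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"temperature outside valid range [{lo}, {hi}] °C"
            )
        out = self.d_ref * self.q10 ** ((self.t_ref - t) / 10.0)
        return float(out) if np.isscalar(temperature) else out


@dataclass(frozen=True)
class EggObservation:
    """One sampling occasion's egg-ratio inputs.

    ``n_eggs`` is the density of eggs attached to females (eggs L⁻¹),
    ``n_females`` the female density (ind L⁻¹). ``correction`` is a
    multiplicative egg-ratio correction factor c_E (default 1, i.e. raw
    egg ratios; the corrected-ratio definition is configurable because it
    is an external calibration, not derivable from counts alone).
    """

    n_eggs: float
    n_females: float
    temperature: float = 25.0
    correction: float = 1.0

    def __post_init__(self):
        if self.n_eggs < 0 or self.n_females < 0:
            raise ValueError("densities must be non-negative")
        if self.n_females == 0 and self.n_eggs > 0:
            raise ValueError("eggs recorded with zero females")
        if self.correction <= 0:
            raise ValueError("correction factor must be positive")

    @property
    def egg_ratio(self) -> float:
        """Corrected eggs per female, c_E · N_E / N_♀."""
        if self.n_females == 0:
            raise UndefinedRateError("egg ratio undefined at zero females")
        return self.correction * self.n_eggs / self.n_females


def growth_rate(n1: float, n2: float, t1: float, t2: float) -> float:
    """In situ per-capita growth rate r = (ln N2 − ln N1)/(t2 − t1), d⁻¹."""
    if t2 <= t1:
        raise ValueError(f"interval must be positive, got t1={t1}, t2={t2}")
    if n1 <= 0 or n2 <= 0:
        raise UndefinedRateError(
            "growth rate undefined for zero/negative densities"
        )
    return (math.log(n2) - math.log(n1)) / (t2 - t1)


def egg_development_time(temperature, model: DevelopmentTimeModel | None = None):
    """Egg development time D_E (days) at `temperature` (°C)."""
    return (model or DevelopmentTimeModel())(temperature)


def birth_rate(
    n_eggs,
    n_females,
    development_time,
    correction: float = 1.0,
):
    """Egg-ratio birth rate b = ln(1 + c_E·N_E/(D_E·N_♀)), d⁻¹.

    Always non-negative. Raises :class:`UndefinedRateError` when the female
    density is zero — the rate is flagged as undefined, never silently 0.
    Accepts scalars or arrays (broadcast).
    """
    n_e = np.asarray(n_eggs, dtype=float)
    n_f = np.asarray(n_females, dtype=float)
    d_e = np.asarray(development_time, dtype=float)
    if np.any(n_e < 0) or np.any(n_f < 0):
        raise ValueError("densities must be non-negative")
    if np.any(d_e <= 0):
        raise ValueError("development time must be positive")
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    if np.any(n_f == 0):
        raise UndefinedRateError("birth rate undefined at zero female density")
    b = np.log1p(correction * n_e / (d_e * n_f))
    return float(b) if b.ndim == 0 else b


def birth_rate_obs(obs: EggObservation, development_time: float) -> float:
    """Birth rate from an :class:`EggObservation`."""
    return birth_rate(obs.n_eggs, obs.n_females, development_time, obs.correction)


def death_rate(b, r):
    """Death rate d = b − r, d⁻¹.

    Negative values are legitimate output: birth rates too low to account
    for observed growth signal external recruitment from the resting-egg
    bank. Callers should treat ``d < 0`` as a recruitment flag.
    """
    b = np.asarray(b, dtype=float)
    r = np.asarray(r, dtype=float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(r))):
        raise ValueError("b and r must be finite")
    d = b - r
    return float(d) if d.ndim == 0 else d


def lifespan_death_rate(mean_lifespan: float, ndigits: int | None = None) -> float:
    """Age-related death rate 1/lifespan (exponential survivorship), d⁻¹.

    With ``ndigits`` the presentation value is returned (e.g. a 9.5 d mean
    lifespan presents as 0.11 d⁻¹ at two decimals).
    """
    if mean_lifespan <= 0:
        raise ValueError("mean lifespan must be positive")
    rate = 1.0 / mean_lifespan
    return round(rate, ndigits) if ndigits is not None else rate


@dataclass
class DemographicSeries:
    """Per-interval demographic rates for one species.

    ``data`` has one row per consecutive sample pair with columns
    ``t1, t2, n1, n2, r, b, d, egg_ratio, development_time,
    recruitment_flag, valid``. Intervals containing a zero density carry
    NaN for r and d (``valid`` False) — the rate chain is broken, never
    interpolated, because ln N is undefined at 0.
    """

    species: str
    data: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.data)


def demographic_series(
    frame: pd.DataFrame,
    species: str,
    dev_model: DevelopmentTimeModel | None = None,
    correction: float = 1.0,
    time_col: str = "day",
) -> DemographicSeries:
    """Assemble r, b, d over consecutive sampling intervals for `species`.

    `frame` needs columns ``{time_col}``, ``density_<species>``,
    ``eggs_<species>``, ``females_<species>`` and ``temp_c``. b is computed
    at the interval start. Requires at least two samples with positive
    density for the species.
    """
    dev_model = dev_model or DevelopmentTimeModel()
    need = [time_col, f"density_{species}", f"eggs_{species}",
            f"females_{species}", "temp_c"]
    missing = [c for c in need if c not in frame.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    df = frame[need].dropna(subset=[time_col]).sort_values(time_col)
    if (df[f"density_{species}"] > 0).sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 samples with positive density for {species}"
        )

    t = df[time_col].to_numpy(dtype=float)
    n = df[f"density_{species}"].to_numpy(dtype=float)
    eggs = df[f"eggs_{species}"].to_numpy(dtype=float)
    fem = df[f"females_{species}"].to_numpy(dtype=float)
    temp = df["temp_c"].to_numpy(dtype=float)

    rows = []
    for i in range(len(df) - 1):
        d_e = dev_model(np.clip(temp[i], *dev_model.valid_range))
        if fem[i] > 0:
            b = birth_rate(eggs[i], fem[i], d_e, correction)
            egg_ratio = correction * eggs[i] / fem[i]
        else:
            b, egg_ratio = np.nan, np.nan
        valid = n[i] > 0 and n[i + 1] > 0 and np.isfinite(b)
        r = growth_rate(n[i], n[i + 1], t[i], t[i + 1]) if (
            n[i] > 0 and n[i + 1] > 0) else np.nan
        d = b - r if valid else np.nan
        rows.append({
            "t1": t[i], "t2": t[i + 1], "n1": n[i], "n2": n[i + 1],
            "r": r, "b": b, "d": d, "egg_ratio": egg_ratio,
            "development_time": d_e,
            "recruitment_flag": bool(valid and d < 0), "valid": bool(valid),
        })
    return DemographicSeries(species=species, data=pd.DataFrame(rows))
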