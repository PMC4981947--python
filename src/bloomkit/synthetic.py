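"""Synthetic multi-lake plankton time series with known ground truth.

Generates weekly monitoring data with the statistical structure the
downstream analyses assume for shallow tropical soda lakes:

* an AR(1) temperature series, a bounded salinity random walk, lognormal
  chlorophyll *a* spanning the hypertrophic range, and a particulate-matter
  (PM) series with episodic resuspension pulses;
* three rotifer species updated weekly by a birth–death exponential step
  plus additive external recruitment — hatch pulses triggered by PM
  exceedances a fixed number of weeks earlier (the stimulus→hatch lag);
* egg ratios coupled to resources so that the egg-ratio birth rate used to
  build the series can be recovered from the emitted egg/female counts;
* phytoplankton group series with injected mean-shift breakpoints.

Everything stochastic flows from one seed; per-lake RNG streams are derived
from the master seed by fixed offsets so adding lakes never perturbs
earlier lakes. A :class:`GroundTruth` ledger records every injected hatch
pulse, the true lag, the recruitment added each week and the injected
breakpoints, enabling parameter-recovery tests with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demography import DevelopmentTimeModel, birth_rate

__all__ = [
    "GeneratorConfig",
    "BreakpointSpec",
    "LakeMeta",
    "PlanktonTimeSeries",
    "MetaDataset",
    "GroundTruth",
    "LakeTruth",
    "generate_environment",
    "generate_rotifer_dynamics",
    "generate_lake",
    "generate_multilake_dataset",
]

#: g dry mass m⁻³ contributed by one individual L⁻¹, per species.
#: B. plicatilis is the largest of the three; values sit in the range
#: implied by peak biomasses of tens of g DM m⁻³ at ~10⁵–10⁶ ind L⁻¹.
SPECIES_MASS = {
    "B_dimidiatus": 8.0e-5,
    "B_plicatilis": 1.5e-4,
    "H_jenkinae": 5.0e-5,
}

PHYTO_GROUPS = (
    "filamentous_cyano",
    "single_cyano",
    "cryptophytes",
    "chlorophytes",
    "diatoms_chrysophytes",
)


class InvalidConfigError(ValueError):
    """Generator configuration violates a precondition."""


@dataclass(frozen=True)
class BreakpointSpec:
    """A mean shift injected into a phytoplankton group series.

    The group's lognormal median is multiplied by ``factor`` from ``week``
    (0-based) onwards.
    """

    variable: str
    week: int
    factor: float


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study system.

    Defaults describe the study conditions: weekly sampling, three rotifer
    species, a baseline field death rate of 0.43 d⁻¹, salinity within
    5.1–62.5, Chl *a* spanning ~11–1650 µg L⁻¹, episodic PM resuspension
    pulses, and a 3-week stimulus→hatch lag with a +1 week offset for the
    later-hatching *B. plicatilis*.
    """

    n_weeks: int = 60
    n_lakes: int = 7
    species: tuple[str, ...] = ("B_dimidiatus", "B_plicatilis", "H_jenkinae")
    step_days: float = 7.0
    seed: int = 0

    # demography
    d0: float = 0.43                # baseline death rate, d⁻¹
    d_noise_sd: float = 0.03        # weekly death-rate jitter, d⁻¹
    n0: float = 10_000.0            # starting density, ind L⁻¹
    # mean egg ratio sets mean b = ln(1+E/D_E) ≈ 0.26 d⁻¹, well below d0:
    # pulses produce sharp week-scale bloom spikes that collapse back to
    # baseline within one or two samples, the episodic regime seen in
    # hypertrophic soda lakes
    mean_eggs_per_female: float = 0.30
    resource_coupling: float = 0.15  # egg-ratio elasticity w.r.t. Chl a
    egg_noise_sd: float = 0.15       # lognormal sd of egg-ratio noise
    dev_model: DevelopmentTimeModel = field(default_factory=DevelopmentTimeModel)

    # hatching
    hatch_lag_weeks: int = 3
    species_lag_offsets: tuple[int, ...] = (0, 1, 0)
    pulse_prob: float = 0.10         # per-week resuspension probability
    pm_threshold: float = 150.0      # mg L⁻¹ above which hatching is stimulated
    pm_pulse_magnitude: float = 180.0  # mg L⁻¹ added by a resuspension event
    eta: float = 400.0               # ind L⁻¹ hatched per mg L⁻¹ PM exceedance

    # environment
    temp_mean: float = 25.0
    temp_ar1: float = 0.6
    temp_noise_sd: float = 1.0
    salinity_range: tuple[float, float] = (5.1, 62.5)
    salinity_step_sd: float = 0.8
    chla_log_mean: float = float(np.log(150.0))
    chla_log_sd: float = 0.8
    chla_ar1: float = 0.7
    pm_baseline_median: float = 80.0
    pm_baseline_sigma: float = 0.3

    # phytoplankton breakpoints; None → one decline in small algae at
    # ~n/3 and a filamentous increase two weeks later (the grazing switch)
    breakpoints: tuple[BreakpointSpec, ...] | None = None

    def __post_init__(self):
        if self.n_weeks < 2:
            raise InvalidConfigError("n_weeks must be >= 2")
        if self.n_lakes < 1:
            raise InvalidConfigError("n_lakes must be >= 1")
        if self.eta < 0 or self.d0 < 0:
            raise InvalidConfigError("eta and d0 must be non-negative")
        if self.hatch_lag_weeks < 0:
            raise InvalidConfigError("hatch lag must be >= 0")
        if len(self.species_lag_offsets) != len(self.species):
            raise InvalidConfigError("one lag offset per species required")
        if not (0.0 <= self.pulse_prob <= 1.0):
            raise InvalidConfigError("pulse_prob must be a probability")

    def default_breakpoints(self) -> tuple[BreakpointSpec, ...]:
        if self.breakpoints is not None:
            return self.breakpoints
        w = max(2, self.n_weeks // 3)
        return (
            BreakpointSpec("small_algae", w, 0.25),
            BreakpointSpec("filamentous_cyano", min(w + 2, self.n_weeks - 2), 4.0),
        )


@dataclass(frozen=True)
class LakeMeta:
    lake_id: str
    ephemeral: bool
    rainy_season_start_week: int
    monthly_rainfall_mm: float
    productivity_scale: float


@dataclass
class PlanktonTimeSeries:
    """One lake's weekly series: densities, biomass, eggs, environment."""

    lake_id: str
    data: pd.DataFrame = field(repr=False)
    meta: LakeMeta | None = None

    def __len__(self):
        return len(self.data)


@dataclass
class MetaDataset:
    """The multi-lake monitoring corpus."""

    lakes: list[PlanktonTimeSeries]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [ts.data.assign(lake_id=ts.lake_id) for ts in self.lakes],
            ignore_index=True,
        )

    @property
    def n_samples(self) -> int:
        return sum(len(ts) for ts in self.lakes)


@dataclass
class LakeTruth:
    """Ground truth for one lake."""

    lake_id: str
    hatch_weeks: dict[str, np.ndarray]        # weeks where H_t > 0 was added
    hatch_magnitudes: dict[str, np.ndarray]   # ind L⁻¹ added at those weeks
    recruitment: dict[str, np.ndarray]        # per-week H_t series
    lag_weeks: dict[str, int]                 # true stimulus→hatch lag
    birth_rates: dict[str, np.ndarray]        # b_t used in the update, d⁻¹
    death_rates: dict[str, np.ndarray]        # d_t used in the update, d⁻¹
    breakpoint_weeks: dict[str, list[int]]    # injected mean-shift indices
    bloom_onset_weeks: np.ndarray             # by-construction onsets


@dataclass
class GroundTruth:
    """The generator's ledger across lakes."""

    lakes: list[LakeTruth]

    def for_lake(self, lake_id: str) -> LakeTruth:
        return next(t for t in self.lakes if t.lake_id == lake_id)


def _lake_rng(seed: int, lake_index: int, stream: int) -> np.random.Generator:
    # fixed-offset streams: adding lakes never perturbs earlier lakes
    return np.random.default_rng([int(seed), int(lake_index), int(stream)])


def generate_environment(
    config: GeneratorConfig, lake_index: int = 0,
    productivity_scale: float = 1.0,
) -> pd.DataFrame:
    """Weekly environmental covariates for one lake.

    Temperature is AR(1) around the configured mean; salinity a reflected
    random walk inside the configured range; PM a lognormal baseline plus
    Bernoulli resuspension pulses; Chl *a* lognormal with AR(1) persistence;
    Secchi depth declines with PM and Chl *a*. Deterministic given the seed.
    """
    n = config.n_weeks
    rng = _lake_rng(config.seed, lake_index, 0)

    temp = np.empty(n)
    temp[0] = config.temp_mean
    for t in range(1, n):
        temp[t] = (config.temp_mean
                   + config.temp_ar1 * (temp[t - 1] - config.temp_mean)
                   + rng.normal(0.0, config.temp_noise_sd))

    lo, hi = config.salinity_range
    sal = np.empty(n)
    sal[0] = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
    for t in range(1, n):
        step = rng.normal(0.0, config.salinity_step_sd)
        s = sal[t - 1] + step
        # reflect at the configured bounds
        if s < lo:
            s = lo + (lo - s)
        if s > hi:
            s = hi - (s - hi)
        sal[t] = min(max(s, lo), hi)

    log_chla = np.empty(n)
    mu = config.chla_log_mean + np.log(productivity_scale)
    innov_sd = config.chla_log_sd * np.sqrt(1.0 - config.chla_ar1 ** 2)
    log_chla[0] = mu + rng.normal(0.0, config.chla_log_sd)
    for t in range(1, n):
        log_chla[t] = (mu + config.chla_ar1 * (log_chla[t - 1] - mu)
                       + rng.normal(0.0, innov_sd))
    chla = np.exp(log_chla)

    pm_base = config.pm_baseline_median * np.exp(
        rng.normal(0.0, config.pm_baseline_sigma, size=n))
    pulses = rng.random(n) < config.pulse_prob
    pm = pm_base + np.where(pulses, config.pm_pulse_magnitude, 0.0)

    secchi = 150.0 / (pm + 0.05 * chla + 10.0)
    rain = rng.gamma(shape=2.0, scale=15.0, size=n)

    return pd.DataFrame({
        "week": np.arange(n),
        "day": np.arange(n) * config.step_days,
        "temp_c": temp,
        "salinity": sal,
        "secchi_m": secchi,
        "pm_mg_l": pm,
        "chla_ug_l": chla,
        "rainfall_mm": rain,
    })


def _phytoplankton(config: GeneratorConfig, rng: np.random.Generator,
                   chla: np.ndarray) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Phytoplankton group biomasses (mg C L⁻¹) with injected mean shifts."""
    n = config.n_weeks
    medians = {
        "filamentous_cyano": 4.0,
        "single_cyano": 1.5,
        "cryptophytes": 0.6,
        "chlorophytes": 0.8,
        "diatoms_chrysophytes": 0.4,
        "small_algae": 3.0,
    }
    bps = config.default_breakpoints()
    bp_index: dict[str, list[int]] = {}
    cols = {}
    for var, med in medians.items():
        level = np.full(n, med)
        for bp in bps:
            if bp.variable == var and 0 < bp.week < n:
                level[bp.week:] *= bp.factor
                bp_index.setdefault(var, []).append(int(bp.week))
        scale = 0.3 + 0.7 * chla / np.median(chla)  # track productivity
        cols[var] = level * scale * np.exp(rng.normal(0.0, 0.25, size=n))
    for v in bp_index:
        bp_index[v] = sorted(bp_index[v])
    return pd.DataFrame(cols), bp_index


def generate_rotifer_dynamics(
    env: pd.DataFrame, config: GeneratorConfig,
    lake_index: int = 0, lake_id: str = "lake_0",
    meta: LakeMeta | None = None,
) -> tuple[PlanktonTimeSeries, LakeTruth]:
    """Rotifer birth–death dynamics with external hatch recruitment.

    Weekly update per species (step Δ = ``config.step_days`` days):

        ``N(t+1) = N(t) · exp(Δ·(b_t − d_t)) + H_t``

    with ``b_t = ln(1 + E_t/D_E(T_t))`` from the generated egg ratio,
    ``d_t = d0 + noise`` and hatch input
    ``H_t = η · max(0, PM(t − L) − threshold)`` for species lag L. Emitted
    egg and female counts are consistent with E_t, so the egg-ratio method
    recovers b_t exactly on noise-free output.
    """
    if len(env) < config.n_weeks:
        raise InvalidConfigError("environment series shorter than n_weeks")
    n = config.n_weeks
    rng = _lake_rng(config.seed, lake_index, 1)
    temp = np.clip(env["temp_c"].to_numpy(), *config.dev_model.valid_range)
    chla = env["chla_ug_l"].to_numpy()
    pm = env["pm_mg_l"].to_numpy()
    d_e = np.asarray(config.dev_model(temp))

    chla_ref = float(np.exp(config.chla_log_mean))
    data = {c: env[c].to_numpy() for c in env.columns}
    hatch_weeks, hatch_mags, recruit = {}, {}, {}
    lag_map, b_map, d_map = {}, {}, {}
    total_biomass = np.zeros(n)

    for si, sp in enumerate(config.species):
        lag = config.hatch_lag_weeks + config.species_lag_offsets[si]
        # resource-coupled lognormal egg ratio, positive-skewed
        egg_noise = rng.normal(0.0, config.egg_noise_sd, size=n)
        e_ratio = (config.mean_eggs_per_female
                   * (chla / chla_ref) ** config.resource_coupling
                   * np.exp(egg_noise))
        b = np.log1p(e_ratio / d_e)
        d = config.d0 + rng.normal(0.0, config.d_noise_sd, size=n)

        h = np.zeros(n)
        idx = np.arange(n)
        src = idx - lag
        okay = src >= 0
        h[okay] = config.eta * np.maximum(0.0, pm[src[okay]] - config.pm_threshold)
        h[0] = 0.0  # week 0 is the initial state; nothing can arrive into it

        npop = np.empty(n)
        npop[0] = config.n0 * (0.5 + si * 0.3)
        for t in range(n - 1):
            npop[t + 1] = (npop[t] * np.exp(config.step_days * (b[t] - d[t]))
                           + h[t + 1])
            # residual background population below practical detection
            npop[t + 1] = max(npop[t + 1], 1.0)

        females = npop.copy()                  # amictic, all-female stock
        eggs = e_ratio * females
        mass = SPECIES_MASS.get(sp, 1.0e-4)
        biomass = npop * mass
        total_biomass += biomass

        data[f"density_{sp}"] = npop
        data[f"biomass_{sp}"] = biomass
        data[f"eggs_{sp}"] = eggs
        data[f"females_{sp}"] = females

        pos = np.flatnonzero(h > 0)
        hatch_weeks[sp] = pos
        hatch_mags[sp] = h[pos]
        recruit[sp] = h
        lag_map[sp] = int(lag)
        b_map[sp] = b
        d_map[sp] = d

    phyto, bp_index = _phytoplankton(config, rng, chla)
    for c in phyto.columns:
        data[c] = phyto[c].to_numpy()
    data["total_rotifer_biomass"] = total_biomass

    # by-construction bloom onsets on the noise-free total biomass:
    # >200% jump between consecutive weeks and above 4 g DM m⁻³
    ratio = total_biomass[1:] / np.maximum(total_biomass[:-1], 1e-12)
    onsets = np.flatnonzero((ratio > 3.0) & (total_biomass[1:] > 4.0)) + 1

    frame = pd.DataFrame(data)
    truth = LakeTruth(
        lake_id=lake_id, hatch_weeks=hatch_weeks, hatch_magnitudes=hatch_mags,
        recruitment=recruit, lag_weeks=lag_map, birth_rates=b_map,
        death_rates=d_map, breakpoint_weeks=bp_index,
        bloom_onset_weeks=onsets,
    )
    return PlanktonTimeSeries(lake_id=lake_id, data=frame, meta=meta), truth


def generate_lake(config: GeneratorConfig, lake_index: int = 0,
                  ) -> tuple[PlanktonTimeSeries, LakeTruth]:
    """Environment + dynamics + metadata for one lake."""
    rng = _lake_rng(config.seed, lake_index, 2)
    meta = LakeMeta(
        lake_id=f"lake_{lake_index}",
        ephemeral=bool(rng.random() < 0.3),
        rainy_season_start_week=int(rng.integers(0, 52)),
        monthly_rainfall_mm=float(rng.gamma(3.0, 25.0)),
        productivity_scale=float(np.exp(rng.normal(0.0, 0.4))),
    )
    env = generate_environment(config, lake_index, meta.productivity_scale)
    return generate_rotifer_dynamics(
        env, config, lake_index, meta.lake_id, meta)


def generate_multilake_dataset(
    config: GeneratorConfig,
) -> tuple[MetaDataset, GroundTruth]:
    """The full monitoring corpus: ``n_lakes`` weekly lake series + ledger."""
    lakes, truths = [], []
    for i in range(config.n_lakes):
        ts, truth = generate_lake(config, i)
        lakes.append(ts)
        truths.append(truth)
    return MetaDataset(lakes=lakes), GroundTruth(lakes=truths)
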