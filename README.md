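# bloomkit

Analysis toolkit for **non-seasonal zooplankton blooms in shallow soda
lakes**: bloom-onset detection across multi-lake monitoring corpora,
egg-ratio demography, population projection with resting-egg recruitment
inference, lagged variance partitioning of environmental drivers,
phytoplankton breakpoint detection, and the lake energy-export arithmetic
for flamingo grazing — plus a synthetic-data generator with a ground-truth
ledger so the whole chain is testable without any field download.

Built for quantitative ecologists and limnologists working with weekly (or
coarser) plankton time series: per-sample species densities and biomass,
egg/female counts and environmental covariates in plain CSV.

## The science in brief

Rotifer populations in tropical soda lakes grow as a pelagic birth–death
process with episodic external recruitment from a sediment resting-egg
bank. Per sampling interval the egg-ratio method gives

    r = (ln N₂ − ln N₁)/(t₂ − t₁)          in situ growth rate (d⁻¹)
    b = ln(1 + N_E /(D_E · N_♀))           birth rate from the egg ratio
    d = b − r                              death rate

where `D_E` is the temperature-dependent egg development time. Death rates
near or below zero flag population growth that pelagic reproduction cannot
explain — the signature of hatching from the egg bank. Projections
`N(t+Δ) = N(t)·exp(Δ(b(t) − d))` under scenario death rates (0, 0.11,
0.43 d⁻¹), with bootstrap 95% envelopes from Poisson-resampled egg counts,
turn that signature into a number: the observed density minus the upper
95% bound is a conservative estimate of external recruitment.

Around this core: a bloom-onset rule (biomass jump > 3× and above
4 g DM m⁻³ or a lake-specific 90% CI), mixed-effect logistic regressions of
onset probability with all-subsets AIC selection, partial redundancy
analysis partitioning rotifer community variance between intrinsic-growth
drivers and the sediment-resuspension proxy (particulate matter) at lags of
0–7 weeks with Bonferroni-corrected permutation tests, and penalized-
contrast (Lavielle) mean-shift segmentation of phytoplankton series.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import pandas as pd
from bloomkit import blooms, demography, recruitment
from bloomkit.synthetic import GeneratorConfig, generate_lake

# a 40-week synthetic lake with known hatch pulses
cfg = GeneratorConfig(n_weeks=40, n_lakes=1, seed=11)
ts, truth = generate_lake(cfg)

# 1. detect bloom onsets on total rotifer biomass
flags, events = blooms.detect_bloom_onsets(
    ts.data["total_rotifer_biomass"].to_numpy(),
    blooms.BloomRule(factor=3.0, abs_threshold=4.0, mode="fixed"))
print("onset weeks:", [e.onset_index for e in events])

# 2. egg-ratio demography around the first onset
ds = demography.demographic_series(ts.data, "B_dimidiatus", cfg.dev_model)
w = events[0].onset_index
print("interval %d: b=%.3f  r=%.3f  d=%.3f" %
      (w, ds.data["b"][w-1], ds.data["r"][w-1], ds.data["d"][w-1]))

# 3. how much of the bloom does pelagic reproduction explain?
egg = pd.DataFrame({
    "day": [0.0, 7.0],
    "eggs": ts.data[f"eggs_B_dimidiatus"].iloc[w-1:w+1].to_numpy(),
    "females": ts.data[f"females_B_dimidiatus"].iloc[w-1:w+1].to_numpy(),
    "temp_c": ts.data["temp_c"].iloc[w-1:w+1].to_numpy()})
sc = recruitment.ScenarioConfig(
    n0=float(ts.data["density_B_dimidiatus"].iloc[w-1]), d=0.11, seed=0)
ens = recruitment.bootstrap_trajectory(egg, sc, cfg.dev_model)
est = recruitment.external_recruitment(
    float(ts.data["density_B_dimidiatus"].iloc[w]), ens)
print("observed %.0f, modelled upper bound %.0f -> external fraction %.2f"
      % (est.observed, est.modelled_upper, est.external_fraction))
```

Output:

```
onset weeks: [11, 34]
interval 11: b=0.253  r=1.557  d=-1.304
observed 54158, modelled upper bound 574 -> external fraction 0.99
```

The first bloom (week 11) shows the diagnostic pattern: observed growth
(r = 1.56 d⁻¹) far exceeds the egg-ratio birth rate (b = 0.25 d⁻¹), so the
death rate is strongly negative and ~99% of the observed bloom density is
attributed to recruitment from the egg bank rather than pelagic births —
this lake's ground-truth ledger confirms a hatch pulse arrived exactly in
week 11.

A command-line pipeline wraps the same stages:

```sh
bloomkit run --seed 3 --out results_dir     # simulate → detect → … → budget
bloomkit budget                             # one-line energy-export summary
```

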