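# Methods

This note documents the models behind `bloomkit`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real monitoring data.

## The study system and the model

Shallow tropical soda lakes carry rotifer-dominated zooplankton whose
blooms (up to several 10⁵ individuals L⁻¹) appear without seasonal
periodicity. The package implements the analysis chain used to dissect
such blooms: a pelagic birth–death model with external recruitment from a
sediment resting-egg bank, egg-ratio demography, a bloom-onset rule
applied across a multi-lake corpus, constrained-ordination variance
partitioning of environmental drivers with a lag scan, mean-shift
breakpoint detection in phytoplankton series, and the energy-export
arithmetic for flamingo grazing.

### Demography (egg-ratio method)

Per sampling interval of a species' density series:

* growth rate `r = (ln N₂ − ln N₁)/(t₂ − t₁)` (d⁻¹),
* birth rate `b = ln(1 + c_E·N_E/(D_E·N_♀))` from the egg ratio
  (eggs per female divided by the egg development time `D_E`),
* death rate `d = b − r`.

`b` is non-negative by construction; `d < 0` is a legitimate result and is
flagged as the signature of external recruitment — births alone could not
have produced the observed growth. Rates are always per day; interval
lengths come from timestamps. Zero-density samples break the rate chain
(ln 0 is undefined); they are marked invalid, never interpolated, because
interpolation would fabricate dynamics.

**Egg development time.** The temperature dependence is an anchored Q10
form `D_E(T) = D_ref · Q10^((T_ref − T)/10)` with defaults `D_ref = 1 d` at
`T_ref = 25 °C`, `Q10 = 2.5`, valid on 10–35 °C. The only contract the
egg-ratio method needs is that development is faster when warmer; the Q10
form encodes exactly that with two interpretable constants, and any
user-supplied monotone function can replace it. The egg-ratio correction is
an explicit multiplicative factor `c_E` (default 1.0, i.e. raw ratios), so
any external calibration is visible and overridable rather than baked in.

### Population projection and recruitment inference

`N(t+Δ) = N(t)·exp(Δ·(b(t) − d))` with the birth-rate series held
piecewise-constant between (weekly) egg observations and a daily default
step. Canonical death-rate scenarios: `d = 0` (maximal intrinsic growth),
`d = 0.11 d⁻¹` (age-related losses only; the reciprocal of a 9.5 d mean
lifespan under exponential survivorship) and `d = 0.43 d⁻¹` (mean field
mortality including predation). `d` is a scenario input, never fitted.

Confidence envelopes: the resampling scheme was an open design choice. We
use Poisson resampling of the raw egg and female counts per sampling date
(1000 replicates, seeded), recomputing `b` per replicate and projecting;
the envelope is the pointwise 2.5/97.5 percentile band. Poisson is the
natural conservative model for count data and makes the envelope width
shrink as 1/√count.

External recruitment at the horizon is the conservative deficit
`max(0, observed − upper95)`, reported also as a fraction of the observed
density. This estimate deliberately conflates individuals hatched from the
egg bank with the offspring they produced before the observation — weekly
count data cannot separate them — and is floored at zero because only the
deficit interpretation is meaningful.

### Bloom-onset rule and drivers

A sample is an onset when biomass (i) exceeded `factor` × the previous
sample and (ii) exceeded an absolute threshold (4 g DM m⁻³) and/or the
upper limit of a lake-specific 90% normal-theory CI of mean biomass. The
growth factor default is 3.0 — a literal ">200% increase" — with 2.0
(doubling) available, since both definitions circulate; all four
threshold-combination modes (`fixed`, `ci`, `either`, `both`) are
implemented with `either` as default. A rise from exactly zero biomass
counts as an unbounded increase, so only the threshold condition decides
there. Onset magnitude classes partition at 4, 8 and 20 g DM m⁻³ with the
boundary value 20 in the largest class.

Bloom probability is modelled by a mixed-effect logistic regression with a
lake random intercept. The marginal likelihood integrates the scalar random
effect by fixed-order Gauss–Hermite quadrature (order 20) and is maximised
with analytic gradients; with a single scalar effect the quadrature is
essentially exact, the likelihood deterministic, and the fit agrees with
`lme4::glmer(nAGQ = 20)` to ~1e-3 (checked in the test suite). AIC counts
fixed effects plus the random-intercept standard deviation. Model choice is
all-subsets enumeration (≤ 12 candidates) by minimum AIC; non-converged
subsets stay in the table but are excluded from the ranking. Complete
separation yields a flagged non-converged fit, not a crash.

### Variance partitioning and the lag scan

Redundancy analysis with z-standardized response columns by default
(species biomasses live on very different scales; Hellinger is available),
Ezekiel-adjusted R². Partial RDA residualises response and focal predictors
on the conditioning set but keeps the *original* total variance as
denominator, so the conditional R² equals the nested-model difference
`R²(X∪Z) − R²(Z)` exactly — the identity is asserted to 1e-10 in tests.
Two-set partitions report unique, shared and residual fractions; the
unadjusted fractions sum to one exactly, and adjusted fractions may be
slightly negative and are reported as computed, never truncated. The
implementation was cross-checked against `vegan::varpart` to full printed
precision.

Significance of each conditional fraction uses permutation of the
residuals of the reduced model (999 permutations by default, seeded),
with pseudo-F `(R²_cond/m)/((1−R²_full)/(n−m−q−1))` and
`p = (1 + #{F* ≥ F})/(1 + n_perm)` — exact under the null for conditioned
ordination. The lag scan repeats the partition with the response shifted
0–7 weeks after the predictors over a fixed window, so n is identical at
every lag; p-values are Bonferroni-corrected with family size 8. Positive
lag means biology responds after the environment.

### Breakpoint detection

Mean-shift segmentation by least squares: dynamic programming finds the
globally optimal segment boundaries for each candidate K (minimum segment
length 2, ties broken toward the earliest breakpoint for determinism), and
the number of segments follows the penalized-contrast rule: rescale J(K)
to [1, Kmax], take the discrete second difference, and choose the largest
K whose second difference exceeds S = 0.75; otherwise K = 1. Kmax defaults
to min(8, n/4). Abundance series are log(x + floor)-transformed first
(floor = half the smallest positive value) because they span orders of
magnitude; segment means are reported on the original scale. The DP is
verified against exhaustive enumeration of all segmentations for n ≤ 12.
Note that with short series (n ≈ 30) the S = 0.75 rule retains appreciable
false-split probability on unstructured noise; it is a selection
heuristic, not a calibrated test.

### Energy export

`export = ingested × (1 − returned)` on fractions of daily primary
production; with ingestion 0.60 and one-third return this gives 0.40.
The ingestion figure is reported in the literature as a lower bound
("> 60%"); the arithmetic treats it as a point value, and no uncertainty
propagation is attempted because none is available.

## The synthetic generator

The generator emulates a seven-lake weekly monitoring corpus so every
stage is testable against known ground truth:

* **Environment** — AR(1) temperature (mean 25 °C), a reflected random
  walk for salinity inside 5.1–62.5, lognormal AR(1) chlorophyll *a*
  spanning roughly 11–1650 µg L⁻¹, lognormal particulate matter (median
  80 mg L⁻¹) plus Bernoulli resuspension pulses (+180 mg L⁻¹ at
  probability 0.10 per week), and Secchi depth declining with turbidity.
* **Rotifers** — three species; weekly update
  `N(t+1) = N(t)·exp(7·(b_t − d_t)) + H_t` with `b_t` from a
  resource-coupled lognormal egg ratio, `d_t = d0 + noise`
  (`d0 = 0.43 d⁻¹`), and hatch input
  `H_t = η·max(0, PM(t−L) − threshold)` at stimulus→hatch lag `L = 3`
  weeks (+1 week for the later-hatching larger congener, matching the
  observed succession). Hatch pulses are additive *after* the exponential
  step because emergence is external recruitment, not a birth-rate change.
  The default egg ratio (0.30 eggs per female) puts mean `b ≈ 0.26 d⁻¹`
  well below `d0`, so pulses produce sharp bloom spikes that collapse
  within one or two samples — the episodic regime of these lakes — with
  background densities of order 10³–10⁴ and blooms above 10⁵ ind L⁻¹.
  Emitted egg and female counts are exactly consistent with `b_t`, so the
  egg-ratio method recovers the generator's rates to machine precision on
  noise-free output.
* **Phytoplankton** — five group series plus a small-algae aggregate,
  lognormal around level curves with injected mean shifts (default: a
  small-algae decline at ~n/3 and a filamentous increase two weeks later,
  the grazing-switch signature).
* **Ledger** — every hatch pulse (time, magnitude), the true lag,
  per-week recruitment, injected breakpoints and by-construction bloom
  onsets. One RNG stream per lake is derived from the master seed by fixed
  offsets, so adding lakes never perturbs earlier ones and identical
  config + seed is byte-identical.

Distributional forms (lognormal PM and egg ratios, AR(1) persistence) are
stated modelling assumptions — realistic shapes for these quantities — not
inferences from any particular dataset.

**What passing tests show.** Parameter recovery (lag, recruitment,
breakpoints, death rates) demonstrates the estimators are correct under
the generative model they assume: additive pulse recruitment, exact
egg-count consistency, mean-shift phytoplankton changes. Real monitoring
data add observation error in counts, taxonomic aggregation, missing
weeks, and drivers outside the model; recovery rates here are upper
bounds on field performance, not predictions of it.

## Problem sizes and numerics

Test and acceptance runs use deliberately compact problems chosen to make
the Monte-Carlo answers stable: 40–60-week series, 20-replicate recovery
suites, 500 null datasets with 99 permutations for the type-I check, and
1000 bootstrap replicates. Tolerances: algebraic identities at 1e-10;
cross-library oracle agreement at 1e-3 or better; Monte-Carlo rates with
~2σ binomial slack. Degenerate inputs are handled explicitly: zero
densities break rate chains, zero females make the birth rate undefined
(raised, never silently 0), constant series yield no breakpoints and no
onsets, zero-variance covariates are rejected rather than standardized.

## Known limitations

* The egg-development parameterisation and egg-ratio correction are
  stated defaults, not field calibrations; both are configurable.
* The mixed logit supports a single scalar (lake) random intercept only.
* The recruitment estimate cannot separate hatchlings from their
  offspring; it is conservative via the upper CI bound but biased upward
  by within-interval reproduction of recruits.
* Penalized-contrast segment selection is not calibrated for short, noisy
  series; treat K > 1 on n < 30 with caution.
* No temporal autocorrelation modelling anywhere in the regression
  machinery (the analyses assume none is present, and the permutation
  scheme assumes exchangeable residuals).
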