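"""Bloom-onset detection and drivers across a multi-lake corpus.

A sampling occasion is scored as the onset of a rotifer bloom when total
rotifer biomass both (1) jumped by more than a configurable growth factor
relative to the previous sample (default 3×, i.e. a >200% increase) and
(2) exceeded an absolute threshold (default 4 g DM m⁻³) and/or the upper
limit of a lake-specific confidence interval of mean biomass — the CI
alternative accommodates differences in baseline productivity among lakes.

The probability of bloom onset is then modelled as a mixed-effect logistic
regression with lake identity as a random intercept, with all-subsets AIC
selection over candidate fixed effects. statsmodels has no frequentist
random-intercept logit, so the marginal likelihood is maximised directly,
integrating the lake effect by fixed-order Gauss–Hermite quadrature: with
a single scalar random effect the quadrature is essentially exact and the
likelihood fully deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BloomRule",
    "BloomEvent",
    "LogitModelFit",
    "PairedContrast",
    "BloomFrequency",
    "detect_bloom_onsets",
    "lake_ci_threshold",
    "standardize_covariates",
    "fit_bloom_logit",
    "select_model_aic",
    "prebloom_contrast",
    "bloom_frequency",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class BloomRule:
    """The bloom-onset rule.

    ``factor`` is the required biomass ratio B_i/B_{i-1} (3.0 ≡ a >200%
    increase; 2.0 ≡ doubling). ``mode`` controls how the absolute threshold
    and the lake CI threshold combine: ``fixed`` (absolute only), ``ci``
    (lake CI only), ``either`` (default) or ``both``.
    """

    factor: float = 3.0
    abs_threshold: float = 4.0
    ci_level: float = 0.90
    mode: str = "either"

    def __post_init__(self):
        if self.factor <= 1:
            raise ValueError("growth factor must exceed 1")
        if self.abs_threshold <= 0:
            raise ValueError("absolute threshold must be positive")
        if not (0 < self.ci_level < 1):
            raise ValueError("CI level must be in (0, 1)")
        if self.mode not in {"fixed", "ci", "either", "both"}:
            raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass(frozen=True)
class BloomEvent:
    lake_id: str
    onset_index: int
    biomass: float           # g DM m⁻³ at onset
    magnitude_class: str     # "<4", "4-8", "8-20", ">=20"


def _magnitude_class(biomass: float) -> str:
    if biomass >= 20:
        return ">=20"
    if biomass >= 8:
        return "8-20"
    if biomass >= 4:
        return "4-8"
    return "<4"


def lake_ci_threshold(biomass, level: float = 0.90) -> float:
    """Upper limit of the normal-theory CI for a lake's mean biomass.

    ``mean + z_{(1+level)/2} · sd/√n``; z = 1.6449 at level 0.90.
    """
    x = np.asarray(biomass, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 biomass values for a lake CI")
    z = stats.norm.ppf((1 + level) / 2)
    return float(x.mean() + z * x.std(ddof=1) / math.sqrt(len(x)))


def detect_bloom_onsets(
    biomass, rule: BloomRule = BloomRule(), lake_id: str = "lake",
) -> tuple[np.ndarray, list[BloomEvent]]:
    """Apply the onset rule to one lake's total rotifer biomass series.

    Returns the 0/1 onset flag vector (flag[0] always 0 — an onset needs a
    predecessor) and the list of events. A rise from exactly zero biomass
    counts as an unbounded increase, so only the threshold condition
    decides there.
    """
    b = np.asarray(biomass, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise InsufficientDataError("need >= 2 samples")
    if np.any(~np.isfinite(b)):
        raise ValueError("biomass series contains missing values")
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")

    if rule.mode in {"ci", "either", "both"}:
        ci_thr = lake_ci_threshold(b, rule.ci_level)
    else:
        ci_thr = np.inf

    flags = np.zeros(len(b), dtype=int)
    events: list[BloomEvent] = []
    for i in range(1, len(b)):
        growth = (b[i] > rule.factor * b[i - 1]) if b[i - 1] > 0 else (b[i] > 0)
        over_abs = b[i] > rule.abs_threshold
        over_ci = b[i] > ci_thr
        over = {
            "fixed": over_abs,
            "ci": over_ci,
            "either": over_abs or over_ci,
            "both": over_abs and over_ci,
        }[rule.mode]
        if growth and over:
            flags[i] = 1
            events.append(BloomEvent(lake_id, i, float(b[i]),
                                     _magnitude_class(float(b[i]))))
    return flags, events


def standardize_covariates(
    frame: pd.DataFrame, variables: list[str], mode: str = "z",
) -> pd.DataFrame:
    """Z-standardize (pooled across all lakes) or range-transform to [0, 1].

    Pooled standardization puts covariates measured on very different
    scales (salinity, Chl a, rainfall) on a common footing before pooling
    lakes in one regression; the range transform is the plotting variant.
    """
    out = frame.copy()
    for v in variables:
        if v not in frame.columns:
            raise KeyError(f"variable {v!r} not in dataset")
        x = frame[v].astype(float)
        if mode == "z":
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"variable {v!r} has zero pooled variance")
            out[v] = (x - x.mean()) / sd
        elif mode == "range":
            span = x.max() - x.min()
            if span == 0:
                raise ValueError(f"variable {v!r} is constant")
            out[v] = (x - x.min()) / span
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


@dataclass
class LogitModelFit:
    """A fitted (mixed) logistic regression.

    ``k`` counts estimated parameters: fixed effects (incl. intercept)
    plus the random-intercept standard deviation when present;
    ``aic = 2k − 2·loglik``.
    """

    params: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma_lake: float
    loglik: float
    aic: float
    n: int
    k: int
    converged: bool
    predictors: tuple[str, ...] = ()
    message: str = ""


_GH_ORDER = 20


def _mixed_logit_nll(params, x, y, group_slices, nodes, log_weights,
                     with_grad=False):
    beta, log_sigma = params[:-1], params[-1]
    sigma = math.exp(min(log_sigma, 10.0))
    eta = x @ beta
    lin = eta[:, None] + sigma * nodes[None, :]
    # log Bernoulli likelihood per observation and node
    ll = np.where(y[:, None] > 0.5,
                  -np.logaddexp(0.0, -lin), -np.logaddexp(0.0, lin))
    p = special.expit(lin)
    resid = y[:, None] - p                        # ∂ll/∂η per obs, node
    total = 0.0
    grad = np.zeros_like(params)
    for lo, hi in group_slices:
        g = ll[lo:hi].sum(axis=0) + log_weights   # (K,)
        lse = special.logsumexp(g)
        total += lse
        if with_grad:
            post = np.exp(g - lse)                # posterior node weights
            r = resid[lo:hi]                      # (n_g, K)
            grad[:-1] += (x[lo:hi].T @ r) @ post
            grad[-1] += sigma * float((r.sum(axis=0) * nodes) @ post)
    if with_grad:
        return -total, -grad
    return -total


def fit_bloom_logit(
    frame: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    group: str | None = "lake_id",
    add_intercept: bool = True,
) -> LogitModelFit:
    """Mixed-effect logistic regression of bloom onset on covariates.

    Lake identity (``group``) enters as a random intercept whose scalar
    integral is evaluated by Gauss–Hermite quadrature (order 20); the
    marginal likelihood is maximised over (β, log σ). With ``group=None``
    (σ forced to 0) the fit reduces to a plain logistic regression.
    Complete separation or optimizer failure is reported as a
    non-converged fit, never a crash.
    """
    y = frame[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    cols = list(fixed)
    x = frame[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
    names = list(cols)
    if add_intercept:
        x = np.column_stack([np.ones(len(y)), x])
        names = ["intercept"] + names
    n, p = x.shape

    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess1
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    def _plain_start():
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, x).fit(disp=0, maxiter=200)
            return np.asarray(res.params, float), True, ""
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as e:
            return np.zeros(p), False, f"plain logit failed: {e}"

    beta0, start_ok, msg = _plain_start()

    if group is None:
        # σ ≡ 0: plain logistic regression
        res = sm.Logit(y, x).fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=names)
        return LogitModelFit(
            params=params,
            zvalues=pd.Series(res.tvalues, index=names),
            pvalues=pd.Series(res.pvalues, index=names),
            sigma_lake=0.0, loglik=float(res.llf),
            aic=2 * p - 2 * float(res.llf), n=n, k=p,
            converged=bool(res.mle_retvals["converged"]),
            predictors=tuple(cols),
        )

    codes, _ = pd.factorize(frame[group], sort=True)
    order = np.argsort(codes, kind="stable")
    x_s, y_s, codes_s = x[order], y[order], codes[order]
    bounds = np.flatnonzero(np.diff(codes_s)) + 1
    starts = np.concatenate([[0], bounds, [n]])
    group_slices = list(zip(starts[:-1], starts[1:]))
    if len(group_slices) < 2:
        raise ValueError("need >= 2 groups for a random effect")

    gh_x, gh_w = np.polynomial.hermite.hermgauss(_GH_ORDER)
    nodes = math.sqrt(2.0) * gh_x
    log_weights = np.log(gh_w) - 0.5 * math.log(math.pi)

    theta0 = np.concatenate([beta0, [math.log(0.5)]])
    with np.errstate(all="ignore"):
        res = optimize.minimize(
            _mixed_logit_nll, theta0,
            args=(x_s, y_s, group_slices, nodes, log_weights, True),
            jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
    beta_hat = res.x[:-1]
    sigma_hat = math.exp(min(res.x[-1], 10.0))
    loglik = -float(res.fun)
    grad_ok = np.max(np.abs(np.atleast_1d(res.jac))) < 1e-3
    converged = (bool(res.success) or grad_ok) and start_ok and np.isfinite(loglik)

    se = np.full(p, np.nan)
    try:
        hess = approx_hess1(
            res.x, _mixed_logit_nll,
            args=(x_s, y_s, group_slices, nodes, log_weights))
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)[:p]
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        converged = False

    with np.errstate(all="ignore"):
        z = beta_hat / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    k = p + 1  # fixed effects + random-intercept sd
    return LogitModelFit(
        params=pd.Series(beta_hat, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma_lake=sigma_hat, loglik=loglik, aic=2 * k - 2 * loglik,
        n=n, k=k, converged=converged, predictors=tuple(cols),
        message=str(res.message) + ("" if start_ok else f"; {msg}"),
    )


def select_model_aic(
    frame: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    group: str | None = "lake_id",
) -> tuple[LogitModelFit, pd.DataFrame]:
    """All-subsets AIC selection over candidate fixed effects.

    Fits every one of the 2^k subsets (including intercept-only) and
    returns the minimum-AIC converged fit plus the full AIC table. Failed
    fits stay in the table flagged non-converged but are excluded from the
    ranking.
    """
    if len(candidates) > 12:
        raise ValueError("all-subsets enumeration limited to 12 candidates")
    rows, fits = [], []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            try:
                fit = fit_bloom_logit(frame, outcome, list(subset), group)
            except Exception as e:  # noqa: BLE001 - recorded, not raised
                fit = LogitModelFit(
                    params=pd.Series(dtype=float), zvalues=pd.Series(dtype=float),
                    pvalues=pd.Series(dtype=float), sigma_lake=np.nan,
                    loglik=np.nan, aic=np.inf, n=len(frame), k=len(subset) + 2,
                    converged=False, predictors=subset, message=str(e))
            fits.append(fit)
            rows.append({
                "predictors": "+".join(subset) if subset else "(intercept)",
                "n_predictors": size, "k": fit.k, "loglik": fit.loglik,
                "aic": fit.aic, "converged": fit.converged,
            })
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise RuntimeError("no candidate model converged")
    best = min(ok, key=lambda f: f.aic)
    return best, table


@dataclass(frozen=True)
class PairedContrast:
    n_pairs: int
    mean_difference: float
    t_statistic: float
    p_value: float
    degenerate: bool = False     # zero-variance differences: p is a limit


def prebloom_contrast(
    frame: pd.DataFrame, events: list[BloomEvent], variable: str,
    index_col: str | None = None,
) -> PairedContrast:
    """Paired pre-bloom vs onset contrast of a phytoplankton variable.

    For every bloom event with a defined predecessor sample, pairs the
    variable at the onset with its value one sample earlier and runs a
    two-sided paired t-test on the differences.
    """
    if variable not in frame.columns:
        raise KeyError(f"variable {variable!r} not in dataset")
    pre, on = [], []
    for ev in events:
        sub = frame
        if "lake_id" in frame.columns:
            sub = frame[frame["lake_id"] == ev.lake_id].reset_index(drop=True)
        if ev.onset_index < 1 or ev.onset_index >= len(sub):
            continue
        pre.append(float(sub[variable].iloc[ev.onset_index - 1]))
        on.append(float(sub[variable].iloc[ev.onset_index]))
    if len(pre) < 2:
        raise InsufficientDataError("need >= 2 bloom events with predecessors")
    diff = np.asarray(on) - np.asarray(pre)
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedContrast(len(diff), 0.0, 0.0, 1.0, degenerate=True)
        # constant non-zero shift: t diverges, p → 0
        return PairedContrast(len(diff), float(diff.mean()),
                              math.inf if diff.mean() > 0 else -math.inf,
                              0.0, degenerate=True)
    t, p = stats.ttest_rel(on, pre)
    return PairedContrast(len(diff), float(diff.mean()), float(t), float(p))


@dataclass(frozen=True)
class BloomFrequency:
    n_events: int
    monitored_months: float
    months_per_bloom: float      # inf (flagged) when no events
    blooms_per_month: float
    no_events: bool = False


def bloom_frequency(monitored_months: float, n_events: int) -> BloomFrequency:
    """Average bloom return interval: total monitored months per onset."""
    if monitored_months <= 0:
        raise ValueError("monitored duration must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    if n_events == 0:
        return BloomFrequency(0, monitored_months, math.inf, 0.0, no_events=True)
    return BloomFrequency(
        n_events, monitored_months,
        monitored_months / n_events, n_events / monitored_months,
    )
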