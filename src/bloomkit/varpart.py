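"""Redundancy analysis, variance partitioning and the lagged driver scan.

Redundancy analysis (RDA) measures the share of total variance in a
multivariate species matrix Y explained by a predictor matrix X:
Ŷ = X(XᵀX)⁻¹XᵀY after centring, R² = tr(ŶᵀŶ)/tr(YᵀY), with the Ezekiel
small-sample correction 1 − (1−R²)(n−1)/(n−m−1). Partial RDA removes a
conditioning set Z first (residualise Y and X on Z); the conditional R²
reported here keeps the *original* total variance of Y as denominator, so
it equals the nested-model difference R²(X∪Z) − R²(Z) exactly.

Two-set variance partitioning splits total explained variance into the
fraction unique to the intrinsic-growth predictors (a), the fraction
unique to the hatching proxy (c, particulate matter), their shared part
(b) and the residual; a + b + c + residual = 1 for the unadjusted
fractions. Adjusted fractions can be slightly negative and are reported
as computed. Significance of each conditional fraction comes from a
permutation test on the residuals of the reduced model, and the whole
partition is repeated at response lags of 0–7 weeks (Bonferroni family
size 8) over a fixed window so n stays constant across lags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RDAFit",
    "VarPartResult",
    "CollinearityError",
    "rda",
    "partial_rda",
    "variance_partition",
    "permutation_test",
    "lagged_varpart",
    "intrinsic_driver_regression",
]


class CollinearityError(ValueError):
    """Predictor matrix rank-deficient after centring."""


def _as_matrix(a, name) -> np.ndarray:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float)
    m = np.asarray(a, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    return m


def _colnames(a, prefix, m) -> list[str]:
    if isinstance(a, pd.DataFrame):
        return [str(c) for c in a.columns]
    return [f"{prefix}{i}" for i in range(m)]


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def _standardize_y(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "standardize":
        yc = _center(y)
        sd = y.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return yc / sd
    if transform == "hellinger":
        if np.any(y < 0):
            raise ValueError("Hellinger transform requires non-negative data")
        rowsum = y.sum(axis=1, keepdims=True)
        rowsum = np.where(rowsum > 0, rowsum, 1.0)
        return _center(np.sqrt(y / rowsum))
    if transform == "center":
        return _center(y)
    raise ValueError(f"unknown transform {transform!r}")


def _check_rank(x: np.ndarray, names: list[str]):
    if x.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(x)
    if r < x.shape[1]:
        # name offending columns via QR pivot magnitudes
        _, rr = np.linalg.qr(x)
        diag = np.abs(np.diag(rr))
        tol = max(x.shape) * np.finfo(float).eps * (diag.max() or 1.0)
        bad = [names[i] for i in range(len(diag)) if diag[i] <= tol]
        raise CollinearityError(
            f"collinear predictors after centring: {bad or names}")


def _fit_ss(yt: np.ndarray, xc: np.ndarray) -> float:
    """Sum of squares of the projection of yt onto span(xc)."""
    if xc.shape[1] == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(xc, yt, rcond=None)
    return float(np.sum((xc @ coef) ** 2))


def _project(yt: np.ndarray, xc: np.ndarray) -> np.ndarray:
    if xc.shape[1] == 0:
        return np.zeros_like(yt)
    coef, *_ = np.linalg.lstsq(xc, yt, rcond=None)
    return xc @ coef


@dataclass
class RDAFit:
    r2: float
    adj_r2: float
    n: int
    m: int                        # focal predictor columns
    q: int = 0                    # conditioning columns
    eigenvalues: np.ndarray = field(default=None, repr=False)
    axes: np.ndarray = field(default=None, repr=False)


def _ezekiel(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda(y, x, transform: str = "standardize") -> RDAFit:
    """Redundancy analysis of response matrix ``y`` on predictors ``x``.

    Y columns are standardized by default (species biomasses live on very
    different scales); ``transform`` may be "hellinger" or "center".
    """
    ym = _as_matrix(y, "y")
    xm = _as_matrix(x, "x")
    if len(ym) != len(xm):
        raise ValueError("y and x must have the same number of rows")
    n, m = xm.shape
    yt = _standardize_y(ym, transform)
    xc = _center(xm)
    _check_rank(xc, _colnames(x, "x", m))
    total = float(np.sum(yt ** 2))
    if total == 0:
        raise ValueError("response matrix has zero total variance")
    yhat = _project(yt, xc)
    r2 = float(np.sum(yhat ** 2)) / total
    cross = yhat.T @ yhat
    eigval, eigvec = np.linalg.eigh(cross)
    order = np.argsort(eigval)[::-1]
    return RDAFit(
        r2=r2, adj_r2=_ezekiel(r2, n, m), n=n, m=m,
        eigenvalues=eigval[order], axes=eigvec[:, order],
    )


def partial_rda(y, x, z, transform: str = "standardize") -> RDAFit:
    """Partial RDA: variance of ``y`` explained by ``x`` after removing ``z``.

    Y and X are residualised on Z; the conditional R² keeps total variance
    of Y as denominator, so it equals R²(X∪Z) − R²(Z) exactly. The
    adjusted value is the difference of Ezekiel-adjusted nested R²s.
    """
    ym = _as_matrix(y, "y")
    xm = _as_matrix(x, "x")
    zm = _as_matrix(z, "z") if z is not None else np.empty((len(ym), 0))
    if not (len(ym) == len(xm) == len(zm)):
        raise ValueError("row counts differ")
    n, m = xm.shape
    q = zm.shape[1]
    yt = _standardize_y(ym, transform)
    xc, zc = _center(xm), _center(zm)
    _check_rank(xc, _colnames(x, "x", m))
    _check_rank(zc, _colnames(z, "z", q))
    total = float(np.sum(yt ** 2))
    y_res = yt - _project(yt, zc)
    x_res = xc - _project(xc, zc)
    # focal columns fully contained in span(Z) leave nothing to explain;
    # zero them out rather than projecting onto numerical-noise directions
    scale = np.linalg.norm(xc, axis=0)
    resid_norm = np.linalg.norm(x_res, axis=0)
    contained = resid_norm <= 1e-9 * np.maximum(scale, 1.0)
    if contained.any():
        x_res = x_res.copy()
        x_res[:, contained] = 0.0
    yhat = _project(y_res, x_res)
    r2_cond = float(np.sum(yhat ** 2)) / total
    r2_z = _fit_ss(yt, zc) / total
    adj = _ezekiel(r2_cond + r2_z, n, m + q) - _ezekiel(r2_z, n, q)
    cross = yhat.T @ yhat
    eigval, eigvec = np.linalg.eigh(cross)
    order = np.argsort(eigval)[::-1]
    return RDAFit(r2=r2_cond, adj_r2=adj, n=n, m=m, q=q,
                  eigenvalues=eigval[order], axes=eigvec[:, order])


@dataclass
class VarPartResult:
    """Two-set variance partition at one lag."""

    lag: int
    a: float                     # unique to X1 (intrinsic | PM)
    b: float                     # shared
    c: float                     # unique to X2 (PM | intrinsic)
    residual: float
    adj_a: float
    adj_b: float
    adj_c: float
    adj_residual: float
    p_a: float | None = None     # permutation p for X1 | X2
    p_c: float | None = None     # permutation p for X2 | X1
    p_a_bonferroni: float | None = None
    p_c_bonferroni: float | None = None
    n: int = 0
    note: str = "adjusted fractions may be negative; reported as computed"


def _r2_pair(yt, xm, total, n):
    """(R², adjusted R²) of yt on centred xm; df = effective rank, so the
    union of two overlapping predictor sets is charged only its true
    dimension."""
    xc = _center(xm)
    rank = int(np.linalg.matrix_rank(xc)) if xc.shape[1] else 0
    r2 = _fit_ss(yt, xc) / total
    return r2, _ezekiel(r2, n, rank)


def variance_partition(y, x1, x2, lag: int = 0,
                       transform: str = "standardize") -> VarPartResult:
    """Partition Y's variance between predictor sets X1 and X2.

    The two sets may share (even duplicate) columns: shared information
    lands in the joint fraction b, and the union's degrees of freedom are
    its effective rank.
    """
    ym = _as_matrix(y, "y")
    x1m = _as_matrix(x1, "x1")
    x2m = _as_matrix(x2, "x2")
    n = len(ym)
    yt = _standardize_y(ym, transform)
    total = float(np.sum(yt ** 2))
    r2_full, adj_full = _r2_pair(yt, np.hstack([x1m, x2m]), total, n)
    r2_1, adj_1 = _r2_pair(yt, x1m, total, n)
    r2_2, adj_2 = _r2_pair(yt, x2m, total, n)
    a = r2_full - r2_2
    c = r2_full - r2_1
    b = r2_full - a - c
    return VarPartResult(
        lag=lag, a=a, b=b, c=c, residual=1.0 - r2_full,
        adj_a=adj_full - adj_2, adj_b=adj_1 + adj_2 - adj_full,
        adj_c=adj_full - adj_1, adj_residual=1.0 - adj_full, n=n,
    )


def permutation_test(y, x, z, n_perm: int = 999, seed: int = 0,
                     transform: str = "standardize") -> tuple[float, float]:
    """Permutation p-value for the conditional effect of ``x`` given ``z``.

    Pseudo-F = (R²_cond/m) / ((1 − R²_full)/(n − m − q − 1)); permutes the
    residuals of the reduced model (Y | Z) and re-adds the Z fit — the
    standard exact-under-null scheme for conditioned ordination.
    p = (1 + #{F* ≥ F}) / (1 + n_perm). Returns (p, F_observed).
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives too coarse a p-value resolution")
    ym = _as_matrix(y, "y")
    xm = _as_matrix(x, "x")
    zm = _as_matrix(z, "z") if z is not None else np.empty((len(ym), 0))
    n, m = xm.shape
    q = zm.shape[1]
    dof = n - m - q - 1
    if dof <= 0:
        raise ValueError("not enough rows for the pseudo-F denominator")
    yt = _standardize_y(ym, transform)
    xc, zc = _center(xm), _center(zm)
    total = float(np.sum(yt ** 2))
    x_res = xc - _project(xc, zc)

    def pseudo_f(y_mat):
        fit_z = _project(y_mat, zc)
        y_res = y_mat - fit_z
        ss_cond = _fit_ss(y_res, x_res)
        ss_full = _fit_ss(y_mat, np.hstack([xc, zc]))
        denom = float(np.sum(y_mat ** 2))
        r2_cond = ss_cond / denom
        r2_full = ss_full / denom
        return (r2_cond / m) / ((1.0 - r2_full) / dof)

    f_obs = pseudo_f(yt)
    fit_z = _project(yt, zc)
    resid = yt - fit_z
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(fit_z + resid[perm]) >= f_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm), f_obs


def lagged_varpart(
    y: pd.DataFrame, x1: pd.DataFrame, x2: pd.DataFrame,
    max_lag: int = 7, n_perm: int = 999, seed: int = 0,
    transform: str = "standardize",
) -> list[VarPartResult]:
    """Repeat the partition with the response lagged 0..max_lag weeks.

    Positive lag means the biology responds k weeks *after* the
    environmental signal: response rows at weeks [max_lag, T) are paired
    with predictor rows k weeks earlier, so the window — and n — is
    identical for every lag. Permutation p-values for both conditional
    fractions are Bonferroni-corrected with family size max_lag + 1.
    """
    ym = _as_matrix(y, "y")
    x1m = _as_matrix(x1, "x1")
    x2m = _as_matrix(x2, "x2")
    t = len(ym)
    n_win = t - max_lag
    if n_win < x1m.shape[1] + x2m.shape[1] + 3:
        raise ValueError(
            f"series too short: window of {n_win} rows after reserving "
            f"{max_lag} lag weeks")
    family = max_lag + 1
    results = []
    for k in range(family):
        rows_y = np.arange(max_lag, t)
        rows_x = rows_y - k
        yw, x1w, x2w = ym[rows_y], x1m[rows_x], x2m[rows_x]
        vp = variance_partition(yw, x1w, x2w, lag=k, transform=transform)
        p_a, _ = permutation_test(yw, x1w, x2w, n_perm, seed=seed + 2 * k,
                                  transform=transform)
        p_c, _ = permutation_test(yw, x2w, x1w, n_perm, seed=seed + 2 * k + 1,
                                  transform=transform)
        vp.p_a, vp.p_c = p_a, p_c
        vp.p_a_bonferroni = min(1.0, family * p_a)
        vp.p_c_bonferroni = min(1.0, family * p_c)
        results.append(vp)
    return results


def intrinsic_driver_regression(
    frame: pd.DataFrame, response: str, candidates: list[str],
):
    """All-subsets OLS with AIC selection over intrinsic growth drivers.

    Returns (best statsmodels OLS results, AIC table with 2^k rows).
    """
    if len(candidates) > 12:
        raise ValueError("all-subsets enumeration limited to 12 candidates")
    import statsmodels.api as sm

    y = frame[response].astype(float)
    xall = frame[candidates].astype(float)
    _check_rank(_center(xall.to_numpy()), candidates)
    rows, fits = [], []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            x = sm.add_constant(xall[list(subset)]) if subset else \
                pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
            res = sm.OLS(y, x).fit()
            fits.append((subset, res))
            rows.append({
                "predictors": "+".join(subset) if subset else "(intercept)",
                "n_predictors": size, "aic": res.aic, "r2": res.rsquared,
            })
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best_subset, best = min(fits, key=lambda t: t[1].aic)
    return best, table
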