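"""Benchmark concentration (BMC) modeling of continuous dose-response data.

Transcriptomic endpoints: probes are prefiltered with a permutation
Williams' trend test (isotonic/pool-adjacent-violators amalgamated means)
plus a fold-change gate, then fit with a nine-model continuous suite
(linear, 2nd/3rd degree polynomial, power with exponent >= 1, hill, and the
EPA exponential family exp2-exp5) by constant-variance Gaussian maximum
likelihood.  The BMC is the concentration at which the modeled mean departs
from the control mean by one benchmark response (default 1 modeled standard
deviation).  Model selection takes the lowest-AIC converged, non-saturated
fit with a defined, finite BMC confidence interval; per-probe results are
filtered (lack-of-fit p, BMCU/BMCL ratio, range, annotation), collapsed to
gene level by the median, and the 25th-ranked gene's BMC is the
transcriptional point of departure (tPOD).

Viability endpoints (viable-cell densities) use the hybrid extra-risk
approach: "abnormal" is defined by a tail probability of the control
distribution and the BMC solves extra risk = level (default 0.5).

Confidence bounds on every BMC come from a seeded parametric bootstrap
(refit on data simulated from the fitted model).  Potency ranking orders
compounds by BMC and calls two compounds equivalent when their confidence
intervals overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "ModelFit",
    "BMCResult",
    "TPODResult",
    "WilliamsResult",
    "MODEL_NAMES",
    "pava",
    "williams_trend",
    "prefilter_probes",
    "fit_all_models",
    "bmc_from_fit",
    "select_best",
    "model_and_bmc",
    "filter_gene_bmcs",
    "collapse_and_tpod",
    "viability_bmc",
    "hybrid_bmc_from_fit",
    "potency_rank",
]

MODEL_NAMES = (
    "linear", "poly2", "poly3", "power", "hill",
    "exp2", "exp3", "exp4", "exp5",
)


# --------------------------------------------------------------------------
# data containers

@dataclass
class DoseResponseSeries:
    """Per-replicate responses over a dose series including a control at 0."""

    doses: np.ndarray
    responses: np.ndarray
    endpoint: str = ""
    units: str = "ug/mL"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be equal-length vectors")
        levels, counts = np.unique(self.doses, return_counts=True)
        if len(levels) < 4 or levels[0] != 0:
            raise ValueError("need >= 4 dose groups including a control at 0")
        if counts.min() < 2:
            raise ValueError("need >= 2 replicates per dose group")

    @property
    def dose_groups(self) -> np.ndarray:
        return np.unique(self.doses)

    @property
    def max_dose(self) -> float:
        return float(self.doses.max())

    def group_stats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(levels, group means, group sizes) sorted by dose."""
        levels = self.dose_groups
        means = np.array([self.responses[self.doses == d].mean() for d in levels])
        counts = np.array([(self.doses == d).sum() for d in levels])
        return levels, means, counts


@dataclass
class ModelFit:
    """A fitted continuous dose-response model.

    ``params`` are the mean-function parameters; ``sigma`` is the ML
    residual SD (constant variance); ``direction`` is the adverse direction
    (+1 increasing / −1 decreasing) used by the sign-carrying exponential
    models.  ``fit_p`` is the lack-of-fit p against the cell-means model
    (NaN when the model saturates the dose groups).
    """

    model: str
    params: np.ndarray
    sigma: float
    doses: np.ndarray
    responses: np.ndarray
    direction: int = 1
    loglik: float = math.nan
    aic: float = math.nan
    fit_p: float = math.nan
    converged: bool = True
    saturated: bool = False

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def sigma_bmr(self) -> float:
        """Degrees-of-freedom-corrected residual SD used for the BMR.

        The ML estimate sqrt(RSS/N) is biased low on small designs; the
        benchmark response uses sqrt(RSS/(N − p)) instead (falls back to the
        ML sigma when the correction is undefined).
        """
        n = len(self.responses)
        p = self.n_params
        if n > p:
            return float(self.sigma * math.sqrt(n / (n - p)))
        return self.sigma

    def mu(self, d: np.ndarray | float) -> np.ndarray | float:
        return _MODEL_FUNCS[self.model](np.asarray(d, dtype=float), self.params,
                                        self.direction)


@dataclass
class BMCResult:
    """A benchmark concentration with bootstrap confidence bounds."""

    bmc: float
    bmcl: float
    bmcu: float
    bmr_spec: dict
    model: ModelFit | None = None
    defined: bool = True
    units: str = "ug/mL"
    label: str = ""

    @property
    def has_finite_interval(self) -> bool:
        return (
            self.defined
            and np.isfinite(self.bmcl)
            and np.isfinite(self.bmcu)
            and self.bmcl > 0
        )


@dataclass
class TPODResult:
    """Gene-level BMC summary and the rank-based transcriptional POD."""

    condition: str
    gene_bmcs: pd.DataFrame
    tpod: float | None
    n_genes_passing: int
    rank: int = 25
    reason: str = ""


class WilliamsResult(NamedTuple):
    p: float
    statistic: float
    direction: int


# --------------------------------------------------------------------------
# Williams' trend test

def pava(values: Sequence[float], weights: Sequence[float],
         increasing: bool = True) -> np.ndarray:
    """Weighted isotonic regression by pool-adjacent-violators."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not increasing:
        return -pava(-y, w, increasing=True)
    # blocks as (level, weight, count)
    levels: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        levels.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(levels) > 1 and levels[-2] > levels[-1]:
            lv = (levels[-2] * wts[-2] + levels[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wt = wts[-2] + wts[-1]
            ct = counts[-2] + counts[-1]
            levels[-2:] = [lv]
            wts[-2:] = [wt]
            counts[-2:] = [ct]
    return np.repeat(levels, counts)


def _williams_statistic(
    responses: np.ndarray,
    group_slices: list[np.ndarray],
    counts: np.ndarray,
) -> tuple[float, int]:
    """Max-t Williams statistic over both directions for one labelling."""
    means = np.array([responses[idx].mean() for idx in group_slices])
    n_total = len(responses)
    rss = sum(((responses[idx] - m) ** 2).sum()
              for idx, m in zip(group_slices, means))
    df = n_total - len(group_slices)
    s2 = rss / df if df > 0 else 0.0
    n0, nk = counts[0], counts[-1]
    se = math.sqrt(s2 * (1.0 / nk + 1.0 / n0)) if s2 > 0 else 0.0
    up = pava(means[1:], counts[1:], increasing=True)[-1] - means[0]
    dn = means[0] - pava(means[1:], counts[1:], increasing=False)[-1]
    if se == 0.0:
        stat = math.inf if max(up, dn) > 0 else 0.0
    else:
        stat = max(up, dn) / se
    direction = 1 if up >= dn else -1
    return stat, direction


def williams_trend(
    series: DoseResponseSeries, n_perm: int = 100, seed: int = 0
) -> WilliamsResult:
    """Permutation Williams' trend test for a monotone dose response.

    The statistic compares the control mean with the isotonic
    (pool-adjacent-violators) amalgamated mean of the top dose group, in
    whichever direction departs more.  The p-value counts label
    permutations with a statistic at least as large, with the add-one
    convention, so p ∈ [1/(n_perm+1), 1].
    """
    levels = series.dose_groups
    if len(levels) < 4:
        raise ValueError("need >= 3 dose groups above the control")
    group_slices = [np.flatnonzero(series.doses == d) for d in levels]
    counts = np.array([len(idx) for idx in group_slices])
    obs, direction = _williams_statistic(series.responses, group_slices, counts)
    rng = np.random.default_rng(seed)
    y = series.responses
    exceed = 0
    for _ in range(n_perm):
        perm_stat, _ = _williams_statistic(rng.permutation(y), group_slices, counts)
        if perm_stat >= obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return WilliamsResult(p=p, statistic=obs, direction=direction)


def prefilter_probes(
    values: pd.DataFrame,
    doses: np.ndarray | Sequence[float],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Williams-trend and fold-change prefilter of a probe matrix.

    ``values`` is probes × samples of log2 ratios; ``doses`` aligns with the
    columns.  A probe is kept when its Williams p < ``p_max`` and its
    maximal absolute fold change over dose groups (relative to the control
    group mean) is >= ``fc_min``.  Returns a frame ``probe, williams_p,
    max_abs_fc, keep``.
    """
    doses = np.asarray(doses, dtype=float)
    levels = np.unique(doses)
    group_slices = [np.flatnonzero(doses == d) for d in levels]
    counts = np.array([len(idx) for idx in group_slices])
    rng = np.random.default_rng(seed)
    n = len(doses)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    rows = []
    for probe, row in values.iterrows():
        y = row.to_numpy(dtype=float)
        obs, _ = _williams_statistic(y, group_slices, counts)
        exceed = sum(
            _williams_statistic(y[perm], group_slices, counts)[0] >= obs
            for perm in perms
        )
        p = (1.0 + exceed) / (1.0 + n_perm)
        means = np.array([y[idx].mean() for idx in group_slices])
        max_abs_fc = float(np.exp2(np.abs(means[1:] - means[0]).max()))
        rows.append(
            {
                "probe": probe,
                "williams_p": p,
                "max_abs_fc": max_abs_fc,
                "keep": (p < p_max) and (max_abs_fc >= fc_min),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model suite

def _mu_linear(d, th, s):
    return th[0] + th[1] * d


def _mu_poly2(d, th, s):
    return th[0] + th[1] * d + th[2] * d**2


def _mu_poly3(d, th, s):
    return th[0] + th[1] * d + th[2] * d**2 + th[3] * d**3


def _mu_power(d, th, s):
    a, b, g = th
    return a + b * np.power(np.maximum(d, 0.0), g)


def _mu_hill(d, th, s):
    a, v, k, n = th
    d = np.maximum(d, 0.0)
    with np.errstate(over="ignore"):
        return a + v * d**n / (k**n + d**n)


def _mu_exp2(d, th, s):
    a, b = th
    with np.errstate(over="ignore"):
        return a * np.exp(s * b * d)


def _mu_exp3(d, th, s):
    a, b, g = th
    with np.errstate(over="ignore"):
        return a * np.exp(s * np.power(b * np.maximum(d, 0.0), g))


def _mu_exp4(d, th, s):
    a, b, c = th
    return a * (c - (c - 1.0) * np.exp(-b * d))


def _mu_exp5(d, th, s):
    a, b, c, g = th
    return a * (c - (c - 1.0) * np.exp(-np.power(b * np.maximum(d, 0.0), g)))


def _safe_log(x):
    return np.log(np.maximum(x, 1e-300))


def _jac_power(d, th, s):
    a, b, g = th
    dp = np.maximum(d, 0.0)
    pg = np.power(dp, g)
    dg = np.where(dp > 0, b * pg * _safe_log(dp), 0.0)
    return np.column_stack([np.ones_like(d), pg, dg])


def _jac_hill(d, th, s):
    a, v, k, n = th
    dp = np.maximum(d, 0.0)
    dn = dp**n
    kn = k**n
    denom = (kn + dn) ** 2
    h = np.where(dp > 0, dn / (kn + dn), 0.0)
    dk = -v * dn * n * k ** (n - 1.0) / denom
    dn_ = np.where(dp > 0, v * dn * kn * (_safe_log(dp) - math.log(k)) / denom, 0.0)
    return np.column_stack([np.ones_like(d), h, dk, dn_])


def _jac_exp2(d, th, s):
    a, b = th
    e = np.exp(s * b * d)
    return np.column_stack([e, a * s * d * e])


def _jac_exp3(d, th, s):
    a, b, g = th
    dp = np.maximum(d, 0.0)
    u = np.power(b * dp, g)
    e = np.exp(s * u)
    db = a * s * e * g * np.power(b * dp, g - 1.0) * dp
    dg = np.where(b * dp > 0, a * s * e * u * _safe_log(b * dp), 0.0)
    return np.column_stack([e, db, dg])


def _jac_exp4(d, th, s):
    a, b, c = th
    e = np.exp(-b * d)
    return np.column_stack([c - (c - 1.0) * e, a * (c - 1.0) * d * e,
                            a * (1.0 - e)])


def _jac_exp5(d, th, s):
    a, b, c, g = th
    dp = np.maximum(d, 0.0)
    u = np.power(b * dp, g)
    e = np.exp(-u)
    db = a * (c - 1.0) * e * g * np.power(b * dp, g - 1.0) * dp
    dg = np.where(b * dp > 0, a * (c - 1.0) * e * u * _safe_log(b * dp), 0.0)
    return np.column_stack([c - (c - 1.0) * e, db, a * (1.0 - e), dg])


_MODEL_JACS: dict[str, Callable] = {
    "power": _jac_power,
    "hill": _jac_hill,
    "exp2": _jac_exp2,
    "exp3": _jac_exp3,
    "exp4": _jac_exp4,
    "exp5": _jac_exp5,
}


_MODEL_FUNCS: dict[str, Callable] = {
    "linear": _mu_linear,
    "poly2": _mu_poly2,
    "poly3": _mu_poly3,
    "power": _mu_power,
    "hill": _mu_hill,
    "exp2": _mu_exp2,
    "exp3": _mu_exp3,
    "exp4": _mu_exp4,
    "exp5": _mu_exp5,
}

_POLY_DEGREE = {"linear": 1, "poly2": 2, "poly3": 3}


def _starts_and_bounds(model: str, d: np.ndarray, y: np.ndarray,
                       direction: int) -> tuple[list[np.ndarray], tuple]:
    """Heuristic multi-start initial points and box bounds per model."""
    maxd = d.max()
    m0 = y[d == 0].mean()
    mtop = y[d == maxd].mean()
    span = mtop - m0
    a0 = m0 if abs(m0) > 1e-8 else (1e-3 if span >= 0 else -1e-3)
    inf = np.inf
    if model == "power":
        starts = [np.array([m0, span / maxd if maxd else 0.0, 1.0]),
                  np.array([m0, span / maxd**2 if maxd else 0.0, 2.0])]
        bounds = ([-inf, -inf, 1.0], [inf, inf, 18.0])
    elif model == "hill":
        starts = [np.array([m0, span, maxd / 4.0, 1.0]),
                  np.array([m0, span, maxd / 2.0, 2.0]),
                  np.array([m0, 2 * span, maxd, 1.0])]
        bounds = ([-inf, -inf, maxd * 1e-3, 0.5], [inf, inf, maxd * 30.0, 18.0])
    elif model == "exp2":
        b0 = abs(math.log(abs(mtop / m0))) / maxd if m0 * mtop > 0 else 1.0 / maxd
        starts = [np.array([a0, b0]), np.array([a0, 0.1 / maxd])]
        bounds = ([-inf, 0.0], [inf, 1e3 / maxd])
    elif model == "exp3":
        b0 = abs(math.log(abs(mtop / m0))) / maxd if m0 * mtop > 0 else 1.0 / maxd
        starts = [np.array([a0, b0, 1.0]), np.array([a0, b0, 2.0])]
        bounds = ([-inf, 0.0, 1.0], [inf, 1e3 / maxd, 18.0])
    elif model == "exp4":
        c0 = mtop / m0 if abs(m0) > 1e-8 else 1.5
        c0 = min(max(c0, 1e-3), 1e3)
        starts = [np.array([a0, 1.0 / maxd, c0]),
                  np.array([a0, 0.2 / maxd, c0])]
        bounds = ([-inf, 1e-8 / maxd, 1e-6], [inf, 1e3 / maxd, 1e6])
    elif model == "exp5":
        c0 = mtop / m0 if abs(m0) > 1e-8 else 1.5
        c0 = min(max(c0, 1e-3), 1e3)
        starts = [np.array([a0, 1.0 / maxd, c0, 1.0]),
                  np.array([a0, 0.5 / maxd, c0, 2.0])]
        bounds = ([-inf, 1e-8 / maxd, 1e-6, 1.0], [inf, 1e3 / maxd, 1e6, 18.0])
    else:  # pragma: no cover - polynomials are closed form
        raise ValueError(model)
    return starts, bounds


def _finalize_fit(model: str, params: np.ndarray, d: np.ndarray, y: np.ndarray,
                  direction: int, converged: bool) -> ModelFit:
    mu = _MODEL_FUNCS[model](d, params, direction)
    rss = float(((y - mu) ** 2).sum())
    n = len(y)
    sigma2 = max(rss / n, 1e-300)
    sigma = math.sqrt(sigma2)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = len(params) + 1  # mean params + sigma
    aic = 2.0 * k - 2.0 * loglik

    levels = np.unique(d)
    sse_pe = sum(((y[d == lv] - y[d == lv].mean()) ** 2).sum() for lv in levels)
    df_pe = n - len(levels)
    df_lof = len(levels) - len(params)
    saturated = df_lof <= 0
    if saturated or df_pe <= 0:
        fit_p = math.nan
    else:
        sse_lof = max(rss - sse_pe, 0.0)
        if sse_pe <= 0:
            fit_p = 1.0 if sse_lof <= 1e-12 else 0.0
        else:
            f = (sse_lof / df_lof) / (sse_pe / df_pe)
            fit_p = float(stats.f.sf(f, df_lof, df_pe))
    return ModelFit(
        model=model, params=np.asarray(params, dtype=float), sigma=sigma,
        doses=d, responses=y, direction=direction, loglik=loglik, aic=aic,
        fit_p=fit_p, converged=converged, saturated=saturated,
    )


def _fit_single(model: str, d: np.ndarray, y: np.ndarray, direction: int,
                seed: int = 0, x0: np.ndarray | None = None,
                n_starts: int = 1, warm_only: bool = False,
                max_nfev: int = 250) -> ModelFit:
    """Fit one model by (closed-form or multi-start) least squares.

    ``warm_only`` with ``x0`` restricts to a single warm start (used by the
    bootstrap, where the simulated data sit near the fitted model).
    """
    if model in _POLY_DEGREE:
        deg = _POLY_DEGREE[model]
        coefs = np.polynomial.polynomial.polyfit(d, y, deg)
        return _finalize_fit(model, coefs, d, y, direction, converged=True)

    starts, bounds = _starts_and_bounds(model, d, y, direction)
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)] + (
            [] if warm_only else starts
        )
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    best = None
    tried = 0
    for base in starts:
        for jitter in range(n_starts):
            x = base if jitter == 0 else base * rng.uniform(0.5, 1.5, size=base.shape)
            x = np.clip(x, np.where(np.isfinite(lo), lo, -1e12),
                        np.where(np.isfinite(hi), hi, 1e12))
            try:
                res = optimize.least_squares(
                    lambda th: _MODEL_FUNCS[model](d, th, direction) - y,
                    x, bounds=bounds, max_nfev=max_nfev, ftol=1e-6, xtol=1e-6,
                    jac=lambda th: _MODEL_JACS[model](d, th, direction),
                )
            except Exception:
                continue
            tried += 1
            cost = float(res.cost)
            if best is None or cost < best[0]:
                best = (cost, res.x, bool(res.success))
    if best is None:
        fit = _finalize_fit(model, starts[0], d, y, direction, converged=False)
        return fit
    return _finalize_fit(model, best[1], d, y, direction, converged=best[2])


def _trend_direction(series: DoseResponseSeries) -> int:
    _, means, counts = series.group_stats()
    up = pava(means[1:], counts[1:], increasing=True)[-1] - means[0]
    dn = means[0] - pava(means[1:], counts[1:], increasing=False)[-1]
    return 1 if up >= dn else -1


def fit_all_models(
    series: DoseResponseSeries,
    seed: int = 0,
    models: Sequence[str] = MODEL_NAMES,
) -> list[ModelFit]:
    """Fit the continuous model suite by constant-variance Gaussian ML.

    Polynomial-family models are solved in closed form; the nonlinear
    families use seeded multi-start bounded least squares (equivalent to ML
    under the constant-variance Gaussian likelihood).  The adverse direction
    for the sign-carrying exponential models is taken from the isotonic
    trend of the group means.
    """
    d, y = series.doses, series.responses
    direction = _trend_direction(series)
    fits = [
        _fit_single(m, d, y, direction, seed=seed + i)
        for i, m in enumerate(models)
    ]
    if not any(f.converged for f in fits):
        raise RuntimeError(f"no model converged for endpoint {series.endpoint!r}")
    return fits


# --------------------------------------------------------------------------
# BMC computation

def _solve_departure(
    mu: Callable[[np.ndarray], np.ndarray],
    target_fn: Callable[[np.ndarray], np.ndarray],
    max_dose: float,
) -> float | None:
    """Smallest d in (0, 100·max_dose] where target_fn crosses zero."""
    lo = max_dose * 1e-9
    hi = max_dose * 100.0
    grid = np.geomspace(lo, hi, 600)
    vals = np.asarray(target_fn(grid), dtype=float)
    if not np.isfinite(vals).all():
        finite = np.isfinite(vals)
        grid, vals = grid[finite], vals[finite]
        if len(grid) == 0:
            return None
    if vals[0] >= 0:
        return float(grid[0])
    idx = np.flatnonzero(vals >= 0)
    if len(idx) == 0:
        return None
    i = idx[0]
    try:
        return float(optimize.brentq(lambda x: float(target_fn(np.array([x]))[0]),
                                     grid[i - 1], grid[i]))
    except ValueError:
        return float(grid[i])


def _point_bmc(fit: ModelFit, bmr_k: float) -> float | None:
    if fit.sigma <= 1e-10:
        return None
    mu0 = float(fit.mu(0.0))
    target = bmr_k * fit.sigma_bmr

    def g(d):
        return np.abs(np.asarray(fit.mu(d), dtype=float) - mu0) - target

    return _solve_departure(fit.mu, g, float(fit.doses.max()))


def _bootstrap_ci(
    fit: ModelFit,
    point_fn: Callable[[ModelFit], float | None],
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile parametric-bootstrap CI for any per-fit point estimate."""
    rng = np.random.default_rng(seed)
    d, mu_hat = fit.doses, np.asarray(fit.mu(fit.doses), dtype=float)
    draws = []
    sigma_sim = fit.sigma_bmr  # df-corrected; the ML sigma is biased low
    for b in range(n_boot):
        y_sim = mu_hat + rng.normal(0.0, sigma_sim, size=len(d))
        refit = _fit_single(fit.model, d, y_sim, fit.direction,
                            seed=seed + b + 1, x0=fit.params, n_starts=1,
                            warm_only=True, max_nfev=60)
        val = point_fn(refit)
        if val is not None and np.isfinite(val):
            draws.append(val)
    if len(draws) < max(20, n_boot // 4):
        return math.nan, math.nan
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


def _widen_to_include(bmc: float, bmcl: float, bmcu: float) -> tuple[float, float]:
    """Keep the interval invariant bmcl <= bmc <= bmcu."""
    if np.isfinite(bmcl):
        bmcl = min(bmcl, bmc)
    if np.isfinite(bmcu):
        bmcu = max(bmcu, bmc)
    return bmcl, bmcu


def bmc_from_fit(
    fit: ModelFit,
    bmr_k: float = 1.0,
    ci: bool = True,
    n_boot: int = 250,
    seed: int = 0,
    units: str = "ug/mL",
    label: str = "",
) -> BMCResult:
    """BMC at which |µ(d) − µ(0)| equals ``bmr_k`` modeled residual SDs.

    Solved by bracketed root-finding on (0, 100 × max dose] (closed-form
    models still go through the same solver; the bracket is exact to brentq
    tolerance).  95% confidence bounds come from a seeded parametric
    bootstrap of ``n_boot`` refits; a flat model or absent crossing yields
    an undefined-BMC result.
    """
    spec = {"type": "sd_multiple", "k": bmr_k}
    bmc = _point_bmc(fit, bmr_k)
    if bmc is None:
        return BMCResult(math.nan, math.nan, math.nan, spec, fit, defined=False,
                         units=units, label=label)
    if ci:
        bmcl, bmcu = _bootstrap_ci(fit, lambda f: _point_bmc(f, bmr_k),
                                   n_boot, seed)
        bmcl, bmcu = _widen_to_include(bmc, bmcl, bmcu)
    else:
        bmcl = bmcu = math.nan
    return BMCResult(bmc, bmcl, bmcu, spec, fit, defined=True, units=units,
                     label=label)


def select_best(
    fits: list[ModelFit],
    bmcs: dict[str, BMCResult] | None = None,
    require_interval: bool = True,
) -> ModelFit | None:
    """Lowest-AIC converged, non-saturated fit with a usable BMC.

    Saturated fits (as many mean parameters as dose groups) are excluded.
    When ``bmcs`` maps model names to BMC results, eligibility additionally
    requires a defined BMC with a finite interval (if ``require_interval``).
    AIC ties break toward the simpler model.
    """
    eligible = [f for f in fits if f.converged and not f.saturated]
    eligible.sort(key=lambda f: (f.aic, f.n_params, f.model))
    for f in eligible:
        if bmcs is not None:
            r = bmcs.get(f.model)
            if r is None or not r.defined:
                continue
            if require_interval and not r.has_finite_interval:
                continue
        return f
    return None


def model_and_bmc(
    series: DoseResponseSeries,
    bmr_k: float = 1.0,
    n_boot: int = 250,
    seed: int = 0,
    models: Sequence[str] = MODEL_NAMES,
    label: str = "",
) -> BMCResult | None:
    """Fit the suite, walk fits in AIC order, return the first usable BMC."""
    fits = fit_all_models(series, seed=seed, models=models)
    eligible = [f for f in fits if f.converged and not f.saturated]
    eligible.sort(key=lambda f: (f.aic, f.n_params, f.model))
    for f in eligible:
        res = bmc_from_fit(f, bmr_k=bmr_k, n_boot=n_boot, seed=seed,
                           units=series.units, label=label or series.endpoint)
        if res.defined and res.has_finite_interval:
            return res
    return None


# --------------------------------------------------------------------------
# gene-level filtering and tPOD

def filter_gene_bmcs(results: pd.DataFrame, max_dose: float) -> pd.DataFrame:
    """Apply the per-probe BMC quality filters.

    Removes probes with lack-of-fit p < 0.1, BMCU/BMCL >= 40 (or an
    undefined interval), best BMC above the highest tested concentration,
    and probes without a gene annotation.  ``results`` needs columns
    ``probe, gene, bmc, bmcl, bmcu, fit_p``.
    """
    df = results.copy()
    ok = np.isfinite(df["bmc"])
    ok &= ~(df["fit_p"] < 0.1)  # NaN lack-of-fit p is not evidence of misfit
    ratio = df["bmcu"] / df["bmcl"]
    ok &= np.isfinite(ratio) & (df["bmcl"] > 0) & (ratio < 40.0)
    ok &= df["bmc"] <= max_dose
    ok &= df["gene"].notna() & (df["gene"].astype(str).str.len() > 0)
    return df[ok].reset_index(drop=True)


def collapse_and_tpod(
    filtered: pd.DataFrame, condition: str = "", rank: int = 25
) -> TPODResult:
    """Collapse probe BMCs to gene medians and take the rank-th gene's BMC.

    Genes are sorted by ascending BMC (ties by BMCL then name); the tPOD is
    the ``rank``-th gene's BMC and is undefined when fewer genes pass.
    """
    if len(filtered) == 0:
        return TPODResult(condition, pd.DataFrame(), None, 0, rank,
                          reason="no probes passed filtering")
    genes = (
        filtered.groupby("gene")
        .agg(bmc=("bmc", "median"), bmcl=("bmcl", "median"),
             bmcu=("bmcu", "median"), n_probes=("probe", "size"))
        .reset_index()
        .sort_values(["bmc", "bmcl", "gene"])
        .reset_index(drop=True)
    )
    n = len(genes)
    if n < rank:
        return TPODResult(condition, genes, None, n, rank,
                          reason=f"only {n} genes passed (need {rank})")
    return TPODResult(condition, genes, float(genes["bmc"].iloc[rank - 1]), n, rank)


# --------------------------------------------------------------------------
# hybrid extra-risk BMC for viability endpoints

def _variance_fn(fit: ModelFit, variance: str) -> Callable[[np.ndarray], np.ndarray]:
    """σ(d) under the constant or power-of-mean variance setting."""
    if variance == "constant":
        s = fit.sigma_bmr
        return lambda d: np.full_like(np.asarray(d, dtype=float), s)
    if variance != "power":
        raise ValueError("variance must be 'constant' or 'power'")
    d, y = fit.doses, fit.responses
    levels = np.unique(d)
    means = np.array([y[d == lv].mean() for lv in levels])
    var = np.array([y[d == lv].var(ddof=1) for lv in levels])
    good = (means > 0) & (var > 0)
    if good.sum() < 2:
        return lambda dd: np.full_like(np.asarray(dd, dtype=float), fit.sigma)
    rho, log_alpha = np.polyfit(np.log(means[good]), np.log(var[good]), 1)
    alpha = math.exp(log_alpha)

    def sig(dd):
        mu = np.maximum(np.asarray(fit.mu(dd), dtype=float), 1e-12)
        return np.sqrt(alpha * mu**rho)

    return sig


def hybrid_bmc_from_fit(
    fit: ModelFit,
    level: float = 0.5,
    tail_p0: float = 0.01,
    variance: str = "constant",
) -> float | None:
    """Hybrid extra-risk BMC from one fitted mean model.

    The abnormal cutoff is the ``tail_p0`` quantile of the control
    distribution (c = µ(0) − z_{1−p0}·σ(0) for a decreasing-adverse
    response).  P(d) is the probability of an abnormal response at dose d
    and the BMC solves extra risk (P(d) − p0)/(1 − p0) = ``level``.
    """
    sig = _variance_fn(fit, variance)
    mu0 = float(fit.mu(0.0))
    s0 = float(sig(np.array([0.0]))[0])
    if s0 <= 0:
        return None
    z0 = stats.norm.ppf(1.0 - tail_p0)
    target_p = tail_p0 + level * (1.0 - tail_p0)
    if fit.direction < 0:
        cutoff = mu0 - z0 * s0

        def g(d):
            p = stats.norm.cdf((cutoff - np.asarray(fit.mu(d), dtype=float))
                               / sig(d))
            return p - target_p
    else:
        cutoff = mu0 + z0 * s0

        def g(d):
            p = stats.norm.cdf((np.asarray(fit.mu(d), dtype=float) - cutoff)
                               / sig(d))
            return p - target_p

    return _solve_departure(fit.mu, g, float(fit.doses.max()))


def viability_bmc(
    series: DoseResponseSeries,
    level: float = 0.5,
    tail_p0: float = 0.01,
    variance: str = "constant",
    seed: int = 0,
    n_boot: int = 250,
    models: Sequence[str] = MODEL_NAMES,
    label: str = "",
) -> BMCResult | None:
    """Hybrid extra-risk BMC of a viable-cell-density dose series.

    Fits the model suite, walks converged non-saturated fits in AIC order
    and returns the first with a defined hybrid BMC and finite bootstrap
    interval; None when the response is flat or nothing is usable.
    """
    fits = fit_all_models(series, seed=seed, models=models)
    eligible = [f for f in fits if f.converged and not f.saturated]
    eligible.sort(key=lambda f: (f.aic, f.n_params, f.model))
    spec = {"type": "hybrid_extra_risk", "level": level, "tail_p0": tail_p0}
    for f in eligible:
        bmc = hybrid_bmc_from_fit(f, level=level, tail_p0=tail_p0,
                                  variance=variance)
        if bmc is None:
            continue
        bmcl, bmcu = _bootstrap_ci(
            f,
            lambda rf: hybrid_bmc_from_fit(rf, level=level, tail_p0=tail_p0,
                                           variance=variance),
            n_boot, seed,
        )
        bmcl, bmcu = _widen_to_include(bmc, bmcl, bmcu)
        res = BMCResult(bmc, bmcl, bmcu, spec, f, defined=True,
                        units=series.units, label=label or series.endpoint)
        if res.has_finite_interval:
            return res
    return None


# --------------------------------------------------------------------------
# potency ranking

@dataclass
class PotencyRanking:
    """BMC-ordered compounds with CI-overlap equivalence relations."""

    table: pd.DataFrame  # label, bmc, bmcl, bmcu sorted by bmc
    chain: str  # e.g. "A ~ B > C"

    def equivalent(self, a: str, b: str) -> bool:
        t = self.table.set_index("label")
        if a == b:
            return True
        lo = max(t.loc[a, "bmcl"], t.loc[b, "bmcl"])
        hi = min(t.loc[a, "bmcu"], t.loc[b, "bmcu"])
        return bool(lo <= hi)


def potency_rank(results: list[BMCResult]) -> PotencyRanking:
    """Order compounds by BMC; overlapping CIs are reported as equivalent.

    Most potent (lowest BMC) first.  The chain joins consecutive compounds
    with ``~`` when their confidence intervals intersect and ``>`` when they
    are disjoint; equivalence is not transitive and is never forced into a
    total order beyond this chain.
    """
    if not results:
        raise ValueError("no BMC results to rank")
    units = {r.units for r in results}
    if len(units) > 1:
        raise ValueError(f"mixed concentration units: {sorted(units)}")
    usable = [r for r in results if r.defined]
    rows = [
        {"label": r.label, "bmc": r.bmc, "bmcl": r.bmcl, "bmcu": r.bmcu}
        for r in sorted(usable, key=lambda r: r.bmc)
    ]
    table = pd.DataFrame(rows, columns=["label", "bmc", "bmcl", "bmcu"])
    parts: list[str] = []
    for i, row in table.iterrows():
        if i == 0:
            parts.append(str(row["label"]))
            continue
        prev = table.iloc[i - 1]
        overlap = max(prev["bmcl"], row["bmcl"]) <= min(prev["bmcu"], row["bmcu"])
        parts.append(("~ " if overlap else "> ") + str(row["label"]))
    return PotencyRanking(table=table, chain=" ".join(parts))
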