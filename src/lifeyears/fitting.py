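"""Nonlinear least-squares fitting of lifetime models to a life table.

Each family is fitted to an empirical series read off the table:

* ``mx`` — the per-interval death probabilities dx/lx.  The model's
  prediction for this series is its own interval probability
  1 - S(x+1)/S(x), so a table generated from the family is recovered
  exactly (up to solver tolerance) rather than with the O(mu) bias that
  comparing an instantaneous hazard against interval data would carry.
* ``death_cdf`` — the death-age distribution 1 - lx/l0, matched by the
  model CDF.  This is the default for the Gompertz (Gumbel) family, whose
  printed f/F ratio decreases with age and cannot track adult mortality,
  while its CDF fits the death distribution directly.

The fitted shape ``l`` (|l| for Gompertz) is the healthy-life-years-lost
estimate.  Optimization is multi-start Levenberg-Marquardt in log-parameter
space, deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from . import hazards as hz
from .errors import ConfigError, FitError
from .life_table import LifeTable

__all__ = [
    "FitConfig", "FitResult",
    "empirical_series", "fit_model", "goodness_of_fit", "hlyl_from_fit",
]

Family = Literal["loglogistic", "weibull", "gompertz"]
Series = Literal["mx", "death_cdf"]

_DEFAULT_SERIES: dict[str, Series] = {
    "loglogistic": "mx",
    "weibull": "mx",
    "gompertz": "death_cdf",
}


@dataclass(frozen=True)
class FitConfig:
    family: Family = "loglogistic"
    series: Series | None = None          # None -> per-family default
    age_min: int = 1                      # monotone laws cannot carry the infant spike
    age_max: int | None = None            # None -> omega - 1 (skip the closure row)
    init: tuple[float, float] | None = None
    tol: float = 1e-10
    max_iter: int = 10_000
    n_starts: int = 8
    seed: int = 0

    def resolved_series(self) -> Series:
        return self.series or _DEFAULT_SERIES[self.family]


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus the goodness-of-fit surface (R^2, SSE, std. error)."""

    family: Family
    params: object
    sse: float
    r2: float
    std_error: float
    n: int
    age_range: tuple[int, int]
    converged: bool
    hlyl: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "hlyl", abs(self.params.l))

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "params": json.loads(self.params.to_json()),
                "hlyl": self.hlyl,
                "r2": self.r2,
                "sse": self.sse,
                "std_error": self.std_error,
                "n": self.n,
                "age_range": list(self.age_range),
                "converged": self.converged,
            }
        )


def empirical_series(
    lt: LifeTable,
    series: Series,
    age_min: int = 0,
    age_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The observed curve a model is fitted to, over [age_min, age_max]."""
    age_max = lt.omega if age_max is None else age_max
    if age_min > age_max:
        raise ConfigError(f"empty age range [{age_min}, {age_max}]")
    sel = slice(age_min, age_max + 1)
    ages = lt.ages[sel]
    if series == "mx":
        values = (lt.dx / lt.lx)[sel]
    elif series == "death_cdf":
        values = 1.0 - lt.lx[sel] / lt.lx[0]
    else:
        raise ConfigError(f"unknown series {series!r}")
    if len(ages) == 0:
        raise ConfigError(f"empty age range [{age_min}, {age_max}]")
    return ages, values


def goodness_of_fit(observed, predicted, p: int) -> tuple[float, float, float]:
    """(R^2, SSE, residual std. error) with std_error = sqrt(SSE/(n-p))."""
    o = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if o.shape != f.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(o)
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    sse = float(np.sum((o - f) ** 2))
    tss = float(np.sum((o - o.mean()) ** 2))
    r2 = math.nan if tss == 0 else 1.0 - sse / tss
    return r2, sse, math.sqrt(sse / (n - p))


# -- internal model plumbing --------------------------------------------------

def _cumhaz(family: Family, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    if family == "loglogistic":
        return hz.loglogistic_cumhaz(x, math.exp(theta[1]), math.exp(theta[0]))
    if family == "weibull":
        return hz.weibull_cumhaz(x, hz.WeibullParams(math.exp(theta[0]), math.exp(theta[1])))
    return hz.gompertz_cumhaz(x, hz.GompertzParams(math.exp(theta[0]), theta[1]))


def _predict(family: Family, theta: np.ndarray, series: Series, ages: np.ndarray) -> np.ndarray:
    if series == "mx":
        # interval death probability 1 - S(x+1)/S(x)
        return -np.expm1(_cumhaz(family, theta, ages) - _cumhaz(family, theta, ages + 1.0))
    if family == "gompertz":
        return hz.gompertz_cdf(ages, hz.GompertzParams(math.exp(theta[0]), theta[1]))
    return 1.0 - np.exp(-_cumhaz(family, theta, ages))


def _params_from_theta(family: Family, theta: np.ndarray):
    if family == "loglogistic":
        return hz.LogLogisticParams(lam=math.exp(theta[0]), l=math.exp(theta[1]))
    if family == "weibull":
        return hz.WeibullParams(b=math.exp(theta[0]), l=math.exp(theta[1]))
    return hz.GompertzParams(b=math.exp(theta[0]), l=theta[1])


def _base_start(family: Family, lt: LifeTable) -> np.ndarray:
    """Anchor the scale at the modal death age; shape starts at 7."""
    adult = lt.dx[1:]
    mode = float(1 + int(np.argmax(adult))) if len(adult) else 1.0
    mode = max(mode, 2.0)
    if family == "loglogistic":
        return np.array([-7.0 * math.log(mode), math.log(7.0)])
    if family == "weibull":
        return np.array([-math.log(mode), math.log(7.0)])
    return np.array([math.log(0.1), -0.1 * mode])


def _jittered_starts(family: Family, base: np.ndarray, cfg: FitConfig) -> list[np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    starts = [base]
    for _ in range(max(cfg.n_starts - 1, 0)):
        u = rng.uniform(0.5, 1.5, size=2)
        if family == "gompertz":
            starts.append(np.array([base[0] + math.log(u[0]), base[1] * u[1]]))
        else:
            # multiplicative jitter on the natural (lam/b, l) parameters
            starts.append(base + np.log(u))
    return starts


def fit_model(lt: LifeTable, cfg: FitConfig) -> FitResult:
    """Least-squares fit of ``cfg.family`` to the configured series.

    Runs ``n_starts`` jittered starts (seeded, hence deterministic) and
    keeps the best sum of squared residuals.  A degenerate series (all
    values equal) cannot identify a lifetime law and raises FitError.
    """
    series = cfg.resolved_series()
    age_max = cfg.age_max if cfg.age_max is not None else lt.omega - 1
    if cfg.age_min >= age_max:
        raise ConfigError(f"age_min={cfg.age_min} must be < age_max={age_max}")
    ages, observed = empirical_series(lt, series, cfg.age_min, age_max)
    if np.ptp(observed) == 0:
        raise FitError(f"degenerate {series} series: all values equal")

    if cfg.init is not None:
        a, b = cfg.init
        base = (np.array([math.log(a), b]) if cfg.family == "gompertz"
                else np.array([math.log(a), math.log(b)]))
    else:
        base = _base_start(cfg.family, lt)

    def residuals(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = _predict(cfg.family, theta, series, ages)
        return np.nan_to_num(pred - observed, nan=1e6, posinf=1e6, neginf=-1e6)

    best = None
    any_ok = False
    for start in _jittered_starts(cfg.family, base, cfg):
        try:
            sol = least_squares(
                residuals, start, method="lm",
                xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol,
                max_nfev=cfg.max_iter,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        any_ok = any_ok or sol.success
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise FitError(f"all {cfg.n_starts} starts failed for family {cfg.family}")

    _, sol = best
    params = _params_from_theta(cfg.family, sol.x)
    predicted = _predict(cfg.family, sol.x, series, ages)
    r2, sse, std_error = goodness_of_fit(observed, predicted, p=2)
    return FitResult(
        family=cfg.family,
        params=params,
        sse=sse,
        r2=r2,
        std_error=std_error,
        n=len(ages),
        age_range=(int(ages[0]), int(ages[-1])),
        converged=bool(any_ok and sol.success),
    )


def hlyl_from_fit(fr: FitResult) -> float:
    """The HLYL read off a fit: the shape l (|l| for the Gompertz offset)."""
    if not fr.converged:
        raise FitError("cannot extract HLYL from a non-converged fit")
    return fr.hlyl
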