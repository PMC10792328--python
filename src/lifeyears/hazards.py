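"""Closed-form lifetime laws used for mortality fitting.

Three two-parameter families, each written so that the shape/location
parameter ``l`` carries the healthy-life-years-lost (HLYL) interpretation
when the model is fitted to a life table:

* **log-logistic** — scale ``lam`` and shape ``l``; survival
  S(x) = 1/(1 + lam x^l).  With lam = 1 its hazard is the generating
  function of the mortality-space estimator, and the cumulative hazard has
  the closed form ln(1 + x^l).
* **Weibull** — rate ``b`` and shape ``l``; S(x) = exp(-(bx)^l).
* **Gompertz** (Gumbel death-age form) — rate ``b`` and offset ``l``;
  the deaths density is an extreme-value density with location -l/b and
  scale 1/b, so F(x) = exp(-exp(-(l + bx))).  The printed ratio f/F is a
  *reversed* hazard and is exposed as :func:`gompertz_ratio`, never as a
  hazard.

All expressions are evaluated in log space (``log1p``/``expm1``/
``logaddexp``): for human age grids x^l reaches ~1e24 and the naive forms
overflow.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "LogLogisticParams", "WeibullParams", "GompertzParams",
    "loglogistic_pdf", "loglogistic_survival", "loglogistic_hazard",
    "loglogistic_cumhaz", "loglogistic_bx",
    "weibull_pdf", "weibull_survival", "weibull_hazard", "weibull_cumhaz",
    "gompertz_pdf", "gompertz_cdf", "gompertz_survival", "gompertz_ratio",
    "gompertz_cumhaz",
]


def _check_nonneg(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("ages must be non-negative")
    return x


@dataclass(frozen=True)
class LogLogisticParams:
    lam: float  # scale, dimension x^-l
    l: float    # shape; the HLYL carrier (years)

    def __post_init__(self):
        if self.lam <= 0 or self.l <= 0:
            raise ValueError("log-logistic requires lam > 0 and l > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "LogLogisticParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class WeibullParams:
    b: float  # rate (per year)
    l: float  # shape; the HLYL carrier (years)

    def __post_init__(self):
        if self.b <= 0 or self.l <= 0:
            raise ValueError("Weibull requires b > 0 and l > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "WeibullParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class GompertzParams:
    b: float  # rate (per year)
    l: float  # location-scale offset; |l| is the HLYL when fitted

    def __post_init__(self):
        if self.b <= 0 or not np.isfinite(self.l):
            raise ValueError("Gompertz requires b > 0 and finite l")

    # Carriere mu_x = B c^x aliases
    @property
    def B(self) -> float:
        return self.b * np.exp(-self.l)

    @property
    def c(self) -> float:
        return float(np.exp(-self.b))

    @property
    def modal_age(self) -> float:
        """Mode of the death distribution, -l/b."""
        return -self.l / self.b

    def to_json(self) -> str:
        return json.dumps({"b": self.b, "l": self.l})

    @classmethod
    def from_json(cls, s: str) -> "GompertzParams":
        return cls(**json.loads(s))


# -- log-logistic ------------------------------------------------------------

def _ll_log_core(x, lam, l):
    """log(lam) + l*log(x) and log(1 + lam x^l), elementwise, -inf safe."""
    with np.errstate(divide="ignore"):
        t = np.log(lam) + l * np.log(x)
    return t, np.logaddexp(0.0, t)


def loglogistic_survival(x, p: LogLogisticParams):
    """S(x) = 1 / (1 + lam x^l)."""
    x = _check_nonneg(x)
    _, log1p_lxl = _ll_log_core(x, p.lam, p.l)
    return np.exp(-log1p_lxl)


def loglogistic_hazard(x, p: LogLogisticParams):
    """h(x) = lam l x^(l-1) / (1 + lam x^l); infinite at x=0 when l < 1."""
    x = _check_nonneg(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, log1p_lxl = _ll_log_core(x, p.lam, p.l)
        logx = np.log(x)
        out = np.exp(np.log(p.l) + t - logx - log1p_lxl)
    if p.l < 1:
        out = np.where(x == 0, np.inf, out)
    elif p.l == 1:
        out = np.where(x == 0, p.lam, out)
    else:
        out = np.where(x == 0, 0.0, out)
    return out


def loglogistic_pdf(x, p: LogLogisticParams):
    """f(x) = lam l x^(l-1) / (1 + lam x^l)^2 = h(x) S(x)."""
    return loglogistic_hazard(x, p) * loglogistic_survival(x, p)


def loglogistic_cumhaz(x, l: float, lam: float = 1.0):
    """Cumulative hazard ln(1 + lam x^l), stable for x^l up to ~1e300."""
    x = _check_nonneg(x)
    if l <= 0 or lam <= 0:
        raise ValueError("requires l > 0 and lam > 0")
    with np.errstate(divide="ignore"):
        t = np.log(lam) + l * np.log(x)
    return np.logaddexp(0.0, t)  # = log(1 + lam x^l)


def loglogistic_bx(x, l: float):
    """Mortality-space ratio for the unit-scale log-logistic law:
    b(x) = l x^l / ((1 + x^l) ln(1 + x^l)); b(x) -> l as x -> 0+."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("requires x > 0")
    t = l * np.log(x)
    log1p_xl = np.logaddexp(0.0, t)
    return l * np.exp(t - log1p_xl) / log1p_xl


# -- Weibull -----------------------------------------------------------------

def weibull_cumhaz(x, p: WeibullParams):
    """Cumulative hazard (b x)^l."""
    x = _check_nonneg(x)
    with np.errstate(divide="ignore"):
        return np.exp(p.l * (np.log(p.b) + np.log(x)))


def weibull_survival(x, p: WeibullParams):
    """S(x) = exp(-(bx)^l)."""
    return np.exp(-weibull_cumhaz(x, p))


def weibull_hazard(x, p: WeibullParams):
    """h(x) = b l (bx)^(l-1); constant at b when l = 1."""
    x = _check_nonneg(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(np.log(p.b) + np.log(p.l) + (p.l - 1.0) * (np.log(p.b) + np.log(x)))
    if p.l < 1:
        out = np.where(x == 0, np.inf, out)
    elif p.l == 1:
        out = np.where(x == 0, p.b, out)
    else:
        out = np.where(x == 0, 0.0, out)
    return out


def weibull_pdf(x, p: WeibullParams):
    """f(x) = h(x) S(x)."""
    return weibull_hazard(x, p) * weibull_survival(x, p)


# -- Gompertz (Gumbel death-age form) ----------------------------------------

def gompertz_cdf(x, p: GompertzParams):
    """F(x) = exp(-exp(-(l + b x))); defined on the whole real line."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-np.exp(-(p.l + p.b * x)))


def gompertz_survival(x, p: GompertzParams):
    """S(x) = 1 - F(x), computed via expm1 for accuracy near F ~ 1."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return -np.expm1(-np.exp(-(p.l + p.b * x)))


def gompertz_pdf(x, p: GompertzParams):
    """f(x) = b exp(-(l + bx)) exp(-exp(-(l + bx)))."""
    x = np.asarray(x, dtype=float)
    z = -(p.l + p.b * x)
    with np.errstate(over="ignore"):
        return p.b * np.exp(z - np.exp(z))


def gompertz_ratio(x, p: GompertzParams):
    """The printed ratio f(x)/F(x) = b exp(-(l + bx)).

    This is the *reversed* hazard of the Gumbel form, not the force of
    mortality; it decreases with age.  Named to prevent silent misuse.
    """
    x = np.asarray(x, dtype=float)
    return p.b * np.exp(-(p.l + p.b * x))


def gompertz_cumhaz(x, p: GompertzParams):
    """-ln S(x) for the Gumbel death-age form (hazard f/S integrated)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log(gompertz_survival(x, p))
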