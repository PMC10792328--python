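"""Model-free "mortality space" estimator of healthy life years lost.

The life table is extended with four columns: cumulative mortality
Mx = sum_{0}^{x} m_a (inclusive of both endpoints), the average mortality
Mx/x, the person life years lost PLYL = x dx / Mx, and the ratio

    b_x = x m_x / Mx            (total space over mortality space)

with m_x = dx/lx.  b_x rises with age to a peak and then declines; the peak
is the scalar direct HLYL estimate.  The identity x m_x = b_x Mx holds at
every age by construction, and b_x is invariant both to rescaling all rates
by a positive constant and to the choice of radix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .errors import ConfigError
from .life_table import LifeTable

__all__ = ["DirectColumns", "DirectHLYL", "direct_columns", "direct_hlyl", "sms_areas"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectColumns:
    """The four appended columns of the direct method."""

    x: np.ndarray        # age (years)
    Mx: np.ndarray       # cumulative mortality, dimensionless
    avg_Mx: np.ndarray   # Mx / x, NaN at x = 0
    plyl: np.ndarray     # person life years lost, x dx / Mx
    bx: np.ndarray       # HLYL estimator at age x (years)


class DirectHLYL(NamedTuple):
    hlyl: float  # years
    age: int     # age at which the bx curve is summarized


def direct_columns(lt: LifeTable) -> DirectColumns:
    """Append the mortality-space columns to a life table.

    b_0 = 0 (the age factor annihilates the numerator) and the average
    mortality is undefined (NaN) at age 0.  If mortality is identically zero
    up to some age, b_x there is set to 0 with a logged warning.
    """
    x = lt.ages
    mx = np.where(lt.lx > 0, lt.dx / lt.lx, 0.0)
    Mx = np.cumsum(mx)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_Mx = np.where(x > 0, Mx / x, np.nan)
        bx = np.where(Mx > 0, x * mx / np.where(Mx > 0, Mx, 1.0), 0.0)
        plyl = np.where(Mx > 0, x * lt.dx / np.where(Mx > 0, Mx, 1.0), 0.0)
    if np.any((Mx == 0) & (x > 0)):
        logger.warning("zero cumulative mortality prefix: bx set to 0 there")
    return DirectColumns(x=x, Mx=Mx, avg_Mx=avg_Mx, plyl=plyl, bx=bx)


def direct_hlyl(
    lt: LifeTable,
    summary: Literal["max", "at-age"] = "max",
    age: int | None = None,
) -> DirectHLYL:
    """Reduce the b_x curve to the scalar direct HLYL.

    ``summary="max"`` (default) takes the peak of the curve, the smallest
    age winning ties; ``summary="at-age"`` reads the curve at a fixed age.

    On a closed cohort the terminal row has dx/lx = 1 by construction
    (everyone left dies there), so its bx value reflects the closure, not
    mortality; the peak search therefore stops at omega - 1 on closed
    tables with more than one age.
    """
    cols = direct_columns(lt)
    if summary == "max":
        bx = cols.bx[:-1] if (lt.closed and len(cols.bx) > 1) else cols.bx
        i = int(np.argmax(bx))  # argmax returns the first maximum
        return DirectHLYL(hlyl=float(cols.bx[i]), age=int(cols.x[i]))
    if summary == "at-age":
        if age is None or not (0 <= age <= lt.omega):
            raise ConfigError(f"summary='at-age' needs an age in 0..{lt.omega}")
        return DirectHLYL(hlyl=float(cols.bx[age]), age=int(age))
    raise ConfigError(f"unknown summary {summary!r}")


def sms_areas(lt: LifeTable) -> tuple[float, float]:
    """Survival and mortality areas of the survival-mortality-space diagram.

    The survival area is the trapezoidal area under lx/l0 over the closed
    age span (the cohort is extinguished at omega + 1); the mortality area
    is the complement of the (omega + 1) x 1 rectangle.
    """
    s = np.append(lt.lx / lt.lx[0], 0.0)
    survival = float(np.trapezoid(s, dx=1.0))
    total = float(len(lt.ages))  # (omega + 1) x 1 rectangle
    return survival, total - survival
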