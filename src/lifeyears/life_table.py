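"""Complete (single-year-of-age) life-table data model and I/O.

A :class:`LifeTable` holds the cohort columns of a complete life table on a
contiguous integer age grid 0..omega: survivors ``lx`` (persons, starting at
the radix l0), deaths ``dx``, the age-specific mortality rate ``mx`` and the
remaining life expectancy ``ex``.  The table is *closed*: the cohort is
extinguished at the terminal age, so ``dx = lx - l(x+1)`` for x < omega,
``d_omega = l_omega`` and the deaths sum exactly to the radix.

Two conventions matter downstream and are enforced here:

* ``mx`` is defined as ``dx / lx`` (the per-interval death probability given
  survival to exact age x), because that is the quantity the mortality-space
  estimator divides and sums.  Input files carrying a central rate are
  accepted, but after construction ``mx`` always equals ``dx/lx``.
* Trailing ages with ``lx = 0`` are truncated; omega is the last age with a
  positive number of survivors, so ``mx`` and ratios built from it are
  defined everywhere on the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError, ValidityError

__all__ = [
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "complete_life_table",
]

DEFAULT_RADIX = 100_000.0

# accepted header spellings, lowercased
_COLUMN_ALIASES = {
    "age": "age", "x": "age",
    "mx": "mx", "qx": "qx", "lx": "lx", "dx": "dx", "ex": "ex",
}


@dataclass(frozen=True)
class LifeTable:
    """A validated complete life table on ages 0..omega.

    ``closed`` marks a closed cohort (d_omega = l_omega, deaths summing to
    the radix).  An *open* table ends with survivors beyond omega — some
    toy and period inputs are of this kind — and only requires
    0 <= d_omega <= l_omega.
    """

    ages: np.ndarray
    mx: np.ndarray
    dx: np.ndarray
    lx: np.ndarray
    ex: np.ndarray
    radix: float = DEFAULT_RADIX
    meta: dict = field(default_factory=dict)
    closed: bool = True

    def __post_init__(self) -> None:
        for name in ("ages", "mx", "dx", "lx", "ex"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def omega(self) -> int:
        """Terminal age (last age with survivors)."""
        return int(self.ages[-1])

    @property
    def e0(self) -> float:
        """Life expectancy at birth."""
        return float(self.ex[0])

    def __len__(self) -> int:
        return len(self.ages)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ages)
        if n == 0:
            raise ValidityError("empty life table")
        for name in ("mx", "dx", "lx", "ex"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"column {name!r} length != age grid length")
        if not np.array_equal(self.ages, np.arange(n)):
            raise StructureError("ages must be consecutive integers starting at 0")
        if np.any(self.lx < 0) or np.any(self.dx < -1e-9):
            raise ValidityError("negative survivor or death counts")
        if np.any(np.diff(self.lx) > 1e-9):
            raise ValidityError("lx must be non-increasing")
        if self.lx[-1] <= 0:
            raise ValidityError("terminal lx must be positive (zero tail is truncated)")
        if abs(self.lx[0] - self.radix) > 1e-6 * max(self.radix, 1.0):
            raise ValidityError(f"l0={self.lx[0]} does not match radix={self.radix}")
        tol = 1e-6 * max(self.radix, 1.0)
        if n > 1 and np.max(np.abs(self.dx[:-1] - (self.lx[:-1] - self.lx[1:]))) > tol:
            raise ValidityError("dx must equal lx - l(x+1) below the terminal age")
        if self.closed:
            if abs(self.dx[-1] - self.lx[-1]) > tol:
                raise ValidityError("closed cohort requires d_omega = l_omega")
        elif not (-tol <= self.dx[-1] <= self.lx[-1] + tol):
            raise ValidityError("terminal deaths must lie in [0, l_omega]")
        if np.any(self.ex < 0):
            raise ValidityError("ex must be non-negative")

    # -- conversion ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages.astype(int),
                "mx": self.mx,
                "lx": self.lx,
                "dx": self.dx,
                "ex": self.ex,
            }
        )

    @classmethod
    def from_columns(
        cls,
        age,
        *,
        mx=None,
        qx=None,
        lx=None,
        dx=None,
        ex=None,
        radix: float | None = None,
        meta: dict | None = None,
        close: bool = True,
    ) -> "LifeTable":
        """Build a table from whichever columns are available.

        Survivorship is reconstructed where missing: from cumulative deaths,
        from interval probabilities ``qx`` (``l(x+1) = lx (1-qx)``), or from a
        rate column ``mx`` treated as a hazard (``l(x+1) = lx exp(-mx)``).
        After reconstruction ``mx`` is always recomputed as ``dx/lx``.

        ``close=True`` (default) closes the cohort at the terminal age
        (d_omega = l_omega).  With ``close=False`` the terminal deaths come
        from the supplied dx or rate column instead, leaving survivors past
        omega; a supplied dx column always takes precedence at the terminal
        age, so open tables round-trip through files.
        """
        age = np.asarray(age, dtype=float)
        order = np.argsort(age)
        age = age[order]

        def _take(col):
            return None if col is None else np.asarray(col, dtype=float)[order]

        mx, qx, lx, dx, ex = map(_take, (mx, qx, lx, dx, ex))
        n = len(age)
        if not np.array_equal(age, np.arange(n)):
            raise StructureError("ages must be consecutive integers starting at 0")

        probs = None  # interval death probabilities, when lx is rate-derived
        if lx is None:
            if dx is not None:
                if np.any(dx < 0):
                    raise ValidityError("negative death counts")
                total = dx.sum()
                lx = total - np.concatenate(([0.0], np.cumsum(dx)[:-1]))
            elif qx is not None or mx is not None:
                r = DEFAULT_RADIX if radix is None else float(radix)
                surv = 1.0 - qx if qx is not None else np.exp(-mx)
                if np.any(surv < -1e-12) or np.any(surv > 1 + 1e-12):
                    raise ValidityError("death probabilities must lie in [0, 1]")
                lx = r * np.concatenate(([1.0], np.cumprod(np.clip(surv, 0.0, 1.0))[:-1]))
                # keep the supplied probabilities (1 - (1 - q) loses bits at tiny q)
                probs = np.clip(qx, 0.0, 1.0) if qx is not None else -np.expm1(-mx)
            else:
                raise FormatError("need at least one of lx, dx, qx, mx to build a life table")
        if np.any(lx < 0):
            raise ValidityError("negative survivor counts")
        if np.any(np.diff(lx) > 1e-9 * max(lx[0], 1.0)):
            raise ValidityError("lx must be non-increasing")

        # truncate the extinct tail: omega is the last age with survivors
        alive = np.nonzero(lx > 0)[0]
        if len(alive) == 0:
            raise ValidityError("all-zero survivorship")
        last = alive[-1]
        extinct = last + 1 < n or lx[-1] == 0  # cohort actually dies out in range
        keep = slice(0, last + 1)
        age, lx = age[keep], lx[keep]
        ex = None if ex is None else ex[keep]

        if dx is not None:
            # a supplied deaths column is kept verbatim (derived differences
            # would lose precision through file round-trips)
            out = dx[keep].copy()
            if not 0.0 <= out[-1] <= lx[-1] + 1e-9 * max(lx[0], 1.0):
                raise ValidityError("terminal deaths must lie in [0, l_omega]")
        elif probs is not None:
            # rate-derived survivorship: dx = lx qx directly, avoiding the
            # catastrophic cancellation of survivor differences at tiny qx
            out = lx * probs[keep]
            if close or extinct:
                out[-1] = lx[-1]
        else:
            out = lx - np.append(lx[1:], 0.0)  # deaths from lx differences
            if not (close or extinct):
                out[-1] = 0.0  # open table with no terminal death information
        # the cohort is closed iff the terminal deaths exhaust the survivors
        closed = (lx[-1] - out[-1]) <= 1e-9 * max(lx[-1], 1e-300)
        dx = out
        mx = np.where(lx > 0, dx / lx, 0.0)
        if ex is None:
            ex = _expectancy(lx)
        return cls(
            ages=age, mx=mx, dx=dx, lx=lx, ex=ex,
            radix=float(lx[0]) if radix is None else float(radix),
            meta=dict(meta or {}), closed=closed,
        )


def _expectancy(lx: np.ndarray, a_last: float = 0.5) -> np.ndarray:
    """Remaining life expectancy from survivorship, a_x = 1/2 everywhere.

    Person-years lived: L_x = (l_x + l_{x+1})/2 for x < omega and
    L_omega = a_last * l_omega for the (closed) terminal interval.
    """
    l_next = np.append(lx[1:], 0.0)
    Lx = (lx + l_next) / 2.0
    Lx[-1] = a_last * lx[-1]
    Tx = np.cumsum(Lx[::-1])[::-1]
    return np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)


def complete_life_table(lt: LifeTable) -> LifeTable:
    """Recompute the derived columns (mx, ex) from lx/dx.

    ``ex`` is filled via ``Tx/lx`` with trapezoidal person-years and a
    terminal a_omega = 1/2; the operation is idempotent.
    """
    if np.all(lt.lx <= 0):
        raise ValidityError("all-zero survivorship")
    mx = np.where(lt.lx > 0, lt.dx / lt.lx, 0.0)
    return replace(lt, mx=mx, ex=_expectancy(lt.lx))


# -- I/O ---------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_life_table(path, dialect: Literal["csv", "hmd_like"] = "csv") -> LifeTable:
    """Read a delimited life table (comma/tab ``csv`` or whitespace ``hmd_like``).

    The header must contain ``age`` plus at least one of lx, dx, qx, mx;
    missing columns are derived and the result validated.  A JSON metadata
    sidecar (``<stem>.meta.json``) is picked up when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "csv":
        df = pd.read_csv(path, sep=None, engine="python")
    elif dialect == "hmd_like":
        df = pd.read_csv(path, sep=r"\s+", comment="#", skip_blank_lines=True)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    cols: dict[str, np.ndarray] = {}
    for raw in df.columns:
        key = _COLUMN_ALIASES.get(str(raw).strip().lower())
        if key is not None:
            series = df[raw]
            if key == "age":
                # HMD prints the open age as e.g. "110+"
                series = series.astype(str).str.rstrip("+").astype(float)
            cols[key] = np.asarray(series, dtype=float)
    if "age" not in cols:
        raise FormatError(f"{path.name}: no 'age' column in header {list(df.columns)}")
    if not ({"mx", "qx", "lx", "dx"} & cols.keys()):
        raise FormatError(f"{path.name}: need at least one of mx, qx, lx, dx")

    meta: dict = {}
    radix = None
    side = _meta_path(path)
    if side.exists():
        payload = json.loads(side.read_text())
        meta = payload.get("meta", payload)
        radix = payload.get("radix")
    age = cols.pop("age")
    # a supplied dx column carries the terminal interval, so open tables
    # round-trip; rate-only files are closed at omega by convention
    return LifeTable.from_columns(age, radix=radix, meta=meta,
                                  close="dx" not in cols, **cols)


def write_life_table(lt: LifeTable, path) -> Path:
    """Write the table as CSV at full precision, with a JSON metadata sidecar."""
    path = Path(path)
    lt.to_frame().to_csv(path, index=False, float_format="%.17g")
    _meta_path(path).write_text(
        json.dumps({"radix": lt.radix, "meta": lt.meta}, indent=2) + "\n"
    )
    return path
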