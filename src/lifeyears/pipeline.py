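"""Batch estimation of HLYL/HLE across life tables and reference comparison.

One :class:`EstimateRecord` per (life table, method): life expectancy at
birth from the table, the method's healthy-life-years-lost estimate, and
HLE = LE - HLYL.  The WHO HALE values are reference-only anchors — the
package never recomputes them (they come from Sullivan-type morbidity data
this pipeline does not use).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .direct import direct_hlyl
from .errors import LifeYearsError
from .fitting import FitConfig, fit_model, hlyl_from_fit
from .life_table import LifeTable

__all__ = [
    "EstimateRecord",
    "compute_hle",
    "run_estimation",
    "records_to_frame",
    "compare_with_reference",
    "check_reference_consistency",
]

logger = logging.getLogger(__name__)

MODEL_METHODS = ("loglogistic", "weibull", "gompertz")
ALL_METHODS = ("direct",) + MODEL_METHODS


@dataclass(frozen=True)
class EstimateRecord:
    """One row of the results grid (year x sex x method)."""

    year: int | None
    sex: str | None
    method: str
    le: float
    hlyl: float
    hle: float


def compute_hle(le: float, hlyl: float) -> float:
    """HLE = LE - HLYL.  A negative result is allowed but flagged."""
    if le < 0 or hlyl < 0:
        raise ValueError("le and hlyl must be non-negative")
    hle = le - hlyl
    if hle < 0:
        logger.warning("negative HLE (%.3f): hlyl exceeds le", hle)
    return hle


def run_estimation(
    tables: Iterable[LifeTable],
    methods: Sequence[str] = ALL_METHODS,
    cfg: FitConfig | None = None,
) -> list[EstimateRecord]:
    """Estimate HLYL/HLE for every table x method.

    A failed fit produces a record with NaN estimates and a logged warning
    rather than aborting the batch.  ``cfg`` carries the solver settings;
    its family/series are overridden per method.
    """
    cfg = cfg or FitConfig()
    records: list[EstimateRecord] = []
    for lt in tables:
        year = lt.meta.get("year")
        sex = lt.meta.get("sex")
        le = lt.e0
        for method in methods:
            try:
                if method == "direct":
                    hlyl = direct_hlyl(lt).hlyl
                elif method in MODEL_METHODS:
                    fr = fit_model(lt, FitConfig(
                        family=method, age_min=cfg.age_min, age_max=cfg.age_max,
                        tol=cfg.tol, max_iter=cfg.max_iter,
                        n_starts=cfg.n_starts, seed=cfg.seed,
                    ))
                    hlyl = hlyl_from_fit(fr)
                else:
                    raise LifeYearsError(f"unknown method {method!r}")
            except LifeYearsError as exc:
                logger.warning("method %s failed for (year=%s, sex=%s): %s",
                               method, year, sex, exc)
                records.append(EstimateRecord(year, sex, method, le, math.nan, math.nan))
                continue
            records.append(EstimateRecord(year, sex, method, le, hlyl,
                                          compute_hle(le, hlyl)))
    return records


def records_to_frame(records: Iterable[EstimateRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def compare_with_reference(records, ref: pd.DataFrame) -> pd.DataFrame:
    """Absolute differences of each method's HLYL/HLE from the WHO anchors.

    ``records`` may be a list of EstimateRecord or an equivalent DataFrame.
    Returns a long-format frame (year, sex, method, hlyl, hle, who_hlyl,
    who_hle, abs_diff_hlyl, abs_diff_hle, closest) where ``closest`` flags
    the method minimizing |HLYL - WHO HLYL| within each (year, sex).
    (year, sex) keys with no WHO row are skipped with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        return pd.DataFrame(columns=[
            "year", "sex", "method", "hlyl", "hle", "who_hlyl", "who_hle",
            "abs_diff_hlyl", "abs_diff_hle", "closest"])
    who = (ref[ref["method"] == "who"]
           .set_index(["year", "sex"])[["hlyl", "hle"]]
           .rename(columns={"hlyl": "who_hlyl", "hle": "who_hle"}))
    out = []
    for (year, sex), grp in df[df["method"] != "who"].groupby(["year", "sex"], dropna=False):
        try:
            anchor = who.loc[(year, sex)]
        except KeyError:
            logger.warning("no WHO reference for (year=%s, sex=%s); skipped", year, sex)
            continue
        g = grp.copy()
        g["who_hlyl"] = anchor["who_hlyl"]
        g["who_hle"] = anchor["who_hle"]
        g["abs_diff_hlyl"] = (g["hlyl"] - anchor["who_hlyl"]).abs()
        g["abs_diff_hle"] = (g["hle"] - anchor["who_hle"]).abs()
        g["closest"] = g["abs_diff_hlyl"] == g["abs_diff_hlyl"].min()
        out.append(g)
    if not out:
        return pd.DataFrame(columns=list(df.columns) + [
            "who_hlyl", "who_hle", "abs_diff_hlyl", "abs_diff_hle", "closest"])
    return pd.concat(out, ignore_index=True)[
        ["year", "sex", "method", "hlyl", "hle", "who_hlyl", "who_hle",
         "abs_diff_hlyl", "abs_diff_hle", "closest"]]


def check_reference_consistency(ref: pd.DataFrame, tol: float = 0.002) -> pd.DataFrame:
    """Verify hle = le - hlyl for every non-WHO reference cell.

    Returns a report frame with a ``deviation`` column and an ``ok`` flag
    per cell; WHO rows are excluded (WHO HLE rests on WHO's own LE).
    """
    cells = ref[ref["method"] != "who"].copy()
    cells["deviation"] = (cells["hle"] - (cells["le"] - cells["hlyl"])).abs()
    cells["ok"] = cells["deviation"] <= tol + 1e-12
    nbad = int((~cells["ok"]).sum())
    if nbad:
        logger.warning("%d reference cells violate hle = le - hlyl beyond %.3f", nbad, tol)
    return cells[["year", "sex", "method", "le", "hlyl", "hle", "deviation", "ok"]]
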