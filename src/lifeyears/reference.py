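"""Packaged reference estimates: India 2000-2019, four methods plus WHO.

The fixture is a long-format table with one row per (year, sex, method):
life expectancy at birth ``le``, healthy life years lost ``hlyl`` and
healthy life expectancy ``hle`` for the direct, log-logistic, Gompertz and
Weibull estimators, plus the WHO HALE anchors (``method == "who"``, for
which ``le`` is not published alongside and ``hlyl`` exists only in the
years WHO reported it).  For every non-WHO cell the identity
hle = le - hlyl holds to the printed 3-decimal rounding.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference", "BUILTIN_REFERENCES"]

BUILTIN_REFERENCES = ("india_2000_2019",)


def load_reference(name: str = "india_2000_2019") -> pd.DataFrame:
    """Load a packaged reference table as a DataFrame.

    Columns: year (int), sex {total, male, female}, method {direct,
    loglogistic, gompertz, weibull, who}, le, hlyl, hle (years; NaN where
    not published).
    """
    key = name.removeprefix("builtin:")
    if key not in BUILTIN_REFERENCES:
        raise KeyError(f"unknown reference {name!r}; available: {BUILTIN_REFERENCES}")
    with resources.files("lifeyears.data").joinpath(f"{key}.csv").open() as fh:
        df = pd.read_csv(fh)
    df["year"] = df["year"].astype(int)
    return df
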