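"""Longitudinal 0/1 coding of the two longevity indicators over ages 2-15.

Traditional longevity (TL): 1 while the cow is alive, 0 from the culling
age onward. Functional longevity (FL): 1 at ages with a recorded calving,
0 from the culling age onward, missing at alive ages without a calving.

For a censored cow (unknown culling age) information is truncated at her
last reported calving: TL is 1 up to that age and missing afterwards; FL
is 1 at the calving ages and missing everywhere else.

The culling year itself is coded 0 for both indicators (the cow is no
longer in production in the year she is culled).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AGE_MAX, AGE_MIN, AGES, CowHistory

__all__ = ["code_tl", "code_fl", "code_trait", "trajectory_table", "TRAITS"]

TRAITS = ("TL", "FL")


def _check(history: CowHistory) -> None:
    if history.is_censored:
        # a censored cow with no reported calving carries no information:
        # every code is missing
        return
    if history.culling_age is None:
        raise ValueError(f"cow {history.cow}: unknown culling age but not censored")
    if history.culling_age < AGE_MIN:
        raise ValueError(
            f"cow {history.cow}: culling age {history.culling_age} < {AGE_MIN} "
            "is inconsistent with first calving before 30 months")


def code_tl(history: CowHistory) -> np.ndarray:
    """TL codes for ages 2..15; NaN marks a missing record."""
    _check(history)
    codes = np.full(len(AGES), np.nan)
    if history.is_censored:
        last = history.last_calving_age
        if last is not None:
            codes[AGES <= last] = 1.0
    else:
        codes[AGES < history.culling_age] = 1.0
        codes[AGES >= history.culling_age] = 0.0
    return codes


def code_fl(history: CowHistory) -> np.ndarray:
    """FL codes for ages 2..15; NaN marks a missing record."""
    _check(history)
    codes = np.full(len(AGES), np.nan)
    calv = np.isin(AGES, list(history.calving_ages))
    codes[calv] = 1.0
    if not history.is_censored:
        codes[AGES >= history.culling_age] = 0.0
    return codes


def code_trait(history: CowHistory, trait: str) -> np.ndarray:
    if trait == "TL":
        return code_tl(history)
    if trait == "FL":
        return code_fl(history)
    raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")


def trajectory_table(histories, trait: str) -> pd.DataFrame:
    """Long-format (cow, age, code) table; exactly 14 rows per cow, code
    NaN where the record is missing."""
    n = len(histories)
    codes = np.empty((n, len(AGES)))
    cows = np.empty(n, dtype=np.int64)
    for i, h in enumerate(histories):
        codes[i] = code_trait(h, trait)
        cows[i] = h.cow
    return pd.DataFrame({
        "cow": np.repeat(cows, len(AGES)),
        "age": np.tile(AGES, n),
        "code": codes.ravel(),
    })


def write_trajectories(table: pd.DataFrame, path) -> None:
    """Delimited long-format export; missing codes as empty fields."""
    table.to_csv(path, sep="\t", index=False, na_rep="")


def write_wide(table: pd.DataFrame, path, missing_code: str = "0") -> None:
    """Optional wide export (one column per age), missing as a 0-weight
    placeholder code, for interoperability with BLUPF90-style layouts."""
    wide = table.pivot(index="cow", columns="age", values="code")
    wide.columns = [f"age{c}" for c in wide.columns]
    wide.to_csv(path, sep="\t", na_rep=missing_code)
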