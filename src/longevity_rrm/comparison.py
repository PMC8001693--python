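"""Scenario-contrast statistics: commonly-selected proportions, EBV
correlations, paired t-tests, and replicate aggregation.

Every contrast compares a scenario's EBV matrix against the complete-data
(COM) reference of the same design and replicate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AGES

__all__ = ["top_overlap", "ebv_correlation", "paired_ttest",
           "replicate_aggregate", "ReplicateSummary", "overlap_by_age",
           "significance_groups"]


def _top_set(ebv: np.ndarray, age_col: int, n_top: int) -> set:
    # stable order: EBV descending, then row (animal) index ascending
    order = np.lexsort((np.arange(ebv.shape[0]), -ebv[:, age_col]))
    return set(order[:n_top].tolist())


def top_overlap(ref: np.ndarray, alt: np.ndarray, age: int, fraction: float) -> float:
    """Proportion of the reference's top animals at one age also in the
    alternative's top set (top-set size = round(fraction * n))."""
    ref, alt = np.asarray(ref), np.asarray(alt)
    if ref.shape != alt.shape:
        raise ValueError(f"EBV matrices differ in shape: {ref.shape} vs {alt.shape}")
    col = int(np.where(AGES == age)[0][0]) if age in AGES else None
    if col is None:
        raise ValueError(f"age {age} outside the evaluated range {AGES[0]}-{AGES[-1]}")
    n_top = int(round(fraction * ref.shape[0]))
    if n_top < 1:
        raise ValueError(f"fraction {fraction} selects no animals out of {ref.shape[0]}")
    top_ref = _top_set(ref, col, n_top)
    top_alt = _top_set(alt, col, n_top)
    return len(top_ref & top_alt) / len(top_ref)


def overlap_by_age(ref: np.ndarray, alt: np.ndarray, fraction: float) -> np.ndarray:
    return np.array([top_overlap(ref, alt, age, fraction) for age in AGES])


def ebv_correlation(ref: np.ndarray, alt: np.ndarray, scope: str = "all",
                    age: int = 4, censored_ids=None, animal_ids=None) -> float:
    """Pearson correlation between two scenarios' EBVs.

    scope 'all': flattened over every animal and age;
    scope 'age_censored'/'age_uncensored': the single-age column restricted
    to cows whose records were / were not censored-penalized (requires
    ``censored_ids`` and the matrices' ``animal_ids`` row labels).
    """
    ref, alt = np.asarray(ref, float), np.asarray(alt, float)
    if ref.shape != alt.shape:
        raise ValueError(f"EBV matrices differ in shape: {ref.shape} vs {alt.shape}")
    if scope == "all":
        x, y = ref.ravel(), alt.ravel()
    elif scope in ("age_censored", "age_uncensored"):
        if censored_ids is None or animal_ids is None:
            raise ValueError("age-restricted scopes need censored_ids and animal_ids")
        col = int(np.where(AGES == age)[0][0])
        mask = np.isin(np.asarray(animal_ids), list(censored_ids))
        if scope == "age_uncensored":
            mask = ~mask
        x, y = ref[mask, col], alt[mask, col]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side of the correlation")
    return float(stats.pearsonr(x, y).statistic)


def paired_ttest(a, b) -> tuple:
    """Two-sided paired t-test; returns (t, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-d series")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0 and d[0] != 0:
        raise ValueError("zero-variance non-zero differences: t undefined")
    if np.ptp(d) == 0:  # identical series: t = 0, p = 1 by convention
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ReplicateSummary:
    mean: float
    sd: float
    se: float
    n: int
    degenerate: bool  # single replicate: SD reported as 0 with this flag


def replicate_aggregate(values) -> ReplicateSummary:
    """Mean, sample SD (n-1) and SE over replicates."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("no replicate values")
    if len(v) == 1:
        return ReplicateSummary(mean=float(v[0]), sd=0.0, se=0.0, n=1,
                                degenerate=True)
    sd = float(v.std(ddof=1))
    return ReplicateSummary(mean=float(v.mean()), sd=sd,
                            se=sd / np.sqrt(len(v)), n=len(v), degenerate=False)


def significance_groups(values: pd.DataFrame, alpha: float = 0.05,
                        correction: str = "none") -> pd.DataFrame:
    """Pairwise paired t-tests between scenario columns (replicates as rows).

    Returns a tidy table (scenario_a, scenario_b, t, p, significant).
    ``correction='bonferroni'`` is available but off by default, matching
    the uncorrected presentation convention.
    """
    cols = list(values.columns)
    rows = []
    n_tests = len(cols) * (len(cols) - 1) // 2
    for i, ca in enumerate(cols):
        for cb in cols[i + 1:]:
            t, p = paired_ttest(values[ca].to_numpy(), values[cb].to_numpy())
            p_adj = min(1.0, p * n_tests) if correction == "bonferroni" else p
            rows.append({"scenario_a": ca, "scenario_b": cb, "t": t, "p": p_adj,
                         "significant": p_adj < alpha})
    return pd.DataFrame(rows)
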