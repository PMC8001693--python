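"""Shared domain types for the longevity random-regression study.

Ages are whole years of cow age; the evaluation window is 2-15 years
(14 ages). Random-regression effects are parameterized by ``k`` Legendre
coefficients per effect level on the standardized age scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

AGE_MIN = 2
AGE_MAX = 15
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGE_MAX - AGE_MIN + 1

UNKNOWN_PARENT = 0

CENSOR_STATES = ("uncensored", "censored", "penalized-m1", "penalized-m2", "penalized-m3")


class ConfigurationError(ValueError):
    """Raised when a simulation or scenario configuration is unusable."""


def _check_psd(m: np.ndarray, name: str, tol: float = 1e-10) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError(f"{name} must be a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ConfigurationError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ConfigurationError(f"{name} is not positive semi-definite (min eig {w.min():.3e})")


def structured_coefficient_cov(scale: float, k: int = 5,
                               weights: tuple = (1.0, 0.2, 0.05, 0.02, 0.008),
                               rho: float = 0.5) -> np.ndarray:
    """Coefficient-scale covariance with geometrically decaying weight on
    higher polynomial degrees and AR-like cross-coefficient correlation.

    Gives a smooth, mildly U-shaped age-variance profile with the late-age
    rise typical of Legendre covariance functions.
    """
    w = np.asarray(weights, dtype=float)[:k]
    if len(w) < k:
        w = np.concatenate([w, np.full(k - len(w), w[-1] / 2)])
    idx = np.arange(k)
    corr = rho ** np.abs(np.subtract.outer(idx, idx))
    return scale * np.sqrt(np.outer(w, w)) * corr


def default_baseline_survival(sigma_total: float = 0.35,
                              survival_start: float = 0.93,
                              survival_end: float = 0.70) -> np.ndarray:
    """Per-age latent intercepts mu_j for ages 2-15.

    Chosen so that, for an average cow, the probability that the latent
    culling score stays at or above the 0.5 threshold declines linearly
    from ``survival_start`` (age 2) to ``survival_end`` (age 15) -- an
    annual survival pattern typical of beef-cow herd-life data.
    """
    from scipy.stats import norm

    s = np.linspace(survival_start, survival_end, N_AGES)
    return 0.5 + norm.ppf(s) * sigma_total


@dataclass
class SimConfig:
    """Configuration of the synthetic population generator."""

    n_base_animals: int = 850
    n_generations: int = 4
    n_cows_target: int = 2000
    n_herds: int = 15
    seasons_per_year: int = 2
    year_range: tuple = (1990, 2005)
    k_coefficients: int = 5
    G0_true: np.ndarray = field(default_factory=lambda: structured_coefficient_cov(0.016))
    Rq_true: np.ndarray = field(default_factory=lambda: structured_coefficient_cov(0.008))
    Rp_true: np.ndarray = field(default_factory=lambda: structured_coefficient_cov(0.020))
    sigma_e2_true: float = 0.09
    baseline_survival: np.ndarray = field(default_factory=default_baseline_survival)
    calving_skip_prob: float = 0.15
    et_proportion: float = 0.05
    et_shift: float = 0.02
    first_calving_months_range: tuple = (23, 29)
    use_inbreeding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.k_coefficients
        if k < 1:
            raise ConfigurationError("k_coefficients must be >= 1")
        for name in ("G0_true", "Rq_true", "Rp_true"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if m.shape != (k, k):
                raise ConfigurationError(f"{name} must be {k}x{k}, got {m.shape}")
            _check_psd(m, name)
        if self.sigma_e2_true <= 0:
            raise ConfigurationError("sigma_e2_true must be > 0")
        self.baseline_survival = np.asarray(self.baseline_survival, dtype=float)
        if self.baseline_survival.shape != (N_AGES,):
            raise ConfigurationError(
                f"baseline_survival must have one intercept per age 2-15 ({N_AGES} values)")
        for p in ("calving_skip_prob", "et_proportion"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{p} must be in [0, 1], got {v}")
        if self.n_base_animals < 2:
            raise ConfigurationError("n_base_animals must be >= 2")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        lo, hi = self.first_calving_months_range
        if not (0 < lo <= hi < 30):
            raise ConfigurationError("first calving months must lie strictly before 30 months")

    def scaled(self, factor: float) -> "SimConfig":
        """Return a copy with population counts scaled by ``factor``."""
        if not 0 < factor <= 1:
            raise ConfigurationError("scale factor must be in (0, 1]")
        return replace(
            self,
            n_base_animals=max(2, int(round(self.n_base_animals * factor))),
            n_cows_target=max(1, int(round(self.n_cows_target * factor))),
        )


class Pedigree:
    """Topologically ordered pedigree.

    Animal ids are consecutive integers 1..n; parents always have smaller
    ids than their offspring and 0 marks an unknown parent.
    """

    COLUMNS = ["id", "sire", "dam", "sex", "birth_year", "birth_season", "herd", "et_flag"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns {missing}")
        table = table[self.COLUMNS].reset_index(drop=True)
        ids = table["id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(table) + 1)):
            raise ValueError("pedigree ids must be consecutive integers 1..n in order")
        for col in ("sire", "dam"):
            parent = table[col].to_numpy()
            bad = parent >= ids
            if bad.any():
                raise ValueError(
                    f"pedigree not topologically ordered: {col} of animal "
                    f"{ids[bad][0]} is {parent[bad][0]}")
        self.table = table

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def sire(self) -> np.ndarray:
        return self.table["sire"].to_numpy()

    @property
    def dam(self) -> np.ndarray:
        return self.table["dam"].to_numpy()

    def females(self) -> np.ndarray:
        return self.table.loc[self.table["sex"] == "F", "id"].to_numpy()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.table.equals(other.table)


@dataclass
class GeneticEffects:
    """True random-regression coefficients used by the generator.

    ``a`` and ``p`` are (n_animals, k); ``q`` maps HYS class keys
    (herd, year, season) to k-vectors.
    """

    a: np.ndarray
    p: np.ndarray
    q: dict

    @property
    def k(self) -> int:
        return self.a.shape[1]


@dataclass
class CowHistory:
    """One cow's productive history: the unit the scenario machinery transforms."""

    cow: int
    herd: int
    birth_year: int
    birth_season: int
    et_flag: int
    first_calving_age_months: int
    calving_ages: tuple
    culling_age: Optional[int]
    natural_death: int = 1
    censoring_state: str = "uncensored"

    def __post_init__(self) -> None:
        self.calving_ages = tuple(sorted(set(int(a) for a in self.calving_ages)))
        if self.censoring_state not in CENSOR_STATES:
            raise ValueError(f"unknown censoring state {self.censoring_state!r}")
        if self.culling_age is not None and self.calving_ages:
            if max(self.calving_ages) >= self.culling_age:
                raise ValueError(
                    f"cow {self.cow}: calving at age {max(self.calving_ages)} not "
                    f"before culling age {self.culling_age}")

    @property
    def last_calving_age(self) -> Optional[int]:
        return max(self.calving_ages) if self.calving_ages else None

    @property
    def is_censored(self) -> bool:
        return self.censoring_state == "censored"


def histories_to_table(histories) -> pd.DataFrame:
    """Delimited-text-friendly table of cow histories (one row per cow)."""
    rows = [{
        "cow": h.cow, "herd": h.herd, "birth_year": h.birth_year,
        "birth_season": h.birth_season, "et_flag": h.et_flag,
        "first_calving_age_months": h.first_calving_age_months,
        "calving_ages": ",".join(str(a) for a in h.calving_ages),
        "culling_age": "" if h.culling_age is None else h.culling_age,
        "natural_death": h.natural_death,
        "censoring_state": h.censoring_state,
    } for h in histories]
    return pd.DataFrame(rows)


def histories_from_table(table: pd.DataFrame) -> list:
    out = []
    for r in table.itertuples(index=False):
        ca = r.culling_age
        culling = None if (pd.isna(ca) or str(ca) == "") else int(float(ca))
        calv = str(r.calving_ages)
        calvings = tuple(int(x) for x in calv.split(",")) if calv not in ("", "nan") else ()
        out.append(CowHistory(
            cow=int(r.cow), herd=int(r.herd), birth_year=int(r.birth_year),
            birth_season=int(r.birth_season), et_flag=int(r.et_flag),
            first_calving_age_months=int(r.first_calving_age_months),
            calving_ages=calvings, culling_age=culling,
            natural_death=int(r.natural_death), censoring_state=str(r.censoring_state)))
    return out


@dataclass
class VarianceComponents:
    """Coefficient-scale covariance matrices of the model's random effects."""

    G0: np.ndarray
    Rq: np.ndarray
    Rp: np.ndarray
    sigma_e2: float

    def __post_init__(self) -> None:
        self.G0 = np.asarray(self.G0, dtype=float)
        self.Rq = np.asarray(self.Rq, dtype=float)
        self.Rp = np.asarray(self.Rp, dtype=float)
        for name in ("G0", "Rq", "Rp"):
            _check_psd(getattr(self, name), name, tol=1e-8)
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")

    @property
    def k(self) -> int:
        return self.G0.shape[0]


@dataclass
class PriorSpec:
    """Priors of the Bayesian random-regression model.

    Fixed effects get independent zero-mean normals with variance
    ``sigma_b`` (vague by default). Each random-effect covariance matrix
    gets an inverted Wishart with ``iw_df`` degrees of freedom; the
    residual variance a scaled inverted chi-squared. ``iw_df=3`` with a
    k x k matrix (k>2) is improper as a prior but yields a proper
    posterior once data enter; ``is_proper`` reports this.
    """

    sigma_b: float = 1e10
    iw_df: float = 3.0
    iw_scale_g: Optional[np.ndarray] = None
    iw_scale_q: Optional[np.ndarray] = None
    iw_scale_p: Optional[np.ndarray] = None
    iw_scale_default: float = 1e-3
    residual_df: float = 0.0
    residual_scale: float = 0.0

    def scale_matrix(self, which: str, k: int) -> np.ndarray:
        m = {"g": self.iw_scale_g, "q": self.iw_scale_q, "p": self.iw_scale_p}[which]
        if m is None:
            return self.iw_scale_default * np.eye(k)
        m = np.asarray(m, dtype=float)
        _check_psd(m, f"iw_scale_{which}")
        return m

    def is_proper(self, k: int) -> bool:
        return self.iw_df > k + 1 and self.residual_df > 0


@dataclass
class ChainConfig:
    """MCMC run lengths. ``paper`` preset is the published 150,000/50,000/10."""

    chain_length: int = 5000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.chain_length:
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < chain_length")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin

    @classmethod
    def paper(cls, seed: int = 0) -> "ChainConfig":
        return cls(chain_length=150_000, burn_in=50_000, thin=10, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "ChainConfig":
        return cls(chain_length=5000, burn_in=1000, thin=5, seed=seed)


DESIGNS = ("D1_fixed_uncensored", "D2_fixed_total")
TREATMENTS = ("COM", "CEN", "PENm1", "PENm2", "PENm3")
LEVELS = (0, 20, 40, 60, 80)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study grid: design x censoring level x treatment."""

    design: str
    level: int
    treatment: str
    replicate: int = 1
    seed: int = 0
    reference_age_source: str = "evaluation_year"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigurationError(f"design must be one of {DESIGNS}")
        if self.level not in LEVELS:
            raise ConfigurationError(f"level must be one of {LEVELS}")
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"treatment must be one of {TREATMENTS}")
        if (self.level == 0) != (self.treatment == "COM"):
            raise ConfigurationError("level 0 if and only if treatment COM")
        if self.reference_age_source not in ("evaluation_year", "last_calving"):
            raise ConfigurationError("unknown reference_age_source")

    @property
    def name(self) -> str:
        tag = "COM" if self.treatment == "COM" else (
            f"CEN{self.level}" if self.treatment == "CEN"
            else f"PEN{self.level}{self.treatment[3:]}")
        return f"{self.design.split('_')[0]}-{tag}-r{self.replicate}"
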