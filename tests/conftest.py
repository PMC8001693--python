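import numpy as np
import pandas as pd
import pytest

from longevity_rrm.datatypes import CowHistory, Pedigree, SimConfig
from longevity_rrm.synthetic_data import simulate_population


def make_pedigree(sire, dam, sex=None, herd=None, birth_year=None):
    """Minimal pedigree from parent lists (0 = unknown)."""
    n = len(sire)
    return Pedigree(pd.DataFrame({
        "id": np.arange(1, n + 1), "sire": sire, "dam": dam,
        "sex": sex if sex is not None else ["F"] * n,
        "birth_year": birth_year if birth_year is not None else [1995] * n,
        "birth_season": [0] * n,
        "herd": herd if herd is not None else [1] * n,
        "et_flag": [0] * n}))


def random_pedigree(n, seed=0, founders=4):
    rng = np.random.default_rng(seed)
    sire = [0] * founders
    dam = [0] * founders
    for i in range(founders, n):
        sire.append(int(rng.integers(0, i)))  # 0 = unknown allowed
        dam.append(int(rng.integers(0, i)))
    return make_pedigree(sire, dam)


def make_history(cow=1, culling_age=8, calvings=None, censored=False, herd=1,
                 birth_year=1995, first_calving_months=24, **kw):
    if calvings is None:
        upper = culling_age if culling_age is not None else 16
        calvings = tuple(range(2, upper))
    return CowHistory(cow=cow, herd=herd, birth_year=birth_year, birth_season=0,
                      et_flag=0, first_calving_age_months=first_calving_months,
                      calving_ages=tuple(calvings),
                      culling_age=None if censored else culling_age,
                      censoring_state="censored" if censored else "uncensored",
                      **kw)


@pytest.fixture(scope="session")
def tiny_population():
    """Small population shared by model-fitting tests (~90 cows)."""
    cfg = SimConfig(n_base_animals=60, n_generations=2, n_cows_target=40,
                    n_herds=3, seed=3)
    ped, eff, hist = simulate_population(cfg)
    return cfg, ped, eff, hist
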