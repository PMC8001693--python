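"""Synthetic beef-cow populations with the covariance structure the
random-regression model assumes.

The real longevity data this pipeline was designed around is proprietary,
so every downstream stage is exercised on populations generated here:
a multi-generation pedigree with herd structure, true additive /
permanent-environment / herd-year-season random-regression coefficients
drawn from known covariance matrices, and a discrete-time culling process
over ages 2-15.

Culling is driven by a latent annual score

    eta_ij = mu_j + et_shift * ET_i + phi(t_j)' (a_i + p_i + q_h(i,j)) + e_ij

on the same 0/1 scale as the fitted linear model: the cow is culled at
the first age where eta < 0.5. Cows that survive age 15 receive a culling
age uniform in (15, 20], emulating the natural-death inclusion rule
(culled after 15 or died naturally). All random draws are made up front,
so the mapping from baseline survival to culling ages is monotone under
common random numbers.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (AGES, N_AGES, UNKNOWN_PARENT, ConfigurationError,
                        CowHistory, GeneticEffects, Pedigree, SimConfig)
from .rrm_model import inbreeding_coefficients, legendre_covariates

__all__ = ["simulate_pedigree", "simulate_genetic_effects",
           "simulate_cow_histories", "apply_quality_control", "simulate_population"]

logger = logging.getLogger(__name__)

GENERATION_INTERVAL_YEARS = 3


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation pedigree with random mating within herd.

    Each generation has ``n_base_animals`` animals; dams are sampled from
    the previous generation's females of the same herd, sires from the
    previous generation's males of any herd (AI-style connectedness).
    """
    rng = np.random.default_rng(config.seed)
    n_gen = config.n_generations
    n_per = config.n_base_animals
    year0, year1 = config.year_range

    ids, sires, dams, sexes, byears, bseasons, herds, ets = [], [], [], [], [], [], [], []
    prev_males: np.ndarray = np.array([], dtype=int)
    prev_fem_by_herd: dict = {}
    next_id = 1
    for g in range(n_gen + 1):
        byear_base = min(year0 + g * GENERATION_INTERVAL_YEARS, year1)
        gen_ids = np.arange(next_id, next_id + n_per)
        sex = np.where(rng.random(n_per) < 0.5, "M", "F")
        herd = rng.integers(0, config.n_herds, n_per) + 1
        season = rng.integers(0, config.seasons_per_year, n_per)
        byear = byear_base + rng.integers(0, min(GENERATION_INTERVAL_YEARS,
                                                 year1 - byear_base + 1), n_per)
        et = (rng.random(n_per) < config.et_proportion).astype(int)
        if g == 0:
            sire = np.full(n_per, UNKNOWN_PARENT)
            dam = np.full(n_per, UNKNOWN_PARENT)
        else:
            if len(prev_males) == 0 or not prev_fem_by_herd:
                raise ConfigurationError(
                    f"generation {g - 1} has no males or no females; cannot mate")
            sire = rng.choice(prev_males, n_per)
            dam = np.empty(n_per, dtype=int)
            for j in range(n_per):
                fems = prev_fem_by_herd.get(herd[j])
                if fems is None:  # no female in this herd last generation
                    all_f = np.concatenate(list(prev_fem_by_herd.values()))
                    dam[j] = rng.choice(all_f)
                else:
                    dam[j] = rng.choice(fems)
        ids.append(gen_ids)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        byears.append(byear)
        bseasons.append(season)
        herds.append(herd)
        ets.append(et)
        fem = sex == "F"
        prev_males = gen_ids[~fem]
        prev_fem_by_herd = {h: gen_ids[fem & (herd == h)]
                            for h in np.unique(herd[fem])}
        next_id += n_per

    table = pd.DataFrame({
        "id": np.concatenate(ids), "sire": np.concatenate(sires),
        "dam": np.concatenate(dams), "sex": np.concatenate(sexes),
        "birth_year": np.concatenate(byears), "birth_season": np.concatenate(bseasons),
        "herd": np.concatenate(herds), "et_flag": np.concatenate(ets)})
    ped = Pedigree(table)
    n_females = len(ped.females())
    if n_females < config.n_cows_target:
        raise ConfigurationError(
            f"pedigree yields {n_females} females < n_cows_target="
            f"{config.n_cows_target}; increase n_base_animals or n_generations")
    return ped


def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    """n draws from N(0, cov), handling positive semi-definite cov."""
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)
    return rng.standard_normal((n, cov.shape[0])) @ root.T


def hys_class_grid(pedigree: Pedigree, config: SimConfig) -> list:
    """All (herd, year, season) classes a record could fall into."""
    by = pedigree.table["birth_year"]
    years = range(int(by.min()) + AGES[0], int(by.max()) + AGES[-1] + 1)
    return [(h, y, s) for h in range(1, config.n_herds + 1)
            for y in years for s in range(config.seasons_per_year)]


def simulate_genetic_effects(pedigree: Pedigree, config: SimConfig) -> GeneticEffects:
    """True coefficients: founders ~ N(0, G0); descendants get parent
    average plus a Mendelian-sampling deviation with covariance
    (0.5 - 0.25(F_s + F_d)) G0; PE and HYS coefficients are iid."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n, k = pedigree.n, config.k_coefficients
    sire, dam = pedigree.sire, pedigree.dam
    if config.use_inbreeding:
        F = inbreeding_coefficients(sire, dam)
    else:
        F = np.zeros(n)

    z = _draw_mvn(rng, config.G0_true, n)
    a = np.zeros((n, k))
    for i in range(n):
        s, d = sire[i], dam[i]
        pa = np.zeros(k)
        n_known = int(s != UNKNOWN_PARENT) + int(d != UNKNOWN_PARENT)
        fs = F[s - 1] if s != UNKNOWN_PARENT else 0.0
        fd = F[d - 1] if d != UNKNOWN_PARENT else 0.0
        if s != UNKNOWN_PARENT:
            pa += 0.5 * a[s - 1]
        if d != UNKNOWN_PARENT:
            pa += 0.5 * a[d - 1]
        if n_known == 2:
            dvar = 0.5 - 0.25 * (fs + fd)
        elif n_known == 1:
            dvar = 0.75 - 0.25 * (fs + fd)
        else:
            dvar = 1.0
        a[i] = pa + np.sqrt(dvar) * z[i]
    p = _draw_mvn(rng, config.Rp_true, n)
    classes = hys_class_grid(pedigree, config)
    qm = _draw_mvn(rng, config.Rq_true, len(classes))
    q = {c: qm[i] for i, c in enumerate(classes)}
    return GeneticEffects(a=a, p=p, q=q)


def simulate_cow_histories(pedigree: Pedigree, effects: GeneticEffects,
                           config: SimConfig) -> list:
    """Culling and calving histories for every female in the pedigree."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    tab = pedigree.table
    fem = tab[tab["sex"] == "F"]
    cows = fem["id"].to_numpy()
    nc = len(cows)
    if effects.a.shape[0] < pedigree.n:
        missing = cows[cows > effects.a.shape[0]]
        raise KeyError(f"no genetic effects for cows {missing[:5].tolist()}")
    k = config.k_coefficients
    phi = legendre_covariates(AGES, k)  # (14, k)

    herd = fem["herd"].to_numpy()
    byear = fem["birth_year"].to_numpy()
    bseason = fem["birth_season"].to_numpy()
    et = fem["et_flag"].to_numpy()

    g = effects.a[cows - 1] + effects.p[cows - 1]  # (nc, k)
    qmat = np.zeros((nc, N_AGES))
    for j, age in enumerate(AGES):
        for i in range(nc):
            key = (herd[i], byear[i] + age, bseason[i])
            qv = effects.q.get(key)
            if qv is None:
                raise KeyError(f"no HYS effect for class {key} (cow {cows[i]})")
            qmat[i, j] = phi[j] @ qv

    # all random draws up front (common random numbers across config tweaks)
    noise = rng.standard_normal((nc, N_AGES)) * np.sqrt(config.sigma_e2_true)
    post15 = rng.integers(16, 21, nc)  # uniform in (15, 20]
    lo, hi = config.first_calving_months_range
    fc_months = rng.integers(lo, hi + 1, nc)
    skip = rng.random((nc, 19))  # potential calving ages 2..20

    eta = (config.baseline_survival[None, :] + config.et_shift * et[:, None]
           + g @ phi.T + qmat + noise)
    culled = eta < 0.5
    first = np.where(culled.any(axis=1), culled.argmax(axis=1), -1)
    culling_age = np.where(first >= 0, AGES[0] + first, post15)

    histories = []
    for i in range(nc):
        ca = int(culling_age[i])
        ages_in_prod = range(2, ca)
        calvings = [2] + [a for a in ages_in_prod if a > 2
                          and skip[i, a - 2] >= config.calving_skip_prob]
        if ca == 2:
            calvings = []  # culled in the year of first calving
        histories.append(CowHistory(
            cow=int(cows[i]), herd=int(herd[i]), birth_year=int(byear[i]),
            birth_season=int(bseason[i]), et_flag=int(et[i]),
            first_calving_age_months=int(fc_months[i]),
            calving_ages=tuple(calvings), culling_age=ca))
    return histories


def apply_quality_control(histories, return_counts: bool = False):
    """Standard phenotypic filters: cow born in 1990 or later, first
    calving strictly before 30 months, culling age at most 20 years."""
    counts = {"born_before_1990": 0, "first_calving_30mo_or_later": 0,
              "culling_age_over_20": 0}
    kept = []
    for h in histories:
        if h.birth_year < 1990:
            counts["born_before_1990"] += 1
        elif h.first_calving_age_months >= 30:
            counts["first_calving_30mo_or_later"] += 1
        elif h.culling_age is not None and h.culling_age > 20:
            counts["culling_age_over_20"] += 1
        else:
            kept.append(h)
    removed = sum(counts.values())
    logger.info("quality control removed %d of %d cows: %s",
                removed, len(histories), counts)
    if not kept:
        logger.warning("quality control removed every cow")
    if return_counts:
        return kept, counts
    return kept


def observed_scale_heritability(config: SimConfig, trait: str = "TL",
                                n_pairs: int = 100_000, seed: int = 0) -> np.ndarray:
    """Generating heritability of the 0/1 codes, by clone-pair simulation.

    Two cows per pair share the additive coefficients a but draw
    independent permanent-environment, herd-year-season, and residual
    terms; the cross-pair covariance of the codes at age j is therefore
    the additive variance on the observed scale, and its ratio to the
    total code variance is the observed-scale h2_j. This is the exact
    generating value the linear model fitted to the codes estimates,
    unlike the latent-scale h2, which the threshold culling process
    attenuates.
    """
    if trait not in ("TL", "FL"):
        raise ValueError(f"unknown trait {trait!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 43]))
    k = config.k_coefficients
    phi = legendre_covariates(AGES, k)

    def _root(cov):
        w, V = np.linalg.eigh(cov)
        return V * np.sqrt(np.clip(w, 0.0, None))

    a = rng.standard_normal((n_pairs, k)) @ _root(config.G0_true).T
    ga = a @ phi.T
    codes = []
    for _clone in range(2):
        p = rng.standard_normal((n_pairs, k)) @ _root(config.Rp_true).T
        q = rng.standard_normal((n_pairs, k)) @ _root(config.Rq_true).T
        e = rng.standard_normal((n_pairs, N_AGES)) * np.sqrt(config.sigma_e2_true)
        eta = config.baseline_survival[None, :] + ga + (p + q) @ phi.T + e
        culled = eta < 0.5
        first = np.where(culled.any(axis=1), culled.argmax(axis=1), 99)
        cull_age = np.where(first < 99, AGES[0] + first, 99)
        y = (AGES[None, :] < cull_age[:, None]).astype(float)
        if trait == "FL":
            skip = rng.random((n_pairs, N_AGES)) < config.calving_skip_prob
            skip[:, 0] = False  # first calving always at age 2
            y[(y == 1.0) & skip] = np.nan
        codes.append(y)
    y1, y2 = codes
    h2 = np.empty(N_AGES)
    for j in range(N_AGES):
        ok = ~np.isnan(y1[:, j]) & ~np.isnan(y2[:, j])
        va = np.cov(y1[ok, j], y2[ok, j])[0, 1]
        vt = 0.5 * (np.nanvar(y1[:, j]) + np.nanvar(y2[:, j]))
        h2[j] = va / vt if vt > 0 else 0.0
    return h2


def simulate_population(config: SimConfig):
    """Convenience wrapper: pedigree, true effects, QC-filtered histories."""
    ped = simulate_pedigree(config)
    eff = simulate_genetic_effects(ped, config)
    hist = apply_quality_control(simulate_cow_histories(ped, eff, config))
    return ped, eff, hist
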