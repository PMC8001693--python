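"""Orchestration of the full scenario study.

One :class:`RunConfig` drives the factorial grid (longevity indicator x
design x censoring level x treatment x replicate): the base population is
simulated once and shared, censoring assignments differ only by replicate
seed, the complete-data (COM) fit of each (trait, design, replicate) cell
is reused as the reference for every contrast, and completed cells are
skipped on re-runs (results are cached as delimited text under the output
directory).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .censoring_penalty import assign_censoring, build_design, design_counts
from .comparison import ebv_correlation, overlap_by_age, replicate_aggregate
from .datatypes import (AGES, ChainConfig, ConfigurationError, PriorSpec,
                        ScenarioSpec, SimConfig)
from .genetic_parameters import (covariance_functions, ebv_trajectories,
                                 heritability_by_age)
from .gibbs import gibbs_sample, posterior_summarize
from .rrm_model import assemble_mme, build_model_data, solve_blup
from .synthetic_data import simulate_population
from .trait_coding import TRAITS, trajectory_table

__all__ = ["RunConfig", "ScenarioResult", "run_study", "fit_scenario",
           "load_run_config", "PAPER_UNCENSORED_POOL", "PAPER_TOTAL"]

logger = logging.getLogger(__name__)

PAPER_UNCENSORED_POOL = 55_000  # design 1: fixed uncensored count
PAPER_TOTAL = 100_000           # design 2: fixed total count


@dataclass
class RunConfig:
    """Study-level configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    chain: ChainConfig = field(default_factory=ChainConfig.desk)
    priors: PriorSpec = field(default_factory=PriorSpec)
    traits: tuple = TRAITS
    designs: tuple = ("D2_fixed_total",)
    levels: tuple = (20, 40, 60, 80)
    treatments: tuple = ("CEN", "PENm1", "PENm2", "PENm3")
    n_replicates: int = 3
    scale_factor: float = 0.02
    k: int = 5
    top_fractions: tuple = (0.01, 0.10)
    contrast_age: int = 4
    reference_age_source: str = "evaluation_year"
    out_dir: Optional[str] = None
    base_seed: int = 0

    def __post_init__(self):
        if not 0 < self.scale_factor <= 1:
            raise ConfigurationError("scale_factor must be in (0, 1]")
        for t in self.treatments:
            if t not in ("CEN", "PENm1", "PENm2", "PENm3"):
                raise ConfigurationError(f"unknown treatment {t}")

    @property
    def pool_d1(self) -> int:
        return int(round(PAPER_UNCENSORED_POOL * self.scale_factor))

    @property
    def total_d2(self) -> int:
        return int(round(PAPER_TOTAL * self.scale_factor))


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a hierarchical YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "sim" in kwargs:
        kwargs["sim"] = SimConfig(**kwargs["sim"])
    if "chain" in kwargs:
        kwargs["chain"] = ChainConfig(**kwargs["chain"])
    if "priors" in kwargs:
        kwargs["priors"] = PriorSpec(**kwargs["priors"])
    for key in ("traits", "designs", "levels", "treatments", "top_fractions"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


@dataclass
class ScenarioResult:
    """Fit outputs of one scenario cell."""

    spec: ScenarioSpec
    trait: str
    heritability: object            # HeritabilityTrajectory
    ebv: np.ndarray                 # animals x 14
    animal_ids: np.ndarray
    censored_ids: frozenset
    vc_mean: object                 # VarianceComponents
    manifest: dict
    seconds: float


def fit_scenario(dataset, trait: str, pedigree, run: RunConfig,
                 chain_seed: int) -> ScenarioResult:
    """Code the trait, fit the model, and transform to the age scale."""
    t0 = time.time()
    recs = trajectory_table(dataset.histories, trait)
    md = build_model_data(recs, dataset.histories, pedigree, k=run.k)
    chain = ChainConfig(chain_length=run.chain.chain_length,
                        burn_in=run.chain.burn_in, thin=run.chain.thin,
                        seed=chain_seed)
    draws = gibbs_sample(md, run.priors, chain)
    summ = posterior_summarize(draws)
    h2 = heritability_by_age(covariance_functions(md.T, summ.vc_mean),
                             summ.vc_mean.sigma_e2)
    ebv = ebv_trajectories(md.T, draws.location_mean["animal"])
    secs = time.time() - t0
    logger.info("%s %s fitted in %.1f s (%d records)",
                dataset.spec.name, trait, secs, md.n_records)
    return ScenarioResult(spec=dataset.spec, trait=trait, heritability=h2,
                          ebv=ebv, animal_ids=md.animal_ids,
                          censored_ids=dataset.censored_ids,
                          vc_mean=summ.vc_mean, manifest=dataset.manifest,
                          seconds=secs)


def blup_scenario_ebvs(dataset, trait: str, pedigree, vc, k: int = 5,
                       priors: Optional[PriorSpec] = None):
    """Scenario EBVs by BLUP at common (fixed) variance components.

    Re-estimating variance components inside every scenario couples the
    EBV ranking contrasts to the Monte-Carlo noise of each chain; fixing
    the components (routinely at the complete-data estimates, as national
    evaluations fix them at reference values) makes the scenario EBVs
    deterministic, so contrasts against the complete data measure the
    information content of the censored/penalized records alone.

    Returns (ebv_matrix, animal_ids).
    """
    recs = trajectory_table(dataset.histories, trait)
    md = build_model_data(recs, dataset.histories, pedigree, k=k)
    sol = solve_blup(assemble_mme(md, vc, priors))
    return ebv_trajectories(md.T, sol.effect("animal")), md.animal_ids


def _derive_seed(base: int, *parts) -> int:
    import zlib
    ints = [zlib.crc32(str(p).encode()) for p in parts]
    return int(np.random.SeedSequence([base, *ints]).generate_state(1)[0] % (2**31))


def _split_population(histories, run: RunConfig, rng: np.random.Generator) -> dict:
    """Fixed cow pools shared by every replicate.

    D2 uses a fixed random subset of ``total_d2`` cows; D1 additionally
    fixes an uncensored pool of ``pool_d1`` cows inside it, with censored
    cows drawn from the remainder.
    """
    ids = np.array(sorted(h.cow for h in histories))
    need = {"D2_fixed_total": run.total_d2,
            "D1_fixed_uncensored": int(round(run.pool_d1 * 1.8))}
    biggest = max(need[d] for d in run.designs) if run.designs else 0
    if len(ids) < biggest:
        raise ConfigurationError(
            f"population has {len(ids)} cows; designs need {biggest} "
            f"(scale_factor {run.scale_factor})")
    pools = {}
    if "D2_fixed_total" in run.designs:
        pools["D2_fixed_total"] = frozenset(
            int(x) for x in rng.choice(ids, run.total_d2, replace=False))
    if "D1_fixed_uncensored" in run.designs:
        chosen = rng.choice(ids, need["D1_fixed_uncensored"], replace=False)
        pools["D1_fixed_uncensored"] = (
            frozenset(int(x) for x in chosen[:run.pool_d1]),       # uncensored pool
            frozenset(int(x) for x in chosen[run.pool_d1:]))       # censoring reservoir
    return pools


def run_study(run: RunConfig, progress: bool = False) -> dict:
    """Execute the grid and return {'results': [...], 'contrasts': DataFrame,
    'heritabilities': DataFrame, 'manifest': dict}.

    If ``run.out_dir`` is set, tables are written there and previously
    completed cells are loaded instead of refitted.
    """
    out = Path(run.out_dir) if run.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    ped, _effects, hist = simulate_population(run.sim)
    rng = np.random.default_rng(np.random.SeedSequence([run.base_seed, 7]))
    pools = _split_population(hist, run, rng)
    eval_year = int(max(h.birth_year for h in hist) + AGES[-1])
    by_id = {h.cow: h for h in hist}

    results, rows_h2, rows_contrast = [], [], []
    for design in run.designs:
        if design == "D1_fixed_uncensored":
            unc_pool, reservoir = pools[design]
            pool_ids, cen_source = unc_pool, reservoir
            base_count = len(unc_pool)
        else:
            pool_ids = pools[design]
            cen_source, base_count = pool_ids, len(pool_ids)
        cows = [by_id[c] for c in sorted(pool_ids | frozenset(cen_source))]

        for rep in range(1, run.n_replicates + 1):
            assignment = assign_censoring(
                sorted(cen_source), seed=_derive_seed(run.base_seed, design, rep),
                base_count=base_count)
            com_spec = ScenarioSpec(design=design, level=0, treatment="COM",
                                    replicate=rep,
                                    reference_age_source=run.reference_age_source)
            com_ds = build_design(cows, assignment, com_spec, pool_ids, eval_year)
            specs = [ScenarioSpec(design=design, level=lvl, treatment=tr,
                                  replicate=rep,
                                  reference_age_source=run.reference_age_source)
                     for tr in run.treatments for lvl in run.levels]
            for trait in run.traits:
                com_res = _fit_cached(com_ds, trait, ped, run, out)
                results.append(com_res)
                rows_h2.extend(_h2_rows(com_res))
                for spec in specs:
                    ds = build_design(cows, assignment, spec, pool_ids, eval_year)
                    res = _fit_cached(ds, trait, ped, run, out)
                    results.append(res)
                    rows_h2.extend(_h2_rows(res))
                    rows_contrast.extend(_contrast_rows(com_res, res, run))
                    if progress:
                        print(f"  done {trait} {spec.name}", flush=True)

    contrasts = pd.DataFrame(rows_contrast)
    h2_table = pd.DataFrame(rows_h2)
    manifest = {"n_cows": len(hist), "n_animals": ped.n,
                "evaluation_year": eval_year,
                "designs": list(run.designs), "levels": list(run.levels),
                "treatments": list(run.treatments),
                "n_replicates": run.n_replicates,
                "chain": vars(run.chain), "scale_factor": run.scale_factor,
                "base_seed": run.base_seed}
    if out:
        contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        h2_table.to_csv(out / "heritabilities.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"results": results, "contrasts": contrasts,
            "heritabilities": h2_table, "manifest": manifest}


def _cell_key(spec: ScenarioSpec, trait: str) -> str:
    return f"{trait}_{spec.name}"


def _fit_cached(dataset, trait, ped, run: RunConfig, out: Optional[Path]) -> ScenarioResult:
    key = _cell_key(dataset.spec, trait)
    cache = (out / f"cell_{key}.npz") if out else None
    if cache and cache.exists():
        return _load_cell(cache, dataset, trait)
    seed = _derive_seed(run.base_seed, "chain", trait, dataset.spec.name)
    res = fit_scenario(dataset, trait, ped, run, chain_seed=seed)
    if cache:
        _save_cell(cache, res)
    return res


def _save_cell(path: Path, res: ScenarioResult) -> None:
    np.savez(path, ebv=res.ebv, animal_ids=res.animal_ids,
             h2=res.heritability.h2, sigma2_a=res.heritability.sigma2_a,
             sigma2_q=res.heritability.sigma2_q, sigma2_p=res.heritability.sigma2_p,
             sigma2_e=res.heritability.sigma2_e,
             censored_ids=np.array(sorted(res.censored_ids), dtype=np.int64),
             seconds=res.seconds)


def _load_cell(path: Path, dataset, trait) -> ScenarioResult:
    from .genetic_parameters import HeritabilityTrajectory
    z = np.load(path)
    h2 = HeritabilityTrajectory(ages=AGES.copy(), h2=z["h2"],
                                sigma2_a=z["sigma2_a"], sigma2_q=z["sigma2_q"],
                                sigma2_p=z["sigma2_p"], sigma2_e=float(z["sigma2_e"]))
    return ScenarioResult(spec=dataset.spec, trait=trait, heritability=h2,
                          ebv=z["ebv"], animal_ids=z["animal_ids"],
                          censored_ids=frozenset(int(x) for x in z["censored_ids"]),
                          vc_mean=None, manifest=dataset.manifest,
                          seconds=float(z["seconds"]))


def _h2_rows(res: ScenarioResult) -> list:
    return [{"trait": res.trait, "scenario": res.spec.name,
             "design": res.spec.design, "level": res.spec.level,
             "treatment": res.spec.treatment, "replicate": res.spec.replicate,
             "age": int(a), "h2": float(h), "sigma2_a": float(sa)}
            for a, h, sa in zip(res.heritability.ages, res.heritability.h2,
                                res.heritability.sigma2_a)]


def _contrast_rows(com: ScenarioResult, res: ScenarioResult, run: RunConfig) -> list:
    rows = []
    base = {"trait": res.trait, "scenario": res.spec.name,
            "design": res.spec.design, "level": res.spec.level,
            "treatment": res.spec.treatment, "replicate": res.spec.replicate}
    for frac in run.top_fractions:
        ov = overlap_by_age(com.ebv, res.ebv, frac)
        for age, v in zip(AGES, ov):
            rows.append({**base, "metric": f"top{int(frac * 100)}_overlap",
                         "age": int(age), "value": float(v)})
        rows.append({**base, "metric": f"top{int(frac * 100)}_overlap_mean",
                     "age": -1, "value": float(ov.mean())})
    rows.append({**base, "metric": "ebv_corr_all", "age": -1,
                 "value": ebv_correlation(com.ebv, res.ebv, "all")})
    for scope in ("age_censored", "age_uncensored"):
        try:
            v = ebv_correlation(com.ebv, res.ebv, scope, age=run.contrast_age,
                                censored_ids=res.censored_ids,
                                animal_ids=res.animal_ids)
        except ValueError:
            v = np.nan
        rows.append({**base, "metric": f"ebv_corr_{scope}",
                     "age": run.contrast_age, "value": v})
    return rows


def aggregate_contrasts(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Replicate means/SD/SE per (trait, design, level, treatment, metric, age)."""
    rows = []
    keys = ["trait", "design", "level", "treatment", "metric", "age"]
    for key, grp in contrasts.groupby(keys):
        s = replicate_aggregate(grp["value"].dropna())
        rows.append({**dict(zip(keys, key)), "mean": s.mean, "sd": s.sd,
                     "se": s.se, "n": s.n})
    return pd.DataFrame(rows)
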