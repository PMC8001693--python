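import dataclasses

import numpy as np
import pytest

from longevity_rrm.datatypes import ConfigurationError, SimConfig
from longevity_rrm.synthetic_data import (apply_quality_control,
                                          simulate_cow_histories,
                                          simulate_genetic_effects,
                                          simulate_pedigree)

from conftest import make_history


def small_config(**kw):
    defaults = dict(n_base_animals=80, n_generations=2, n_cows_target=30,
                    n_herds=3, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPedigree:
    def test_founders_only_have_unknown_parents(self):
        ped = simulate_pedigree(small_config(n_generations=0))
        assert (ped.sire == 0).all() and (ped.dam == 0).all()

    def test_no_animal_is_its_own_ancestor(self):
        ped = simulate_pedigree(small_config())
        # topological ordering (parents have smaller ids) implies acyclicity;
        # walk ancestors explicitly as a belt-and-braces check
        sire, dam = ped.sire, ped.dam
        for i in range(1, ped.n + 1):
            stack, seen = [i], set()
            while stack:
                j = stack.pop()
                for par in (sire[j - 1], dam[j - 1]):
                    if par == i:
                        pytest.fail(f"animal {i} is its own ancestor")
                    if par != 0 and par not in seen:
                        seen.add(par)
                        stack.append(par)

    def test_fixed_seed_reproduces_identical_pedigree(self):
        cfg = small_config()
        assert simulate_pedigree(cfg) == simulate_pedigree(small_config())

    def test_impossible_configuration_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_pedigree(small_config(n_cows_target=10_000))

    def test_nonfounder_parents_precede_offspring(self):
        ped = simulate_pedigree(small_config())
        nonfounder = ped.table["sire"] != 0
        assert (ped.sire[nonfounder] < ped.table["id"][nonfounder]).all()


class TestGeneticEffects:
    def test_founder_covariance_matches_g0(self):
        # Monte-Carlo moment check: founders only, empirical covariance of a_i
        cfg = small_config(n_base_animals=10_000, n_generations=0,
                           n_cows_target=100, k_coefficients=2,
                           G0_true=np.eye(2), Rq_true=np.eye(2),
                           Rp_true=np.eye(2))
        ped = simulate_pedigree(cfg)
        eff = simulate_genetic_effects(ped, cfg)
        emp = np.cov(eff.a.T)
        # var of a sample covariance entry of N(0, I): ~ (1+delta_ij)/n
        mc_se = np.sqrt((1 + np.eye(2)) / 10_000)
        assert np.all(np.abs(emp - np.eye(2)) < 3 * mc_se)

    def test_offspring_centered_at_parent_average(self):
        cfg = small_config()
        ped = simulate_pedigree(cfg)
        eff = simulate_genetic_effects(ped, cfg)
        tab = ped.table
        both = tab[(tab.sire != 0) & (tab.dam != 0)]
        dev = (eff.a[both.id - 1]
               - 0.5 * (eff.a[both.sire - 1] + eff.a[both.dam - 1]))
        # Mendelian deviations average to ~0 over many offspring
        se = dev.std(axis=0, ddof=1) / np.sqrt(len(both))
        assert np.all(np.abs(dev.mean(axis=0)) < 4 * se)

    def test_zero_g0_gives_zero_breeding_values(self):
        k = 5
        cfg = small_config(G0_true=np.zeros((k, k)))
        ped = simulate_pedigree(cfg)
        eff = simulate_genetic_effects(ped, cfg)
        assert np.all(eff.a == 0.0)

    def test_non_psd_covariance_rejected_before_sampling(self):
        bad = np.eye(5)
        bad[0, 0] = -1.0
        with pytest.raises(ConfigurationError):
            small_config(G0_true=bad)


class TestCowHistories:
    def test_high_baseline_no_noise_means_no_culling_before_15(self):
        cfg = small_config(sigma_e2_true=1e-12, et_shift=0.0,
                           G0_true=np.zeros((5, 5)), Rq_true=np.zeros((5, 5)),
                           Rp_true=np.zeros((5, 5)),
                           baseline_survival=np.ones(14))
        ped = simulate_pedigree(cfg)
        hist = simulate_cow_histories(ped, simulate_genetic_effects(ped, cfg), cfg)
        assert all(h.culling_age > 15 for h in hist)

    def test_zero_baseline_culls_every_cow_at_two(self):
        cfg = small_config(sigma_e2_true=1e-12, et_shift=0.0,
                           G0_true=np.zeros((5, 5)), Rq_true=np.zeros((5, 5)),
                           Rp_true=np.zeros((5, 5)),
                           baseline_survival=np.zeros(14))
        ped = simulate_pedigree(cfg)
        hist = simulate_cow_histories(ped, simulate_genetic_effects(ped, cfg), cfg)
        assert all(h.culling_age == 2 for h in hist)

    def test_no_skips_means_calving_every_year_in_production(self):
        cfg = small_config(calving_skip_prob=0.0)
        ped = simulate_pedigree(cfg)
        hist = simulate_cow_histories(ped, simulate_genetic_effects(ped, cfg), cfg)
        for h in hist:
            assert h.calving_ages == tuple(range(2, h.culling_age))

    def test_calvings_strictly_before_culling(self):
        cfg = small_config()
        ped = simulate_pedigree(cfg)
        hist = simulate_cow_histories(ped, simulate_genetic_effects(ped, cfg), cfg)
        assert all(max(h.calving_ages) < h.culling_age
                   for h in hist if h.calving_ages)

    def test_survival_monotone_in_baseline_under_common_random_numbers(self):
        cfg_lo = small_config()
        ped = simulate_pedigree(cfg_lo)
        eff = simulate_genetic_effects(ped, cfg_lo)
        cfg_hi = dataclasses.replace(
            cfg_lo, baseline_survival=cfg_lo.baseline_survival + 0.2)
        lo = simulate_cow_histories(ped, eff, cfg_lo)
        hi = simulate_cow_histories(ped, eff, cfg_hi)
        assert all(b.culling_age >= a.culling_age for a, b in zip(lo, hi))

    def test_determinism(self):
        cfg = small_config()
        ped = simulate_pedigree(cfg)
        eff = simulate_genetic_effects(ped, cfg)
        assert simulate_cow_histories(ped, eff, cfg) == \
            simulate_cow_histories(ped, eff, cfg)


class TestQualityControl:
    def test_first_calving_at_30_months_removed(self):
        kept = apply_quality_control([make_history(first_calving_months=30)])
        assert kept == []
        kept = apply_quality_control([make_history(first_calving_months=29)])
        assert len(kept) == 1

    def test_culling_age_boundary_20(self):
        h20 = make_history(cow=1, culling_age=20)
        h21 = make_history(cow=2, culling_age=21)
        kept, counts = apply_quality_control([h20, h21], return_counts=True)
        assert [h.cow for h in kept] == [1]
        assert counts["culling_age_over_20"] == 1

    def test_born_before_1990_removed(self):
        kept = apply_quality_control([make_history(birth_year=1989)])
        assert kept == []

    def test_compliant_cows_pass_through_unchanged(self):
        hs = [make_history(cow=i, culling_age=6) for i in (1, 2, 3)]
        assert apply_quality_control(hs) == hs
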