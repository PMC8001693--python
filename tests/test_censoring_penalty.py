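import numpy as np
import pytest

from longevity_rrm.censoring_penalty import (assign_censoring, build_design,
                                             censor_history, design_counts,
                                             penalize_history, reference_age)
from longevity_rrm.datatypes import ConfigurationError, ScenarioSpec

from conftest import make_history


class TestAssignment:
    def test_sizes_and_nesting_100_cows(self):
        a = assign_censoring(range(1, 101), seed=1)
        sizes = [len(a.censored_at(l)) for l in (20, 40, 60, 80)]
        assert sizes == [20, 40, 60, 80]
        assert a.censored_at(20) < a.censored_at(40) < a.censored_at(60) \
            < a.censored_at(80)

    def test_same_seed_identical(self):
        a = assign_censoring(range(50), seed=7)
        b = assign_censoring(range(50), seed=7)
        assert a.sets == b.sets

    def test_level_zero_empty(self):
        a = assign_censoring(range(1, 21), seed=0)
        assert a.censored_at(0) == frozenset()

    def test_too_few_cows(self):
        with pytest.raises(ConfigurationError):
            assign_censoring([1, 2, 3], seed=0)


class TestCensorPenalize:
    def test_censoring_removes_culling_keeps_calvings(self):
        h = censor_history(make_history(culling_age=8, calvings=tuple(range(2, 8))))
        assert h.culling_age is None
        assert h.calving_ages == tuple(range(2, 8))
        assert h.is_censored

    def test_censoring_twice_is_an_error(self):
        h = censor_history(make_history())
        with pytest.raises(ValueError):
            censor_history(h)

    def test_m1_imputes_one_year_after_last_calving(self):
        h = censor_history(make_history(culling_age=9, calvings=(2, 3, 6)))
        p = penalize_history(h, "m1", reference_age=12)
        assert p.culling_age == 7
        assert p.censoring_state == "penalized-m1"

    def test_m2_keeps_young_cows_censored(self):
        h = censor_history(make_history(culling_age=9, calvings=(2, 3, 6)))
        p = penalize_history(h, "m2", reference_age=8)
        assert p.is_censored and p.culling_age is None

    def test_m3_young_cow_two_years_after(self):
        h = censor_history(make_history(culling_age=9, calvings=(2, 3, 6)))
        p = penalize_history(h, "m3", reference_age=8)
        assert p.culling_age == 8

    @pytest.mark.parametrize("crit", ["m1", "m2", "m3"])
    def test_criteria_agree_for_cows_older_than_nine(self, crit):
        h = censor_history(make_history(culling_age=9, calvings=(2, 3, 6)))
        p = penalize_history(h, crit, reference_age=10)
        assert p.culling_age == 7

    def test_nine_exactly_counts_as_young(self):
        h = censor_history(make_history(culling_age=9, calvings=(2, 3, 6)))
        assert penalize_history(h, "m2", reference_age=9).is_censored

    def test_penalty_without_calving_anchor_is_an_error(self):
        h = censor_history(make_history(culling_age=2, calvings=()))
        with pytest.raises(ValueError):
            penalize_history(h, "m1", reference_age=12)

    def test_imputed_age_capped_at_20(self):
        h = censor_history(make_history(culling_age=20, calvings=tuple(range(2, 20))))
        p = penalize_history(h, "m1", reference_age=21)
        assert p.culling_age == 20

    def test_reference_age_sources(self):
        h = censor_history(make_history(birth_year=1995, calvings=(2, 3, 6)))
        assert reference_age(h, evaluation_year=2006) == 11
        assert reference_age(h, evaluation_year=2006, source="last_calving") == 6


class TestDesigns:
    def test_paper_scale_design1_totals(self):
        totals = [design_counts("D1_fixed_uncensored", l, 55_000)["total"]
                  for l in (0, 20, 40, 60, 80)]
        assert totals == [55_000, 66_000, 77_000, 88_000, 99_000]

    def test_paper_scale_design2_uncensored(self):
        unc = [design_counts("D2_fixed_total", l, 100_000)["uncensored"]
               for l in (0, 20, 40, 60, 80)]
        assert unc == [100_000, 80_000, 60_000, 40_000, 20_000]

    def _population(self, n=200):
        return [make_history(cow=i, culling_age=8, calvings=(2, 3, 4, 5))
                for i in range(1, n + 1)]

    def test_d2_construction_counts(self):
        cows = self._population(100)
        a = assign_censoring([h.cow for h in cows], seed=3)
        spec = ScenarioSpec("D2_fixed_total", 40, "CEN", replicate=1)
        ds = build_design(cows, a, spec, [h.cow for h in cows], evaluation_year=2005)
        assert len(ds.histories) == 100
        assert sum(h.is_censored for h in ds.histories) == 40

    def test_d1_construction_counts(self):
        cows = self._population(180)
        pool = [h.cow for h in cows[:100]]
        reservoir = [h.cow for h in cows[100:]]
        a = assign_censoring(reservoir, seed=3, base_count=100)
        spec = ScenarioSpec("D1_fixed_uncensored", 80, "CEN", replicate=1)
        ds = build_design(cows, a, spec, pool, evaluation_year=2005)
        assert len(ds.histories) == 180
        assert sum(h.is_censored for h in ds.histories) == 80

    def test_level_zero_is_complete_data(self):
        cows = self._population(50)
        a = assign_censoring([h.cow for h in cows], seed=3)
        spec = ScenarioSpec("D2_fixed_total", 0, "COM")
        ds = build_design(cows, a, spec, [h.cow for h in cows], evaluation_year=2005)
        assert all(not h.is_censored for h in ds.histories)
        assert len(ds.histories) == 50

    def test_penalized_dataset_has_no_unknown_culling_except_m2_young(self):
        cows = [make_history(cow=i, culling_age=8, calvings=(2, 3, 4, 5),
                             birth_year=2000 if i % 2 else 1992)
                for i in range(1, 101)]
        a = assign_censoring([h.cow for h in cows], seed=5)
        for crit, allow_missing in (("m1", False), ("m2", True), ("m3", False)):
            spec = ScenarioSpec("D2_fixed_total", 60, f"PEN{crit}")
            ds = build_design(cows, a, spec, [h.cow for h in cows],
                              evaluation_year=2005)
            missing = [h for h in ds.histories if h.culling_age is None]
            if allow_missing:
                assert all(2005 - h.birth_year <= 9 for h in missing)
            else:
                assert missing == []

    def test_m2_missing_superset_of_m3(self):
        cows = [make_history(cow=i, culling_age=8, calvings=(2, 3, 4, 5),
                             birth_year=2000 if i % 2 else 1992)
                for i in range(1, 101)]
        a = assign_censoring([h.cow for h in cows], seed=5)
        ids = [h.cow for h in cows]
        missing = {}
        for crit in ("m2", "m3"):
            spec = ScenarioSpec("D2_fixed_total", 60, f"PEN{crit}")
            ds = build_design(cows, a, spec, ids, evaluation_year=2005)
            missing[crit] = {h.cow for h in ds.histories if h.culling_age is None}
        assert missing["m3"] <= missing["m2"]
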