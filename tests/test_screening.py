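"""Bottleneck precision, multiplicity arithmetic, pair enumeration, cascade."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drugscreen.registry import (CancerSpec, DrugSpec, PlantedEffect,
                                 SimulationConfig, simulate_registry)
from drugscreen.case_control import EligibilityRules, find_cases, \
    sample_controls
from drugscreen.screening import (PairSpec, ScreenConfig, ScreeningResult,
                                  apply_cascade, bottleneck_ci,
                                  enumerate_pairs, expected_chance_positives,
                                  results_to_frame, round_ci_display,
                                  run_screen, sort_results)

from conftest import events_frame


class TestBottleneckCI:
    def test_25_cases_10_controls_prints_07_15(self):
        lo, hi = bottleneck_ci(25, 10)
        assert (lo, hi) == pytest.approx((0.6629, 1.5085), abs=5e-4)
        assert round_ci_display((lo, hi)) == (0.7, 1.5)

    def test_infinite_controls_one_cell_limit(self):
        lo, hi = bottleneck_ci(25, math.inf)
        assert hi == pytest.approx(math.exp(1.959963984540054 / 5), rel=1e-9)
        assert round_ci_display((lo, hi)) == (0.7, 1.5)

    def test_limit_of_many_cases_is_unity(self):
        lo, hi = bottleneck_ci(1e12, 10)
        assert lo == pytest.approx(1.0, abs=1e-5)
        assert hi == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("a,r", [(0, 10), (-5, 10), (25, 0), (25, -1)])
    def test_nonpositive_inputs_rejected(self, a, r):
        with pytest.raises(ValueError):
            bottleneck_ci(a, r)

    @given(st.integers(1, 10_000), st.integers(1, 100))
    def test_log_symmetry(self, a, r):
        lo, hi = bottleneck_ci(a, r)
        assert math.log(hi) == pytest.approx(-math.log(lo), rel=1e-12)


class TestChancePositives:
    @pytest.mark.parametrize("n,expected", [
        (13577, 680),   # the individual-drug pair count
        (8996, 450),    # the drug-class pair count
        (0, 0),
    ])
    def test_rounded_to_nearest_ten(self, n, expected):
        assert expected_chance_positives(n, 0.05) == expected

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            expected_chance_positives(100, alpha)

    def test_negative_tests_rejected(self):
        with pytest.raises(ValueError):
            expected_chance_positives(-1)


def sets_with_cases(n_cases, site="C50", hist="8500"):
    rows = []
    for i in range(n_cases):
        rows.append({"set_id": f"S{i:04d}", "role": "case",
                     "person_id": f"P{i:04d}",
                     "index_date": pd.Timestamp("2010-06-01"),
                     "site": site, "histology": hist})
        rows.append({"set_id": f"S{i:04d}", "role": "control",
                     "person_id": f"Q{i:04d}",
                     "index_date": pd.Timestamp("2010-06-01"),
                     "site": site, "histology": hist})
    return pd.DataFrame(rows)


def fills_for(person_ids, atc, n_fills, start_year=2000):
    out = []
    for p in person_ids:
        for k in range(n_fills):
            out.append((p, atc, f"{start_year + k // 12}-{k % 12 + 1:02d}-15"))
    return out


class TestEnumeratePairs:
    @pytest.mark.parametrize("n_high,expect_pair", [(24, False), (25, True)])
    def test_min_exposed_cases_boundary_inclusive(self, n_high, expect_pair):
        sets = sets_with_cases(30)
        exposed = [f"P{i:04d}" for i in range(n_high)]
        ev = events_frame(prescriptions=fills_for(exposed, "C07AB02", 8))
        pairs = enumerate_pairs(sets, ev, ScreenConfig(
            outcome_levels=("histology",)))
        assert bool(pairs) is expect_pair
        if pairs:
            assert pairs[0].n_exposed_cases == 25

    def test_level4_pools_sibling_substances(self):
        # 4 + 4 fills of two sibling level-5 codes: high only at level 4
        sets = sets_with_cases(25)
        people = [f"P{i:04d}" for i in range(25)]
        ev = events_frame(prescriptions=fills_for(people, "C07AB02", 4)
                          + fills_for(people, "C07AB03", 4, start_year=2003))
        assert enumerate_pairs(sets, ev, ScreenConfig(
            outcome_levels=("histology",))) == []
        pairs = enumerate_pairs(sets, ev, ScreenConfig(
            atc_level=4, outcome_levels=("histology",)))
        assert [p.atc for p in pairs] == ["C07AB"]

    def test_site_level_pools_histologies(self):
        sets = pd.concat([sets_with_cases(15, hist="8500"),
                          sets_with_cases(15, hist="8140")],
                         ignore_index=True)
        sets["set_id"] = [f"S{i:04d}" for i in range(len(sets) // 2)
                          for _ in (0, 1)]
        sets["person_id"] = [f"{r}{i:04d}" for i, r in
                             enumerate(sets["role"].map({"case": "P",
                                                         "control": "Q"}))]
        exposed = sets[sets["role"] == "case"]["person_id"]
        ev = events_frame(prescriptions=fills_for(exposed, "C07AB02", 9))
        hist_pairs = enumerate_pairs(sets, ev, ScreenConfig(
            outcome_levels=("histology",)))
        assert hist_pairs == []  # 15 + 15, neither histology reaches 25
        site_pairs = enumerate_pairs(sets, ev, ScreenConfig(
            outcome_levels=("site",)))
        assert len(site_pairs) == 1 and site_pairs[0].n_exposed_cases == 30

    def test_lag_excludes_recent_fills_from_counts(self):
        sets = sets_with_cases(25)
        people = [f"P{i:04d}" for i in range(25)]
        # all fills within 2 years of the 2010-06-01 index
        ev = events_frame(prescriptions=fills_for(people, "C07AB02", 8,
                                                  start_year=2009))
        assert enumerate_pairs(sets, ev, ScreenConfig(
            outcome_levels=("histology",))) == []


def make_result(n=30, ci_high=(1.3, 3.0), ci_doubling=(1.05, 1.6),
                ci_low=(0.8, 1.2)):
    return ScreeningResult(atc="C07AB02", site="C50", histology="8500",
                           n_exposed_cases=n, or_high=2.0, ci_high=ci_high,
                           or_low=1.0, ci_low=ci_low, or_doubling=1.3,
                           ci_doubling=ci_doubling, converged=True)


class TestCascadeFlags:
    CFG = ScreenConfig()

    def test_passing_result(self):
        r = apply_cascade(make_result(), self.CFG)
        assert r.passed_min_cases and r.passed_high_threshold
        assert r.passed_dose_threshold and r.low_use_neutral

    @pytest.mark.parametrize("n,passes", [(24, False), (25, True)])
    def test_bottleneck_boundary(self, n, passes):
        r = apply_cascade(make_result(n=n), self.CFG)
        assert r.passed_min_cases is passes
        assert r.passed_high_threshold is passes

    def test_high_threshold_strictly_above_125(self):
        at = apply_cascade(make_result(ci_high=(1.25, 3.0)), self.CFG)
        above = apply_cascade(make_result(ci_high=(1.2500001, 3.0)), self.CFG)
        assert not at.passed_high_threshold
        assert above.passed_high_threshold

    def test_dose_threshold_strictly_above_one(self):
        at = apply_cascade(make_result(ci_doubling=(1.0, 1.6)), self.CFG)
        above = apply_cascade(make_result(ci_doubling=(1.0000001, 1.6)),
                              self.CFG)
        assert not at.passed_dose_threshold
        assert above.passed_dose_threshold

    def test_stage2_requires_stage1(self):
        r = apply_cascade(make_result(ci_high=(1.1, 3.0),
                                      ci_doubling=(1.2, 1.6)), self.CFG)
        assert not r.passed_high_threshold
        assert not r.passed_dose_threshold

    def test_low_use_neutrality_annotation(self):
        neutral = apply_cascade(make_result(ci_low=(0.9, 1.1)), self.CFG)
        elevated = apply_cascade(make_result(ci_low=(1.2, 1.9)), self.CFG)
        assert neutral.low_use_neutral and not elevated.low_use_neutral

    def test_nonconverged_never_passes(self):
        r = apply_cascade(make_result(), self.CFG, cat_converged=False)
        assert not r.passed_high_threshold

    def test_monotone_subsets_in_any_result_list(self):
        rng = np.random.default_rng(8)
        results = []
        for _ in range(200):
            lo_h = float(rng.uniform(0.8, 2.0))
            lo_d = float(rng.uniform(0.8, 1.3))
            results.append(apply_cascade(
                make_result(n=int(rng.integers(10, 60)),
                            ci_high=(lo_h, lo_h * 2),
                            ci_doubling=(lo_d, lo_d * 1.5)), self.CFG))
        s0 = {id(r) for r in results if r.passed_min_cases}
        s1 = {id(r) for r in results if r.passed_high_threshold}
        s2 = {id(r) for r in results if r.passed_dose_threshold}
        assert s2 <= s1 <= s0
        assert len(s0) > len(s1) > len(s2) > 0


class TestSortResults:
    def test_tie_breaks_deterministic(self):
        a = make_result(); a.or_high = 2.0; a.atc = "B01AA01"; a.site = "C50"
        b = make_result(); b.or_high = 2.0; b.atc = "A10BA02"; b.site = "C61"
        c = make_result(); c.or_high = 3.0; c.atc = "Z99ZZ99"
        d = make_result(); d.or_high = math.nan
        out = sort_results([a, b, c, d])
        assert [r.atc for r in out] == ["Z99ZZ99", "A10BA02", "B01AA01",
                                        d.atc]
        # order of input must not matter
        out2 = sort_results([d, b, a, c])
        assert [(r.atc, r.or_high) for r in out] == \
            [(r.atc, r.or_high) for r in out2]


class TestConfoundingBias:
    def test_confounder_linked_drug_inflates_or(self):
        """Confounding by indication biases the null drug upward, which is
        why the cascade output still needs manual review."""
        logs = []
        for seed in (21, 22, 23):
            cfg = SimulationConfig(
                n_persons=6000, age_range=(45.0, 80.0),
                confounder_strength=1.2,
                drug_specs=[DrugSpec("N05BA02", prescribing_hazard=0.03,
                                     mean_fills=12.0, confounder_linked=True)],
                cancer_specs=[CancerSpec("C34", "8046", baseline_hazard=0.002,
                                         age_slope=0.04,
                                         confounder_coef=0.8)],
                rng_seed=seed)
            persons, events, _ = simulate_registry(cfg)
            rules = EligibilityRules()
            cases = find_cases(persons, events, rules)
            sets = sample_controls(cases, persons, events, rules,
                                   rng_seed=seed)
            results = run_screen(persons, events, sets, ScreenConfig(
                min_exposed_cases=10, outcome_levels=("histology",)))
            logs += [math.log(r.or_high) for r in results
                     if math.isfinite(r.or_high)]
        assert len(logs) >= 2
        assert np.mean(logs) > 0


class TestScreenEndToEnd:
    def test_planted_pair_passes_and_nulls_mostly_do_not(self):
        cfg = SimulationConfig(
            n_persons=9000, age_range=(45.0, 80.0),
            drug_specs=[
                DrugSpec("A10BA02", prescribing_hazard=0.04, mean_fills=14.0),
                DrugSpec("C07AB02", prescribing_hazard=0.04, mean_fills=14.0),
                DrugSpec("M01AE01", prescribing_hazard=0.04, mean_fills=14.0),
            ],
            cancer_specs=[CancerSpec(
                "C50", "8500", baseline_hazard=0.002, age_slope=0.04,
                planted_effects={"A10BA02": PlantedEffect(
                    rr_high_use=4.0, rr_per_doubling=1.6, mode="doubling")})],
            rng_seed=424242)
        persons, events, _ = simulate_registry(cfg)
        rules = EligibilityRules()
        cases = find_cases(persons, events, rules)
        sets = sample_controls(cases, persons, events, rules, rng_seed=1)
        results = run_screen(persons, events, sets,
                             ScreenConfig(outcome_levels=("histology",)))
        by_atc = {r.atc: r for r in results}
        assert by_atc["A10BA02"].passed_dose_threshold
        # cascade monotonicity on the real output
        for r in results:
            if r.passed_dose_threshold:
                assert r.passed_high_threshold
            if r.passed_high_threshold:
                assert r.passed_min_cases

    def test_empty_drug_list_gives_empty_screen(self):
        sets = sets_with_cases(5)
        ev = events_frame()
        assert run_screen(pd.DataFrame({"person_id": [], "education": []}),
                          ev, sets, ScreenConfig()) == []

    def test_results_frame_columns(self):
        frame = results_to_frame([make_result()])
        assert {"atc", "site", "histology", "n_exposed_cases", "or_high",
                "passed_dose_threshold", "low_use_neutral"} <= set(frame)
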