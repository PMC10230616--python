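"""Cumulative incidence estimators, prevalence/RR and comorbidity curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

import liabreg as lr
from liabreg.incidence import incidence_from_arrays


def _five_person_arrays():
    # events at ages 20, 30; censored at 25, 35, 49; entry at 10
    entry = np.full(5, 10.0)
    exit_age = np.array([49.0, 25.0, 49.0, 35.0, 49.0])
    event = np.array([20.0, np.nan, 30.0, np.nan, np.nan])
    return entry, exit_age, event


class TestEstimators:
    def test_hand_worked_km(self):
        entry, exit_age, event = _five_person_arrays()
        curve = incidence_from_arrays(entry, exit_age, event,
                                      estimator="one_minus_km",
                                      age_grid=np.arange(10, 50))
        assert curve.at(49) == pytest.approx(7 / 15, abs=1e-12)

    def test_aj_equals_km_without_competing_events(self):
        entry, exit_age, event = _five_person_arrays()
        km = incidence_from_arrays(entry, exit_age, event,
                                   estimator="one_minus_km")
        aj = incidence_from_arrays(entry, exit_age, event,
                                   estimator="aalen_johansen")
        np.testing.assert_allclose(aj.estimate, km.estimate, atol=1e-15)

    def test_aj_below_km_with_competing_deaths(self):
        rng = np.random.default_rng(3)
        n = 4000
        entry = np.full(n, 10.0)
        exit_age = np.full(n, 49.0)
        event = np.where(rng.random(n) < 0.3, rng.uniform(10, 49, n), np.nan)
        death = np.where(rng.random(n) < 0.3, rng.uniform(10, 49, n), np.nan)
        km = incidence_from_arrays(entry, exit_age, event, death,
                                   estimator="one_minus_km")
        aj = incidence_from_arrays(entry, exit_age, event, death,
                                   estimator="aalen_johansen")
        assert (aj.estimate <= km.estimate + 1e-12).all()
        assert aj.estimate[-1] < km.estimate[-1]

    def test_no_censoring_reduces_to_empirical_cdf(self):
        rng = np.random.default_rng(4)
        n = 500
        event = np.where(rng.random(n) < 0.4, rng.uniform(11, 48, n), np.nan)
        entry = np.full(n, 10.0)
        exit_age = np.full(n, 49.0)
        expected = np.isfinite(np.nan_to_num(event, nan=np.inf)).sum() / n
        for est in ("one_minus_km", "aalen_johansen"):
            curve = incidence_from_arrays(entry, exit_age, event, estimator=est)
            assert curve.at(49) == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines_with_left_truncation(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 1500
        entry = rng.uniform(10, 20, n)
        exit_age = rng.uniform(25, 49, n)
        event = np.where(rng.random(n) < 0.4, rng.uniform(10.5, 49, n), np.nan)
        curve = incidence_from_arrays(entry, exit_age, event,
                                      estimator="one_minus_km",
                                      age_grid=np.arange(10, 50))
        time = np.fmin(np.nan_to_num(event, nan=np.inf), exit_age)
        obs = np.nan_to_num(event, nan=np.inf) <= exit_age
        keep = time > entry
        kmf = lifelines.KaplanMeierFitter().fit(time[keep], obs[keep],
                                                entry=entry[keep])
        for age in (20, 30, 40, 49):
            oracle = 1 - kmf.survival_function_at_times(float(age)).iloc[0]
            assert curve.at(age) == pytest.approx(oracle, abs=1e-10)

    def test_curve_invariants(self, sim_cohort):
        for est in ("one_minus_km", "aalen_johansen"):
            c = lr.cumulative_incidence(sim_cohort, estimator=est)
            assert (np.diff(c.estimate) >= -1e-12).all()
            assert ((c.estimate >= 0) & (c.estimate <= 1)).all()
            assert (c.lower <= c.estimate + 1e-12).all()
            assert (c.upper >= c.estimate - 1e-12).all()

    def test_risk_set_bookkeeping(self, sim_cohort):
        m = sim_cohort.members
        c = lr.cumulative_incidence(sim_cohort, estimator="one_minus_km")
        entry = m["entry_age"].to_numpy()
        time = np.fmin(np.nan_to_num(m["first_mdd_age"].to_numpy(), nan=np.inf),
                       m["exit_age"].to_numpy())
        death_age = (m["death_year"] - (m["birth_year"] + 0.5)).to_numpy()
        time = np.fmin(time, np.nan_to_num(death_age, nan=np.inf))
        keep = time > entry
        for age in (15.0, 25.0, 40.0):
            manual = int(np.sum((entry[keep] <= age) & (time[keep] > age)))
            idx = int(np.flatnonzero(c.ages == age)[0])
            assert c.n_risk[idx] == manual

    def test_all_censored_returns_zero_curve_with_warning(self):
        with pytest.warns(UserWarning, match="all-censored"):
            curve = incidence_from_arrays(np.full(4, 10.0), np.full(4, 30.0),
                                          estimator="one_minus_km")
        assert (curve.estimate == 0).all()

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            incidence_from_arrays(np.array([]), np.array([]))


class TestPrevalenceAndRR:
    def test_rr_simple_ratios(self, code_map):
        from conftest import make_bundle
        SO = "specialist_outpatient"
        persons = [(i, "F" if i <= 10 else "M", 1980, None, None,
                    np.nan, np.nan, True, "") for i in range(1, 21)]
        # 2/10 females and 1/10 males diagnosed -> RR 2.0
        diagnoses = [(1, 2000.5, 10, "F32.1", SO), (2, 2001.5, 10, "F32.1", SO),
                     (11, 2000.5, 10, "F32.1", SO)]
        bundle = make_bundle(persons, diagnoses)
        cohort = lr.select_cohort(bundle, lr.CohortSpec(), code_map,
                                  register_window=(1975, 2013))
        _, rr = lr.lifetime_prevalence_and_rr(cohort, bundle.diagnoses, code_map,
                                              disorders=["mdd"])
        assert rr["mdd"][0] == pytest.approx(2.0)

    def test_rr_recovers_generator_ratio(self, code_map):
        cfg = lr.broad_preset(n_families=60000, seed=20, female_male_rr=1.7,
                              treatment=None, comorbidities={})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0),
                                  code_map)
        _, rr = lr.lifetime_prevalence_and_rr(cohort, b.diagnoses, code_map,
                                              disorders=["mdd"])
        assert rr["mdd"][0] == pytest.approx(1.7, abs=0.1)

    def test_prevalence_table_consistency(self, sim_cohort, sim_bundle, code_map):
        table, _ = lr.lifetime_prevalence_and_rr(sim_cohort, sim_bundle.diagnoses,
                                                 code_map)
        assert (table["diagnosed"] <= table["population"]).all()
        nonzero = table[table["population"] > 0]
        np.testing.assert_allclose(
            nonzero["proportion"],
            nonzero["diagnosed"] / nonzero["population"])


class TestChiSquared:
    @pytest.mark.parametrize("counts,expected_stat,expected_df", [
        ([(30, 100), (10, 100)], 12.5, 1),           # hand formula n(ad-bc)^2/...
        ([(20, 100), (20, 100)], 0.0, 1),
        ([(10, 50), (10, 50), (10, 50)], 0.0, 2),
    ])
    def test_known_tables(self, counts, expected_stat, expected_df):
        res = lr.prevalence_difference_test(counts)
        assert res.statistic == pytest.approx(expected_stat, abs=1e-10)
        assert res.df == expected_df

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            lr.prevalence_difference_test([(5, 0)])


class TestComorbidity:
    def test_counting_fixture(self, code_map):
        from conftest import make_bundle
        SO = "specialist_outpatient"
        # 4 ADHD cases, 1 of whom later develops MDD, none censored before 49
        persons = [(i, "F", 1964 + i, None, None, np.nan, np.nan, True, "")
                   for i in range(1, 5)]
        diagnoses = [(i, 1964 + i + 12.5, 10, "F90.0", SO) for i in range(1, 5)]
        diagnoses.append((1, 1990.0, 10, "F32.1", SO))
        bundle = make_bundle(persons, diagnoses)
        cohort = lr.select_cohort(bundle, lr.CohortSpec(
            min_followup_after_first_dx=0), code_map,
            register_window=(1975, 2030))
        curves = lr.comorbidity_trajectories(cohort, bundle.diagnoses, code_map,
                                             other_disorders=["adhd"],
                                             direction="before")
        assert curves["adhd"].at(49) == pytest.approx(0.25, abs=1e-12)

    def test_uncorrelated_comorbidity_matches_population_incidence(self, code_map):
        cfg = lr.broad_preset(
            n_families=50000, seed=21, treatment=None,
            annual_mortality_hazard=0.0, annual_emigration_hazard=0.0,
            suicide_prob=0.0, register_window=(1975, 2060),
            comorbidities={"anxiety": lr.Comorbidity(0.10, 0.0)})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0,
                                                   require_born_in_country=False),
                                  code_map)
        curves = lr.comorbidity_trajectories(cohort, b.diagnoses, code_map,
                                             other_disorders=["anxiety"],
                                             direction="before")
        pop = lr.cumulative_incidence(cohort, estimator="one_minus_km")
        # conditioning on an uncorrelated disorder leaves MDD incidence unchanged
        ratio = curves["anxiety"].at(49) / pop.at(49)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_empty_stratum_flagged(self, six_person_bundle, code_map):
        cohort = lr.select_cohort(six_person_bundle, lr.CohortSpec(), code_map)
        with pytest.warns(UserWarning, match="empty stratum"):
            curves = lr.comorbidity_trajectories(cohort, six_person_bundle.diagnoses,
                                                 code_map,
                                                 other_disorders=["eating"],
                                                 direction="before")
        assert (curves["eating"].estimate == 0).all()

    def test_index_equals_outcome_rejected(self, sim_cohort, sim_bundle, code_map):
        with pytest.raises(ValueError, match="must differ"):
            lr.comorbidity_trajectories(sim_cohort, sim_bundle.diagnoses,
                                        code_map, index_disorder="mdd",
                                        other_disorders=["mdd"])
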