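"""Liability thresholds, Falconer conversion, orthant kernel and the ACE fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

import liabreg as lr
from liabreg.heritability import _make_design, ace_negloglik


class TestBuildSibPairs:
    def _cohort(self, persons, code_map):
        from conftest import make_bundle
        bundle = make_bundle(persons)
        return lr.select_cohort(bundle, lr.CohortSpec(
            min_followup_after_first_dx=0), code_map,
            register_window=(1975, 2030))

    def test_three_full_siblings_give_three_pairs(self, code_map):
        persons = [
            (1, "F", 1950, None, None, np.nan, np.nan, True, ""),
            (2, "M", 1950, None, None, np.nan, np.nan, True, ""),
            (10, "F", 1980, 1, 2, np.nan, np.nan, True, ""),
            (11, "M", 1982, 1, 2, np.nan, np.nan, True, ""),
            (12, "F", 1984, 1, 2, np.nan, np.nan, True, ""),
        ]
        cohort = self._cohort(persons, code_map)
        pairs = lr.build_sib_pairs(cohort)
        assert len(pairs) == 3
        assert (pairs["relation"] == "full").all()
        assert (pairs["a_R"] == 0.5).all()

    def test_blended_sibship_pair_enumeration(self, code_map):
        # mother with 2 children by father A and 1 by father B
        persons = [
            (1, "F", 1950, None, None, np.nan, np.nan, True, ""),
            (2, "M", 1950, None, None, np.nan, np.nan, True, ""),
            (3, "M", 1952, None, None, np.nan, np.nan, True, ""),
            (10, "F", 1980, 1, 2, np.nan, np.nan, True, ""),
            (11, "M", 1982, 1, 2, np.nan, np.nan, True, ""),
            (12, "F", 1985, 1, 3, np.nan, np.nan, True, ""),
        ]
        pairs = lr.build_sib_pairs(self._cohort(persons, code_map))
        assert (pairs["relation"] == "full").sum() == 1
        assert (pairs["relation"] == "maternal_half").sum() == 2

    def test_only_children_give_empty_set(self, code_map):
        persons = [
            (1, "F", 1950, None, None, np.nan, np.nan, True, ""),
            (2, "M", 1950, None, None, np.nan, np.nan, True, ""),
            (10, "F", 1980, 1, 2, np.nan, np.nan, True, ""),
        ]
        pairs = lr.build_sib_pairs(self._cohort(persons, code_map))
        assert len(pairs) == 0


class TestLiabilityThreshold:
    def test_symmetric_half(self):
        t, i = lr.liability_threshold(0.5)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert i == pytest.approx(2 * stats.norm.pdf(0), rel=1e-12)

    @pytest.mark.parametrize("K,t_expected,i_expected", [
        (0.072, 1.4611, 1.9061),   # inverse-normal oracle values
        (0.048, 1.6646, 2.0797),
    ])
    def test_inverse_normal_oracle(self, K, t_expected, i_expected):
        t, i = lr.liability_threshold(K)
        assert t == pytest.approx(t_expected, abs=5e-4)
        assert i == pytest.approx(i_expected, abs=5e-4)

    def test_invalid_K(self):
        for K in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                lr.liability_threshold(K)


class TestFalconer:
    def test_equal_risks_give_zero(self):
        for variant in ("falconer", "reich"):
            comp = lr.falconer_h2(0.072, 0.072, 0.5, variant)
            assert comp.h2 == pytest.approx(0.0, abs=1e-12)

    def test_doubled_sibling_risk(self):
        comp = lr.falconer_h2(0.072, 0.144, 0.5, "falconer")
        assert comp.h2 == pytest.approx(0.418, abs=2e-3)

    def test_linearity_in_relatedness(self):
        for variant in ("falconer", "reich"):
            h_half = lr.falconer_h2(0.072, 0.144, 0.25, variant).h2
            h_full = lr.falconer_h2(0.072, 0.144, 0.5, variant).h2
            assert h_half == pytest.approx(2 * h_full, rel=1e-12)

    def test_monotone_in_relative_risk(self):
        values = [lr.falconer_h2(0.072, k, 0.5).h2
                  for k in (0.08, 0.10, 0.14, 0.20)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_degenerate_relative_stratum_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lr.falconer_h2(0.072, 0.0, 0.5)

    def test_delta_method_se_present(self):
        comp = lr.falconer_h2(0.072, 0.144, 0.5,
                              K_pop_ci=(0.070, 0.074), K_rel_ci=(0.138, 0.150))
        assert comp.se is not None and comp.se > 0


class TestWeightedMean:
    def test_single_stratum_identity(self):
        comp = lr.falconer_h2(0.072, 0.144, 0.5,
                              K_pop_ci=(0.070, 0.074), K_rel_ci=(0.138, 0.150))
        pooled, se = lr.weighted_mean_h2([comp])
        assert pooled == pytest.approx(comp.h2)
        assert se == pytest.approx(comp.se)

    def test_equal_se_strata_average(self):
        a = lr.FalconerComponent(0.40, 0.02, 0.072, 0.14, 0.5, "falconer")
        b = lr.FalconerComponent(0.48, 0.02, 0.072, 0.15, 0.5, "falconer")
        pooled, _ = lr.weighted_mean_h2([a, b])
        assert pooled == pytest.approx(0.44)

    def test_inverse_variance_arithmetic(self):
        a = lr.FalconerComponent(0.40, 0.02, 0.072, 0.14, 0.5, "falconer")
        b = lr.FalconerComponent(0.48, 0.04, 0.072, 0.15, 0.5, "falconer")
        pooled, se = lr.weighted_mean_h2([a, b])
        assert pooled == pytest.approx(0.416)
        assert se == pytest.approx(np.sqrt(1 / (1 / 0.02**2 + 1 / 0.04**2)))

    def test_sample_size_weighting(self):
        a = lr.FalconerComponent(0.40, 0.02, 0.072, 0.14, 0.5, "falconer")
        b = lr.FalconerComponent(0.48, 0.04, 0.072, 0.15, 0.5, "falconer")
        pooled, _ = lr.weighted_mean_h2([a, b], weighting="sample_size",
                                        sizes=[300, 100])
        assert pooled == pytest.approx(0.42)


class TestBvnOrthant:
    def test_independence(self):
        for t1, t2 in ((0.3, -0.7), (1.5, 1.5), (-2.0, 0.0)):
            expected = ndtr(-t1) * ndtr(-t2)
            assert lr.bvn_orthant(t1, t2, 0.0) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_zero_threshold_closed_form(self):
        for r in np.arange(-0.9, 0.95, 0.1):
            expected = 0.25 + np.arcsin(r) / (2 * np.pi)
            assert lr.bvn_orthant(0.0, 0.0, float(r)) == pytest.approx(
                expected, abs=1e-9)

    def test_comonotone_limits(self):
        for t in (-1.0, 0.5, 2.0):
            assert lr.bvn_orthant(t, t, 1.0) == pytest.approx(ndtr(-t), abs=1e-14)
        assert lr.bvn_orthant(0.0, 0.0, -1.0) == pytest.approx(0.0, abs=1e-14)

    def test_against_scipy_mvn_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            t1, t2 = rng.uniform(-2.5, 2.5, 2)
            r = rng.uniform(-0.95, 0.95)
            oracle = stats.multivariate_normal(
                mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([-t1, -t2])
            assert lr.bvn_orthant(t1, t2, r) == pytest.approx(oracle, abs=1e-7)

    def test_monotone_in_correlation(self):
        vals = [lr.bvn_orthant(1.0, 1.2, r) for r in (-0.5, 0.0, 0.4, 0.8)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            lr.bvn_orthant(0.0, 0.0, 1.5)


def _toy_pairs(n=10, seed=9):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "person_a": np.arange(n), "person_b": np.arange(n) + 1000,
        "relation": rng.choice(["full", "maternal_half"], n),
        "case_a": rng.random(n) < 0.3, "case_b": rng.random(n) < 0.3,
        "sex_a": rng.choice(["F", "M"], n), "sex_b": rng.choice(["F", "M"], n),
        "by_a": rng.integers(1965, 2000, n).astype(float),
        "by_b": rng.integers(1965, 2000, n).astype(float),
    })


class TestAceLikelihood:
    def test_independence_oracle_at_null(self):
        pairs = _toy_pairs()
        design = _make_design(pairs)
        theta = np.array([0.0, 0.0, 1.2, 0.3, -0.1, 0.05])
        got = ace_negloglik(theta, design)
        # at h2=c2=0 the pair likelihood factorises into Bernoulli terms
        _, _, tau, bs, b1, b2 = theta
        manual = 0.0
        for which in ("a", "b"):
            t = tau - (bs * design[f"sex_{which}"] + b1 * design[f"by_{which}"]
                       + b2 * design[f"by2_{which}"])
            p = ndtr(-t)
            case = design[f"case_{which}"]
            manual -= np.sum(design["w"] * np.where(case, np.log(p),
                                                    np.log(1 - p)))
        assert got == pytest.approx(manual, abs=1e-10)

    def test_pair_order_invariance(self):
        pairs = _toy_pairs(50, seed=10)
        swapped = pairs.rename(columns={
            "person_a": "person_b", "person_b": "person_a",
            "case_a": "case_b", "case_b": "case_a",
            "sex_a": "sex_b", "sex_b": "sex_a",
            "by_a": "by_b", "by_b": "by_a"})
        theta = np.array([0.35, 0.1, 1.4, 0.25, -0.05, 0.02])
        assert ace_negloglik(theta, _make_design(pairs)) == pytest.approx(
            ace_negloglik(theta, _make_design(swapped)), rel=1e-12)

    def test_null_data_recovers_null(self, code_map):
        cfg = lr.simulate_sib_pairs_config(
            30000, 12000, base=lr.broad_preset(), a2=0.0, c2=0.0,
            lifetime_risk_by_49=0.2, seed=12, annual_mortality_hazard=0.0,
            annual_emigration_hazard=0.0, suicide_prob=0.0,
            register_window=(1975, 2060), treatment=None, comorbidities={})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0,
                                                   require_born_in_country=False),
                                  code_map)
        est = lr.fit_ace(lr.build_sib_pairs(cohort), compute_se=False)
        assert est.h2 < 0.05 and est.c2 < 0.05

    def test_familial_data_beats_null(self, code_map):
        cfg = lr.simulate_sib_pairs_config(
            30000, 12000, base=lr.broad_preset(), a2=0.8, c2=0.0,
            lifetime_risk_by_49=0.2, seed=13, annual_mortality_hazard=0.0,
            annual_emigration_hazard=0.0, suicide_prob=0.0,
            register_window=(1975, 2060), treatment=None, comorbidities={})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0,
                                                   require_born_in_country=False),
                                  code_map)
        est = lr.fit_ace(lr.build_sib_pairs(cohort), compute_se=False)
        assert est.h2 > 0.5
        assert est.e2 == pytest.approx(1 - est.h2 - est.c2)

    def test_single_relation_warns_nonidentifiable(self):
        pairs = _toy_pairs(20, seed=14)
        pairs["relation"] = "full"
        with pytest.warns(UserWarning, match="not separately identifiable"):
            lr.fit_ace(pairs, compute_se=False)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            lr.fit_ace(_toy_pairs(0))


class TestStratifiedRisks:
    def test_half_sib_environment_shift_raises_baseline_incidence(self, code_map):
        # an additive liability shift in half-sibships elevates the baseline
        # (no affected sibling) risk of maternal half-siblings above that of
        # full siblings, the anomaly register data can show
        cfg = lr.simulate_sib_pairs_config(
            40000, 40000, base=lr.broad_preset(), a2=0.45, c2=0.05,
            lifetime_risk_by_49=0.072, half_sib_env_shift=0.3, seed=16,
            annual_mortality_hazard=0.0, annual_emigration_hazard=0.0,
            suicide_prob=0.0, register_window=(1975, 2060), treatment=None,
            comorbidities={})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0,
                                                   require_born_in_country=False),
                                  code_map)
        pairs = lr.build_sib_pairs(cohort)
        full = lr.sibling_stratified_risks(pairs, "full").iloc[0]
        half = lr.sibling_stratified_risks(pairs, "maternal_half").iloc[0]
        assert half["K_unexposed"] > full["K_unexposed"]

    def test_exposure_risk_elevated_under_heritability(self, code_map):
        cfg = lr.simulate_sib_pairs_config(
            40000, 0, base=lr.broad_preset(), a2=0.6, c2=0.0,
            lifetime_risk_by_49=0.072, seed=15, annual_mortality_hazard=0.0,
            annual_emigration_hazard=0.0, suicide_prob=0.0,
            register_window=(1975, 2060), treatment=None, comorbidities={})
        b = lr.simulate_registry(cfg)
        cohort = lr.select_cohort(b, lr.CohortSpec(min_followup_after_first_dx=0,
                                                   require_born_in_country=False),
                                  code_map)
        pairs = lr.build_sib_pairs(cohort)
        risks = lr.sibling_stratified_risks(pairs, "full")
        row = risks.iloc[0]
        assert row["K_exposed"] > row["K_pop"] > row["K_unexposed"]
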