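"""Base-case evaluation, incrementals, PSA/CEAC, DSA and scenarios."""

import numpy as np
import pytest

import lungscreen as ls


@pytest.fixture(scope="module")
def results(params, settings, strategies):
    return {
        name: ls.evaluate_strategy(params, s, settings)
        for name, s in strategies.items()
    }


class TestBaseCase:
    def test_comparator_has_no_test_cost(self, results):
        assert results["no_screening"].cost_components["test"] == 0.0

    def test_absolute_levels_near_published_totals(self, results):
        # absolute levels depend on appendix timing conventions that are
        # not published; incremental quantities carry the tight contracts
        assert results["ecls"].cost == pytest.approx(414102, rel=0.05)
        assert results["ecls"].qaly == pytest.approx(8570.4, rel=0.005)
        assert results["no_screening"].qaly == pytest.approx(8559.7, rel=0.005)

    def test_zero_prevalence_edge(self, params, settings, strategies):
        p0 = params.with_value("prevalence", 0.0)
        res = {
            n: ls.evaluate_strategy(p0, s, settings)
            for n, s in strategies.items()
        }
        qalys = {r.qaly for r in res.values()}
        assert max(qalys) - min(qalys) < 1e-9
        # cost differences reduce to test + healthy-participant imaging
        d = res["ecls"].cost - res["no_screening"].cost
        expected = 1000 * (
            106.5 + (1 - 0.9038) * ls.discount_amount(503.8, 1.0, ls.DiscountSpec())
        )
        assert d == pytest.approx(expected, rel=1e-9)


class TestIncrementals:
    def test_identical_inputs_give_zero_increments(self, results, settings):
        inc = ls.compare(results["ecls"], results["ecls"], settings.thresholds)
        assert inc.d_cost == 0 and inc.d_qaly == 0
        assert all(v == 0 for v in inc.d_nmb.values())
        assert inc.icer_flag == "undefined"

    def test_qaly_gain_vs_no_screening(self, results, settings):
        inc = ls.compare(results["ecls"], results["no_screening"],
                         settings.thresholds)
        assert inc.d_qaly == pytest.approx(10.7, rel=0.03)

    def test_ldct_icers(self, results, settings):
        vs_ns = ls.compare(results["full_ldct"], results["no_screening"],
                           settings.thresholds)
        assert vs_ns.icer == pytest.approx(25972, rel=0.03)
        vs_ecls = ls.compare(results["full_ldct"], results["ecls"],
                             settings.thresholds)
        assert vs_ecls.icer == pytest.approx(34810, rel=0.03)

    def test_nmb_identity_exact(self, results):
        inc = ls.compare(results["ecls"], results["no_screening"],
                         (17500.0, 20000.0, 31000.0))
        for lam, v in inc.d_nmb.items():
            assert v == lam * inc.d_qaly - inc.d_cost

    def test_pairwise_consistency(self, results, settings):
        ab = ls.compare(results["ecls"], results["no_screening"])
        bc = ls.compare(results["no_screening"], results["full_ldct"])
        ac = ls.compare(results["ecls"], results["full_ldct"])
        assert ac.d_cost == pytest.approx(ab.d_cost + bc.d_cost, rel=1e-12)
        assert ac.d_qaly == pytest.approx(ab.d_qaly + bc.d_qaly, rel=1e-9)

    def test_icer_invariant_to_cohort_size(self, params, strategies):
        icers = []
        for cohort in (500.0, 1000.0, 4000.0):
            st = ls.EvaluationSettings(cohort_size=cohort)
            res = {
                n: ls.evaluate_strategy(params, s, st)
                for n, s in strategies.items()
            }
            icers.append(
                ls.compare(res["full_ldct"], res["no_screening"]).icer
            )
        assert np.ptp(icers) < 1e-6 * abs(icers[0])

    def test_baseline_qaly_parameter_cancels_in_increments(
        self, params, settings, strategies
    ):
        shifted = params.with_value("baseline_disc_qaly_nolc", 12.0)
        for name, s in strategies.items():
            a = ls.evaluate_strategy(params, s, settings)
            b = ls.evaluate_strategy(shifted, s, settings)
            assert b.cost == a.cost
        inc_a = ls.compare(
            ls.evaluate_strategy(params, strategies["ecls"], settings),
            ls.evaluate_strategy(params, strategies["no_screening"], settings),
        )
        inc_b = ls.compare(
            ls.evaluate_strategy(shifted, strategies["ecls"], settings),
            ls.evaluate_strategy(shifted, strategies["no_screening"], settings),
        )
        assert inc_b.d_qaly == pytest.approx(inc_a.d_qaly, abs=1e-8)


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case(
        self, all_fixed_params, settings, results
    ):
        st = ls.EvaluationSettings(psa_draws=20)
        psa = ls.run_psa(all_fixed_params, settings=st, seed=0)
        assert np.allclose(psa.costs["ecls"], results["ecls"].cost)
        assert np.allclose(psa.qalys["ecls"], results["ecls"].qaly)
        # CEAC is an indicator of the NMB-maximal strategy per threshold
        probs = psa.ceac["probability"].to_numpy()
        assert set(np.round(probs, 12)) <= {0.0, 1.0}

    def test_mean_increment_matches_deterministic_within_mc_error(
        self, params, results
    ):
        st = ls.EvaluationSettings(psa_draws=4000)
        psa = ls.run_psa(params, settings=st, seed=3)
        dq = psa.qalys["ecls"] - psa.qalys["no_screening"]
        det = results["ecls"].qaly - results["no_screening"].qaly
        se = dq.std(ddof=1) / np.sqrt(dq.size)
        assert abs(dq.mean() - det) < 3 * se

    def test_seed_reproducibility(self, params):
        st = ls.EvaluationSettings(psa_draws=200)
        a = ls.run_psa(params, settings=st, seed=11)
        b = ls.run_psa(params, settings=st, seed=11)
        assert np.array_equal(a.costs["ecls"], b.costs["ecls"])
        assert a.ceac.equals(b.ceac)
        c = ls.run_psa(params, settings=st, seed=12)
        assert not np.array_equal(a.costs["ecls"], c.costs["ecls"])

    def test_ceac_probabilities_sum_to_one(self, params):
        st = ls.EvaluationSettings(psa_draws=500)
        psa = ls.run_psa(params, settings=st, seed=5)
        sums = psa.ceac.groupby("threshold")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_zero_threshold_prefers_cheapest(self, params):
        st = ls.EvaluationSettings(psa_draws=500)
        psa = ls.run_psa(params, settings=st, seed=5)
        at0 = psa.ceac[psa.ceac.threshold == 0.0].set_index("strategy")
        assert at0.loc["no_screening", "probability"] == pytest.approx(1.0)

    def test_crossover_near_published_thresholds(self, params):
        # no screening leads below ~18k/QALY; the triage test leads above
        psa = ls.run_psa(params, settings=ls.EvaluationSettings(), seed=1)
        t = psa.ceac.pivot(index="threshold", columns="strategy",
                           values="probability")
        assert t.loc[15000, "no_screening"] > t.loc[15000, "ecls"]
        assert t.loc[20000, "ecls"] > t.loc[20000, "no_screening"]
        assert t.loc[40000, "full_ldct"] > t.loc[40000, "ecls"]


class TestDSA:
    def test_low_prevalence_flips_decision(self, params, settings):
        entries = ls.run_dsa(params, settings=settings,
                             parameters=["prevalence"])
        low = next(e for e in entries if e.setting == "min")
        assert low.value == 0.01
        d_nmb = low.incrementals["no_screening"].d_nmb[20000.0]
        assert d_nmb == pytest.approx(-60077, rel=0.03)

    def test_high_prevalence_favours_universal_ldct(self, params, settings):
        entries = ls.run_dsa(params, settings=settings,
                             parameters=["prevalence"])
        high = next(e for e in entries if e.setting == "max")
        for lam in settings.thresholds:
            nmb = {
                n: lam * r.qaly - r.cost for n, r in high.results.items()
            }
            assert max(nmb, key=nmb.get) == "full_ldct"

    def test_degenerate_range_reproduces_base_case(self, params, settings,
                                                   strategies):
        frozen = ls.ParameterSet(
            {
                p.name: p if p.name != "prevalence"
                else type(p)(p.name, p.value, p.dist, (0.02, 0.02))
                for p in params
            }
        )
        entries = ls.run_dsa(frozen, settings=settings,
                             parameters=["prevalence"])
        base = ls.evaluate_strategy(params, strategies["ecls"], settings)
        for e in entries:
            assert e.results["ecls"].cost == pytest.approx(base.cost)

    def test_unranged_parameter_rejected(self, params, settings):
        with pytest.raises(ValueError, match="treat_ls"):
            ls.run_dsa(params, settings=settings, parameters=["treat_ls"])

    def test_discount_rate_rows_present_by_default(self, params, settings):
        entries = ls.run_dsa(params, settings=settings)
        names = {e.parameter for e in entries}
        assert "discount_rate" in names and "prevalence" in names


@pytest.fixture(scope="module")
def plane(params, settings):
    return ls.run_scenarios(params, settings).set_index("alternative")


class TestScenarios:
    def test_random_test_sends_52_percent_to_ldct(self, params):
        from lungscreen.evaluate import default_scenarios

        s2 = default_scenarios()[1].strategy
        dist = ls.pathway_distribution(params.base(), s2)
        sent = sum(
            c.probability for c in dist.cells
            if c.pathway.value in ("TP", "TN_LDCT", "FP", "FN_LDCT")
        )
        assert sent == pytest.approx(0.52, abs=1e-12)

    def test_reduced_sensitivity_not_cost_effective(self, plane):
        assert plane.loc["scenario1_sens_es_25", "icer"] > 30000

    def test_random_test_collinear_with_universal_ldct(self, plane):
        s2 = plane.loc["scenario2_random_test"]
        ld = plane.loc["full_ldct"]
        assert s2["icer"] == pytest.approx(ld["icer"], rel=1e-9)
        assert s2["d_cost"] / ld["d_cost"] == pytest.approx(0.52, rel=1e-9)
        assert s2["d_qaly"] / ld["d_qaly"] == pytest.approx(0.52, rel=1e-9)
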