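"""Incremental analysis, dominance, NMB, PSA machinery, population impact."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecea import (
    DistributionSpec,
    PopulationImpactInputs,
    acceptability,
    compare_arms,
    export_scatter,
    net_monetary_benefit,
    population_impact,
    run_psa,
    sample_parameter_set,
)
from strokecea.cea import _classify
from strokecea.markov import LifetimeOutcome


def _outcome(arm, qalys, cost):
    from strokecea.economics import CostComponents

    return LifetimeOutcome(
        arm=arm, qalys=qalys, cost_healthcare=cost, cost_societal=cost,
        life_years=qalys, acute_qalys=0.0, acute_costs=CostComponents(),
    )


class TestCompareArms:
    def test_published_dominant_comparison(self):
        """QALYs 5.17 vs 4.03 at costs 154,640 vs 160,828: +1.14 QALYs at
        -6,188 USD — the intervention dominates."""
        cmp = compare_arms(_outcome("a", 5.17, 154_640.0),
                           _outcome("b", 4.03, 160_828.0))
        assert cmp.delta_qalys == pytest.approx(1.14)
        assert cmp.delta_cost == pytest.approx(-6_188.0)
        assert cmp.dominance == "intervention_dominant"
        assert cmp.icer is None

    def test_identical_outcomes_equivalent(self):
        cmp = compare_arms(_outcome("a", 2.0, 100.0), _outcome("b", 2.0, 100.0))
        assert cmp.dominance == "equivalent"
        assert cmp.icer is None

    def test_positive_tradeoff_has_defined_icer(self):
        """QALYs 5.25 vs 5.19 at costs 154,407 vs 149,680: +0.06 QALYs for
        +4,727 USD — a genuine trade-off with a positive ICER."""
        cmp = compare_arms(_outcome("a", 5.25, 154_407.0),
                           _outcome("b", 5.19, 149_680.0))
        assert cmp.delta_cost == pytest.approx(4_727.0)
        assert cmp.dominance == "icer_defined"
        assert cmp.icer == pytest.approx(4_727.0 / 0.06, rel=1e-9)

    def test_unknown_perspective_rejected(self):
        with pytest.raises(ValueError, match="perspective"):
            compare_arms(_outcome("a", 1, 1), _outcome("b", 1, 2), "payer")

    @pytest.mark.parametrize(
        "dq,dc,expected",
        [
            (1.0, -1.0, "intervention_dominant"),
            (1.0, 0.0, "intervention_dominant"),
            (0.0, -1.0, "intervention_dominant"),
            (-1.0, 1.0, "comparator_dominant"),
            (-1.0, 0.0, "comparator_dominant"),
            (0.0, 1.0, "comparator_dominant"),
            (0.0, 0.0, "equivalent"),
            (1.0, 1.0, "icer_defined"),
            (-1.0, -1.0, "icer_defined"),
        ],
    )
    def test_sign_quadrants_exhaustive(self, dq, dc, expected):
        dominance, icer = _classify(dq, dc)
        assert dominance == expected
        assert (icer is not None) == (expected == "icer_defined")


class TestNetMonetaryBenefit:
    def test_zero_threshold_is_negative_cost(self):
        assert net_monetary_benefit(2.0, 50_000.0, 0.0) == -50_000.0

    def test_hand_arithmetic(self):
        assert net_monetary_benefit(2.0, 50_000.0, 50_000.0) == 50_000.0

    @given(
        dq=st.floats(-2, 2).filter(lambda x: abs(x) > 1e-6),
        dc=st.floats(-1e5, 1e5).filter(lambda x: abs(x) > 1e-3),
        wtp=st.sampled_from([50_000.0, 100_000.0]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_positive_increment_iff_dominant_or_icer_below_threshold(self, dq, dc, wtp):
        """Sign identity: incremental NMB > 0 iff the intervention dominates,
        or trades off favourably (dq > 0 and ICER < wtp), or loses QALYs at
        savings above the threshold rate."""
        nmb = net_monetary_benefit(dq, dc, wtp)
        dominance, icer = _classify(dq, dc)
        if dominance == "intervention_dominant":
            expected = True
        elif dominance == "comparator_dominant":
            expected = False
        else:
            expected = icer < wtp if dq > 0 else icer > wtp
        assert (nmb > 0) == expected


class TestParameterSampling:
    def test_all_fixed_specs_reproduce_base_case(self, fresh_params):
        fresh_params.psa_spec = {
            k: DistributionSpec("fixed") for k in fresh_params.psa_spec
        }
        rng = np.random.default_rng(0)
        drawn = sample_parameter_set(fresh_params, rng)
        assert drawn.to_dict() == fresh_params.to_dict()

    def test_missing_spec_named(self, fresh_params):
        del fresh_params.psa_spec["annual_wage"]
        with pytest.raises(KeyError, match="annual_wage"):
            sample_parameter_set(fresh_params, np.random.default_rng(0))

    def test_sampled_sets_stay_valid(self, params):
        from strokecea import validate_parameter_set

        rng = np.random.default_rng(42)
        for _ in range(20):
            drawn = sample_parameter_set(params, rng)
            errors = [f for f in validate_parameter_set(drawn) if f.level == "error"]
            assert errors == []

    def test_sample_means_match_distribution_means(self, params):
        """Across 10,000 draws each scalar sampler is moment-matched: the
        sample mean sits within 3 SE of the point estimate."""
        rng = np.random.default_rng(7)
        n = 10_000
        draws_cost = np.empty(n)
        draws_p = np.empty(n)
        draws_mrs = np.empty((n, 7))
        for i in range(n):
            drawn = sample_parameter_set(params, rng)
            draws_cost[i] = drawn.cost_evt
            draws_p[i] = drawn.p_recurrent_annual
            draws_mrs[i] = drawn.mrs90_dist["etici2c3"]
        for sample, target in (
            (draws_cost, params.cost_evt),
            (draws_p, params.p_recurrent_annual),
        ):
            se = sample.std(ddof=1) / np.sqrt(n)
            assert abs(sample.mean() - target) < 3 * se
        se = draws_mrs.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(
            np.abs(draws_mrs.mean(axis=0) - params.mrs90_dist["etici2c3"]) < 3 * se + 1e-12
        )


@pytest.fixture(scope="module")
def samples(params, life_table, config):
    return run_psa(params, life_table, ("etici2c3", "etici2b_accessible"),
                   n_draws=200, master_seed=99, config=config)


class TestRunPsa:
    def test_reproducible_under_master_seed(self, params, life_table, config):
        a = run_psa(params, life_table, ("etici2c3", "etici2b_accessible"),
                    n_draws=20, master_seed=1, config=config)
        b = run_psa(params, life_table, ("etici2c3", "etici2b_accessible"),
                    n_draws=20, master_seed=1, config=config)
        assert [s.incremental("societal") for s in a] == [
            s.incremental("societal") for s in b]

    def test_scatter_has_one_row_per_draw(self, samples):
        sc = export_scatter(samples, "healthcare")
        assert len(sc) == 200
        assert list(sc.columns) == ["draw", "delta_qalys", "delta_cost"]

    def test_scatter_means_match_independent_aggregation(self, samples):
        sc = export_scatter(samples, "societal")
        dq = np.mean([s.outcome_a.qalys - s.outcome_b.qalys for s in samples])
        dc = np.mean([s.outcome_a.cost_societal - s.outcome_b.cost_societal
                      for s in samples])
        assert sc.delta_qalys.mean() == pytest.approx(dq)
        assert sc.delta_cost.mean() == pytest.approx(dc)

    def test_fixed_specs_collapse_to_base_case(self, fresh_params, life_table, config):
        from strokecea import run_lifetime

        fresh_params.psa_spec = {
            k: DistributionSpec("fixed") for k in fresh_params.psa_spec
        }
        samples = run_psa(fresh_params, life_table,
                          ("etici2c3", "etici2b_accessible"),
                          n_draws=5, master_seed=3, config=config)
        base_a = run_lifetime("etici2c3", fresh_params, life_table, config)
        for s in samples:
            assert s.outcome_a.qalys == pytest.approx(base_a.qalys)

    def test_acceptability_counts_match_manual_recount(self, samples):
        for wtp in (50_000.0, 100_000.0):
            res = acceptability(samples, wtp, "healthcare")
            manual = np.mean([
                wtp * (s.outcome_a.qalys - s.outcome_b.qalys)
                - (s.outcome_a.cost_healthcare - s.outcome_b.cost_healthcare) > 0
                for s in samples
            ])
            assert res.fraction_acceptable == pytest.approx(manual)

    def test_acceptability_monotone_in_threshold_when_qalys_gained(self, samples):
        fractions = [
            acceptability(samples, wtp, "societal").fraction_acceptable
            for wtp in (0.0, 25_000.0, 50_000.0, 100_000.0, 200_000.0)
        ]
        if all(s.incremental("societal")[0] >= 0 for s in samples):
            assert fractions == sorted(fractions)

    def test_hand_built_samples_fraction(self):
        samples = [
            _psa_sample(1.0, -10.0), _psa_sample(1.0, 10_000.0),
            _psa_sample(-1.0, 10.0), _psa_sample(-0.5, 100.0),
        ]
        res = acceptability(samples, 50_000.0, "healthcare")
        assert res.fraction_acceptable == 0.5


def _psa_sample(dq, dc):
    from strokecea.cea import PSASample

    return PSASample(draw=0, outcome_a=_outcome("a", dq, dc),
                     outcome_b=_outcome("b", 0.0, 0.0))


_PAPER_IMPACT = PopulationImpactInputs(
    n_procedures=39_000,
    p_incomplete=0.539,
    p_accessible=0.332,
    p_non_accessible=0.668,
    dqaly_accessible=1.14,
    dqaly_non_accessible=0.45,
    dcost_accessible={"healthcare": 6_188.0, "societal": 9_317.0},
    dcost_non_accessible={"healthcare": 6_156.0, "societal": 6_473.0},
)


class TestPopulationImpact:
    def test_reference_annual_figures(self):
        """39,000 procedures, 53.9% incomplete, 33.2/66.8 split, published
        per-patient deltas: 7,956 + 6,319 = 14,275 QALYs; 43 + 86 = 129 M
        USD healthcare and 65 + 91 = 156 M USD societal savings."""
        out = population_impact(_PAPER_IMPACT, rounding_mode="paper")
        assert out.qalys_accessible == 7_956
        assert out.qalys_non_accessible == 6_319
        assert out.qalys_total == 14_275
        assert out.savings_accessible["healthcare"] == 43
        assert out.savings_non_accessible["healthcare"] == 86
        assert out.savings_total["healthcare"] == 129
        assert out.savings_accessible["societal"] == 65
        assert out.savings_non_accessible["societal"] == 91
        assert out.savings_total["societal"] == 156

    def test_exact_mode_unrounded(self):
        out = population_impact(_PAPER_IMPACT, rounding_mode="exact")
        n_acc = 39_000 * 0.539 * 0.332
        assert out.qalys_accessible == pytest.approx(n_acc * 1.14)
        assert out.savings_accessible["healthcare"] == pytest.approx(
            n_acc * 6_188.0 / 1e6)

    def test_zero_procedures_all_zero(self):
        from dataclasses import replace

        out = population_impact(replace(_PAPER_IMPACT, n_procedures=0))
        assert out.qalys_total == 0
        assert all(v == 0 for v in out.savings_total.values())

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_procedure_volume(self, scale):
        from dataclasses import replace

        base = population_impact(_PAPER_IMPACT, "exact")
        scaled = population_impact(
            replace(_PAPER_IMPACT, n_procedures=39_000 * scale), "exact")
        assert scaled.qalys_total == pytest.approx(base.qalys_total * scale)
        for p in ("healthcare", "societal"):
            assert scaled.savings_total[p] == pytest.approx(
                base.savings_total[p] * scale)

    def test_totals_match_per_patient_brute_force(self):
        """Independent oracle: simulate the incomplete-reperfusion patients
        one by one and sum their per-patient deltas."""
        out = population_impact(_PAPER_IMPACT, "exact")
        n_inc = 39_000 * 0.539
        n_acc = round(n_inc * 0.332, 6)
        total_q = 0.0
        total_c = 0.0
        whole_acc, frac_acc = int(n_acc), n_acc - int(n_acc)
        for _ in range(whole_acc):
            total_q += 1.14
            total_c += 6_188.0
        total_q += frac_acc * 1.14
        total_c += frac_acc * 6_188.0
        n_non = n_inc - n_acc
        whole_non, frac_non = int(n_non), n_non - int(n_non)
        for _ in range(whole_non):
            total_q += 0.45
            total_c += 6_156.0
        total_q += frac_non * 0.45
        total_c += frac_non * 6_156.0
        assert out.qalys_total == pytest.approx(total_q)
        assert out.savings_total["healthcare"] == pytest.approx(total_c / 1e6)

    def test_split_must_sum_to_one(self):
        from dataclasses import replace

        with pytest.raises(ValueError, match="p_accessible"):
            population_impact(replace(_PAPER_IMPACT, p_non_accessible=0.5))
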