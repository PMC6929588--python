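"""Switch-cost statistics and permutation inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from taskstruct.agents import flat_agent, hierarchical_agent, simulate_learning_phase
from taskstruct.switchcost import (
    PermutationResult,
    UndefinedCost,
    analyze_cohort,
    compute_switch_cost,
    condition_values,
    infer_supraordinate_dimension,
    permute_group,
    permute_individual,
    pre_post_switch_comparison,
    union_flag,
)


class TestComputeSwitchCost:
    def test_printed_formula_hand_example(self):
        # means 690/610, both SDs 20 -> signed 80, normalized 4.0
        switch = np.array([670.0, 690.0, 710.0])
        repeat = np.array([590.0, 610.0, 630.0])
        st = compute_switch_cost(switch, repeat, "rt")
        assert st.signed_cost == pytest.approx(80.0)
        assert st.normalized_individual == pytest.approx(4.0)
        assert st.abs_cost == pytest.approx(80.0)

    def test_equal_conditions_give_zero(self):
        vals = np.array([600.0, 620.0, 640.0])
        st = compute_switch_cost(vals, vals, "rt")
        assert st.signed_cost == 0.0
        assert st.normalized_individual == 0.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(650, 30, 20), rng.normal(600, 30, 25)
        st_ab = compute_switch_cost(a, b, "rt")
        st_ba = compute_switch_cost(b, a, "rt")
        assert st_ab.signed_cost == pytest.approx(-st_ba.signed_cost)
        assert st_ab.abs_cost == pytest.approx(st_ba.abs_cost)

    def test_accuracy_sign_convention(self):
        # higher accuracy on repeat trials = positive cost
        switch = np.array([1.0, 0.0, 0.0, 1.0])
        repeat = np.array([1.0, 1.0, 1.0, 0.0])
        st = compute_switch_cost(switch, repeat, "accuracy")
        assert st.signed_cost == pytest.approx(0.25)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        scale=hst.floats(min_value=1e-3, max_value=1e3),
        seed=hst.integers(min_value=0, max_value=2**16),
    )
    def test_scale_invariance_of_normalized_cost(self, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(700, 40, 30), rng.normal(640, 35, 30)
        st = compute_switch_cost(a, b, "rt")
        st_scaled = compute_switch_cost(scale * a, scale * b, "rt")
        assert st_scaled.normalized_individual == pytest.approx(
            st.normalized_individual
        )

    def test_single_trial_condition_undefined(self):
        with pytest.raises(UndefinedCost):
            compute_switch_cost(np.array([600.0]), np.array([1.0, 2.0]), "rt")


class TestPermuteIndividual:
    def test_observed_above_all_null_is_significant(self):
        res = PermutationResult(
            observed=2.0, null_values=np.linspace(0.0, 1.0, 500), n_perm=500
        )
        assert res.percentile == 1.0
        assert res.significant

    def test_strong_effect_flagged(self):
        switch = np.array([900.0, 910.0, 905.0, 895.0, 902.0, 898.0])
        repeat = np.array([600.0, 610.0, 605.0, 595.0, 604.0, 597.0])
        res = permute_individual(switch, repeat, n_perm=500, seed=0)
        assert res.significant

    def test_degenerate_all_ties_not_significant(self):
        vals = np.full(6, 500.0)
        res = permute_individual(vals[:3], vals[3:], n_perm=200, seed=0)
        assert res.observed == 0.0
        assert res.percentile_strict == 0.0
        assert not res.significant

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            permute_individual(rng.normal(0, 1, 10), rng.normal(0, 1, 10), n_perm=50)

    def test_monte_carlo_matches_full_enumeration_on_small_toy(self):
        # 8 trials, 4 per condition: exact null from all 70 label assignments
        values = np.array([610.0, 655.0, 590.0, 700.0, 640.0, 615.0, 672.0, 598.0])
        n_s = 4

        def stat(split):
            s = values[list(split)]
            r = values[[i for i in range(8) if i not in split]]
            num = abs(s.mean() - r.mean())
            den = np.sqrt(0.5 * (s.var(ddof=1) + r.var(ddof=1)))
            return num / den

        exact = np.array(
            [stat(c) for c in itertools.combinations(range(8), n_s)]
        )
        res = permute_individual(values[:n_s], values[n_s:], n_perm=20_000, seed=3)
        se_mean = exact.std() / np.sqrt(res.n_perm)
        assert res.null_values.mean() == pytest.approx(exact.mean(), abs=4 * se_mean)
        assert res.null_values.var() == pytest.approx(exact.var(), rel=0.05)
        # every Monte-Carlo draw is a member of the exact support
        assert np.all(np.isin(np.round(res.null_values, 10), np.round(exact, 10)))

    def test_percentiles_uniform_for_flat_agents(self, exp2_clustered):
        pcts = []
        for i in range(500):
            trials = simulate_learning_phase(flat_agent(), exp2_clustered, 40_000 + i)
            s, r = condition_values(trials, exp2_clustered, "age", "rt")
            res = permute_individual(s, r, n_perm=400, seed=i)
            pcts.append(res.percentile)
        stat, p = sps.kstest(pcts, "uniform")
        assert p > 0.01


def test_individual_flag_rate_monotone_in_injected_cost(exp2_clustered):
    """Detection power grows with the injected switch cost."""
    rates = []
    for delta in (0.0, 20.0, 40.0, 80.0):
        agent = (
            flat_agent()
            if delta == 0
            else hierarchical_agent("age", delta)
        )
        flags = 0
        n_agents = 150
        for i in range(n_agents):
            trials = simulate_learning_phase(
                agent, exp2_clustered, 200_000 + int(delta) * 1000 + i
            )
            s, r = condition_values(trials, exp2_clustered, "age", "rt")
            flags += permute_individual(s, r, n_perm=500, seed=i).significant
        rates.append(flags / n_agents)
    assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]


class TestDimensionInference:
    def test_hierarchical_agents_recovered(self, exp2_clustered):
        hits = 0
        for i in range(60):
            agent = hierarchical_agent("gender", 80.0)
            trials = simulate_learning_phase(agent, exp2_clustered, 60_000 + i)
            dim, _ = infer_supraordinate_dimension(trials, exp2_clustered)
            hits += dim == "gender"
        assert hits >= 55

    def test_flat_agents_split_evenly(self, exp2_clustered):
        dims = []
        for i in range(200):
            trials = simulate_learning_phase(flat_agent(), exp2_clustered, 70_000 + i)
            dim, _ = infer_supraordinate_dimension(trials, exp2_clustered)
            dims.append(dim)
        k = sum(d == "age" for d in dims)
        p = sps.binomtest(k, len(dims), 0.5).pvalue
        assert p > 0.001


class TestUnionFlag:
    @pytest.mark.parametrize(
        "rt_pct,acc_pct,expected",
        [(1.0, 0.5, True), (0.5, 0.99, True), (0.5, 0.5, False)],
    )
    def test_truth_table(self, rt_pct, acc_pct, expected):
        def make(pct):
            null = np.linspace(0, 1, 100)
            return PermutationResult(
                observed=float(np.quantile(null, pct) + (1e-9 if pct > 0.9 else 0)),
                null_values=null,
                n_perm=100,
            )

        assert union_flag(make(rt_pct), make(acc_pct)) is expected


class TestPermuteGroup:
    def test_hierarchical_group_detected(self, exp2_clustered):
        inputs = []
        for i in range(30):
            agent = hierarchical_agent("age", 80.0)
            trials = simulate_learning_phase(agent, exp2_clustered, 80_000 + i)
            inputs.append(condition_values(trials, exp2_clustered, "age", "rt"))
        res = permute_group(inputs, n_perm=1000, seed=1)
        assert res.significant

    def test_flat_group_percentiles_uniform_across_cohorts(self, exp2_clustered):
        pcts = []
        for rep in range(100):
            inputs = []
            for i in range(8):
                trials = simulate_learning_phase(
                    flat_agent(), exp2_clustered, 90_000 + 8 * rep + i
                )
                inputs.append(condition_values(trials, exp2_clustered, "age", "rt"))
            res = permute_group(inputs, n_perm=300, seed=rep)
            pcts.append(res.percentile)
        stat, p = sps.kstest(pcts, "uniform")
        assert p > 0.01

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(UndefinedCost):
            permute_group([(rng.normal(0, 1, 10), rng.normal(0, 1, 10))], n_perm=200)


class TestPrePostComparison:
    def test_shrinking_cost_ordering_recovered(self):
        # injected 80 ms before vs 30 ms after the rule switch
        from taskstruct.designs import enumerate_versions

        design = enumerate_versions(3)[0]
        diffs = []
        for i in range(60):
            agent = hierarchical_agent(
                design.mapping.biased_dimension, 80.0, post_switch_cost_ms=30.0
            )
            trials = simulate_learning_phase(agent, design, 95_000 + i)
            costs = pre_post_switch_comparison(
                trials, design, design.mapping.biased_dimension, "rt"
            )
            diffs.append(costs["pre"] - costs["post"])
        assert np.mean(diffs) > 10.0  # pre > post, well beyond noise

    def test_requires_rule_switch_design(self, exp2_clustered):
        trials = simulate_learning_phase(flat_agent(), exp2_clustered, 0)
        with pytest.raises(ValueError):
            pre_post_switch_comparison(trials, exp2_clustered, "age", "rt")


class TestCohortAnalysis:
    def test_outputs_complete_and_consistent(self, small_cohort):
        indiv, group = analyze_cohort(small_cohort, n_perm=300, seed=5)
        assert len(indiv) == 12
        assert set(indiv["inferred_dim"]) <= {"age", "gender"}
        assert indiv["rt_percentile"].between(0, 1).all()
        assert set(group) == {
            ("clustered", "rt"), ("clustered", "accuracy"),
            ("non_clustered", "rt"), ("non_clustered", "accuracy"),
        }

    def test_deterministic_under_seed(self, small_cohort):
        a, _ = analyze_cohort(small_cohort, n_perm=200, seed=5)
        b, _ = analyze_cohort(small_cohort, n_perm=200, seed=5)
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)
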