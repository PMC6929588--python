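"""Recognition/source memory summaries, t-tests, and the ANOVA engine."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from taskstruct.agents import default_populations, flat_agent, simulate_cohort
from taskstruct.memory import (
    UndefinedRates,
    baseline_category,
    binned_anova,
    chance_memory_test,
    cohort_recognition,
    collapse_ratings,
    early_bins_comparison,
    greenhouse_geisser_epsilon,
    independent_t_report,
    mixed_rm_anova,
    one_sample_t_report,
    paired_t_report,
    recognition_summary,
    source_memory_analysis,
    transfer_analysis,
    two_within_anova,
)
from taskstruct.preprocess import assign_bins


class TestCollapse:
    def test_rating_collapse(self):
        recs = pd.DataFrame(
            {"rating": ["DefOld", "ProbOld", "ProbNew", "DefNew", None]}
        )
        out = collapse_ratings(recs)
        assert list(out["response"]) == ["old", "old", "new", "new", None]

    def test_unknown_rating_rejected(self):
        with pytest.raises(ValueError):
            collapse_ratings(pd.DataFrame({"rating": ["Maybe"]}))


def _mem_frame(old_responses, new_responses):
    rows = []
    for i, resp in enumerate(old_responses):
        rows.append(
            {"status": "old", "response": resp, "lp_bin": 1.0 + (i % 4),
             "age": "young", "gender": "female"}
        )
    for resp in new_responses:
        rows.append(
            {"status": "new", "response": resp, "lp_bin": np.nan,
             "age": "young", "gender": "male"}
        )
    return pd.DataFrame(rows)


class TestRecognitionSummary:
    def setup_method(self):
        self.bins = assign_bins(120)
        from taskstruct.designs import enumerate_versions

        self.design = enumerate_versions(2)[0]
        self.base = baseline_category(self.design)

    def test_counting_example(self):
        recs = _mem_frame(["old", "old", "new"], ["new", "new", "old"])
        s = recognition_summary(recs, self.bins, self.base, ("age", "gender"))
        assert s.hit_rate == pytest.approx(2 / 3)
        assert s.fa_rate == pytest.approx(1 / 3)

    def test_perfect_responder(self):
        recs = _mem_frame(["old"] * 8, ["new"] * 4)
        s = recognition_summary(recs, self.bins, self.base, ("age", "gender"))
        assert s.hit_rate == 1.0
        assert s.fa_rate == 0.0

    def test_missing_condition_flagged(self):
        recs = _mem_frame(["old", "old"], [])
        with pytest.raises(UndefinedRates):
            recognition_summary(recs, self.bins, self.base, ("age", "gender"))

    def test_baseline_category_shared_across_versions(self):
        from taskstruct.designs import enumerate_versions

        for exp in (1, 2, 3, 4):
            versions = enumerate_versions(exp)
            base = baseline_category(versions[0])
            keys = {v.mapping.key_for(base) for v in versions}
            assert len(keys) == 1


class TestEffectSizes:
    def test_paired_d_z_and_cl_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.6, 0.1, 25)
        y = rng.normal(0.4, 0.1, 25)
        rep = paired_t_report(x, y)
        assert rep.cohen_d == pytest.approx(rep.t / np.sqrt(25))
        assert rep.cl_effect == pytest.approx(sps.norm.cdf(rep.cohen_d))

    def test_null_difference_near_zero_t(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 0.1, 400)
        y = x + rng.normal(0.0, 0.05, 400)
        rep = paired_t_report(x, y)
        assert abs(rep.cohen_d) < 0.15
        assert rep.cl_effect == pytest.approx(0.5, abs=0.06)

    def test_zero_variance_signals_error(self):
        x = np.full(10, 0.7)
        y = np.full(10, 0.5)
        with pytest.raises(ValueError):
            paired_t_report(x, y)

    def test_negative_t_symmetric_cl(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.0, 1.0, 30)
        y = x + 0.5 + rng.normal(0, 0.3, 30)
        fwd = paired_t_report(y, x)
        rev = paired_t_report(x, y)
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.cl_effect == pytest.approx(1 - fwd.cl_effect)

    def test_independent_d_s_convention(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.65, 0.1, 40)
        y = rng.normal(0.55, 0.1, 35)
        rep = independent_t_report(x, y)
        assert rep.cl_effect == pytest.approx(sps.norm.cdf(rep.cohen_d / np.sqrt(2)))

    def test_estimator_recovery_of_paired_effect(self):
        # true d_z = 0.9 recovered without systematic bias
        rng = np.random.default_rng(8)
        ds = []
        for _ in range(500):
            diffs = rng.normal(0.9, 1.0, 31)
            rep = one_sample_t_report(diffs, 0.0)
            ds.append(rep.cohen_d)
        assert np.mean(ds) == pytest.approx(0.9, abs=0.1)


class TestAnovaEngine:
    # fixed 3-participant toy table
    TOY = np.array(
        [
            [0.71, 0.64, 0.55, 0.50],
            [0.62, 0.66, 0.48, 0.41],
            [0.55, 0.50, 0.47, 0.49],
        ]
    )

    def test_matches_reference_rm_anova_to_six_decimals(self):
        table = mixed_rm_anova(self.TOY, None, gg_correct=False).set_index("effect")
        long = pd.DataFrame(
            {
                "y": self.TOY.reshape(-1),
                "pid": np.repeat(np.arange(3), 4),
                "bin": np.tile(np.arange(4), 3),
            }
        )
        ref = pg.rm_anova(long, dv="y", within="bin", subject="pid",
                          correction=True, detailed=True)
        assert table.loc["bin", "F"] == pytest.approx(ref.loc[0, "F"], abs=1e-6)
        assert table.loc["bin", "p"] == pytest.approx(ref.loc[0, "p_unc"], abs=1e-6)
        assert table.loc["bin", "SS"] == pytest.approx(ref.loc[0, "SS"], abs=1e-6)
        ref_partial = ref.loc[0, "SS"] / (ref.loc[0, "SS"] + ref.loc[1, "SS"])
        assert table.loc["bin", "eta_p_sq"] == pytest.approx(ref_partial, abs=1e-6)
        eps_ref = pg.epsilon(pd.DataFrame(self.TOY), correction="gg")
        assert table.loc["bin", "epsilon"] == pytest.approx(eps_ref, abs=1e-6)

    def test_matches_reference_mixed_anova_balanced(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(0.6, 0.1, (12, 4)) + np.linspace(0, 0.2, 4)
        groups = np.repeat(["a", "b"], 6)
        mine = mixed_rm_anova(
            Y, pd.DataFrame({"group": groups}), gg_correct=False
        ).set_index("effect")
        long = pd.DataFrame(
            {
                "y": Y.reshape(-1),
                "pid": np.repeat(np.arange(12), 4),
                "bin": np.tile(np.arange(4), 12),
                "group": np.repeat(groups, 4),
            }
        )
        ref = pg.mixed_anova(long, dv="y", within="bin", subject="pid",
                             between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], abs=1e-6)
        assert mine.loc["bin", "F"] == pytest.approx(ref.loc["bin", "F"], abs=1e-6)
        assert mine.loc["bin:group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6
        )

    def test_identical_group_profiles_give_zero_group_ss(self):
        block = np.array([[0.7, 0.6, 0.5, 0.4], [0.65, 0.55, 0.5, 0.45]] * 3)
        Y = np.vstack([block, block])
        groups = ["a"] * 6 + ["b"] * 6
        table = mixed_rm_anova(
            Y, pd.DataFrame({"group": groups}), gg_correct=False
        ).set_index("effect")
        assert table.loc["group", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["bin:group", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_spherical_data_epsilon_near_one(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(0, 1, (400, 4))
        assert greenhouse_geisser_epsilon(Y) > 0.95

    def test_covariate_anova_degrees_of_freedom(self):
        rng = np.random.default_rng(13)
        n = 62
        Y = rng.normal(0.6, 0.1, (n, 4))
        groups = np.repeat(["clustered", "non_clustered"], n // 2)
        cov = rng.normal(0, 1, (n, 2))
        table = mixed_rm_anova(
            Y, pd.DataFrame({"group": groups}), covariates=cov, gg_correct=False
        ).set_index("effect")
        # within error df = (b-1)(N - g - c) = 3 * 58 = 174
        assert table.loc["bin", "df2"] == pytest.approx(174.0)
        assert table.loc["bin:cov1", "df1"] == pytest.approx(3.0)
        # between error df = N - g - c = 58
        assert table.loc["cov1", "df2"] == pytest.approx(58.0)


class TestTwoWithinAnova:
    def test_single_group_effect_equals_paired_t_squared(self):
        rng = np.random.default_rng(14)
        cells = rng.normal(0.7, 0.1, (20, 4))
        cells[:, :2] += 0.1  # factor A effect
        groups = np.array(["g1"] * 20)
        table = two_within_anova(cells, groups, "A", "B").set_index("effect")
        contrast = (cells[:, 0] + cells[:, 1] - cells[:, 2] - cells[:, 3]) / 2
        t, _ = sps.ttest_1samp(contrast, 0.0)
        assert table.loc["A", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_null_structure_gives_small_f(self):
        rng = np.random.default_rng(15)
        cells = rng.normal(0.6, 0.05, (60, 4))
        groups = np.repeat(["a", "b"], 30)
        table = two_within_anova(cells, groups, "A", "B")
        assert (table["p"] > 0.001).all()


class TestChanceMemory:
    def test_detects_real_memory_signal(self, small_cohort):
        rec = cohort_recognition(small_cohort)
        rep = chance_memory_test(rec["hit_rate"].to_numpy(), rec["fa_rate"].to_numpy())
        assert rep.p < 0.01
        assert rep.cohen_d > 0

    def test_calibrated_under_null_encoding(self):
        # with zero encoding signal the rejection rate is ~ alpha
        rng = np.random.default_rng(16)
        rejections = 0
        n_cohorts = 400
        for _ in range(n_cohorts):
            hit = rng.normal(0.5, 0.05, 20)
            fa = hit + rng.normal(0, 0.04, 20)
            rep = chance_memory_test(hit, fa)
            rejections += rep.p < 0.05
        rate = rejections / n_cohorts
        se = np.sqrt(0.05 * 0.95 / n_cohorts)
        assert rate == pytest.approx(0.05, abs=3 * se)


class TestCohortPipelines:
    def test_recognition_table_conservation(self, small_cohort):
        rec = cohort_recognition(small_cohort)
        assert rec["hit_rate"].between(0, 1).all()
        assert rec["fa_rate"].between(0, 1).all()
        n_cols = [f"n_bin{b}" for b in range(1, 5)]
        assert (rec[n_cols].sum(axis=1) <= 120).all()
        assert (rec[n_cols] >= 0).all().all()

    def test_binned_anova_smoke(self, small_cohort):
        rec = cohort_recognition(small_cohort)
        table = binned_anova(rec).set_index("effect")
        assert {"group", "bin", "bin:group"} <= set(table.index)
        assert 0 < table.loc["bin", "epsilon"] <= 1

    def test_binned_interaction_detected_with_encoding_deficit(self):
        # implementer-chosen effect size: bin-1 deficit of 0.4 d' units
        weak = flat_agent(encoding_strength_by_bin=(0.6, 0.8, 0.65, 0.55))
        pops = {
            "clustered": [(weak, 1.0)],
            "non_clustered": [(flat_agent(), 1.0)],
        }
        cohort = simulate_cohort(30, pops, 2, seed=21)
        rec = cohort_recognition(cohort)
        table = binned_anova(rec).set_index("effect")
        assert table.loc["bin:group", "p"] < 0.05
        cl = rec.loc[rec["group"] == "clustered", "hit_bin1"].mean()
        ncl = rec.loc[rec["group"] == "non_clustered", "hit_bin1"].mean()
        assert ncl > cl

    def test_early_bins_pooling(self):
        pops = default_populations(("age", "gender"))
        summaries = {
            exp: cohort_recognition(simulate_cohort(8, pops, exp, seed=30 + exp))
            for exp in (2, 3)
        }
        table, t_rep = early_bins_comparison(summaries)
        assert "experiment" in set(table["effect"])
        assert t_rep.n == sum(len(s) for s in summaries.values())

    def test_early_bins_single_experiment_drops_factor(self):
        pops = default_populations(("age", "gender"))
        summaries = {2: cohort_recognition(simulate_cohort(8, pops, 2, seed=33))}
        table, _ = early_bins_comparison(summaries)
        assert "experiment" not in set(table["effect"])


class TestSourceMemory:
    def test_chance_source_memory_not_rejected(self):
        pops = default_populations(("color", "shape"))
        cohort = simulate_cohort(12, pops, 1, seed=41)
        out = source_memory_analysis(cohort)
        accs = out["cells"].filter(like="_old").to_numpy().mean()
        assert accs == pytest.approx(0.5, abs=0.05)

    def test_above_chance_source_memory_detected(self):
        good = flat_agent(source_accuracy=0.75)
        pops = {"clustered": [(good, 1.0)], "non_clustered": [(good, 1.0)]}
        cohort = simulate_cohort(15, pops, 1, seed=42)
        out = source_memory_analysis(cohort)
        assert all(rep.p < 0.01 for rep in out["chance"].values())

    def test_refuses_designs_without_source_questions(self, small_cohort):
        with pytest.raises(ValueError):
            source_memory_analysis(small_cohort)


class TestTransfer:
    def test_transfer_by_bin_interaction_direction(self):
        pops = default_populations(("age", "gender"))
        cohort = simulate_cohort(15, pops, 3, seed=51)
        table = transfer_analysis(cohort).set_index("effect")
        assert table.loc["transfer", "p"] < 0.05
        assert table.loc["transfer:time_bin", "p"] < 0.05

    def test_no_reset_limit_gives_null_transfer_effect(self):
        # instant learners recover immediately: no transfer cost remains
        instant = flat_agent(learn_tau=1e-9)
        pops = {"clustered": [(instant, 1.0)], "non_clustered": [(instant, 1.0)]}
        cohort = simulate_cohort(15, pops, 3, seed=52)
        table = transfer_analysis(cohort).set_index("effect")
        assert table.loc["transfer", "p"] > 0.01
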