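"""Mixed models, post-hoc contrasts and baseline characterization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from engagement_profiles.outcome_models import (
    MULTIPLICITY_CAVEAT,
    analyze_outcomes,
    anova_from_summary,
    characterize_profiles,
    fit_group_time_model,
    posthoc_group_at_time,
    posthoc_time_within_group,
)
from engagement_profiles.synthetic_data import (
    OutcomeEffectSpec,
    generate_outcomes,
)


def truth_frame(sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    i = 0
    for group, n in sizes.items():
        for _ in range(n):
            rows.append({"user_id": f"U{i:03d}", "group": group})
            i += 1
    return pd.DataFrame(rows)


def spec(shifts: dict[str, float], residual_sd=4.0, ri_sd=3.0,
         **kw) -> OutcomeEffectSpec:
    return OutcomeEffectSpec("Y", kw.pop("baseline_mean", 50.0), 0.0, shifts,
                             residual_sd=residual_sd,
                             random_intercept_sd=ri_sd, **kw)


class TestFitGroupTimeModel:
    def test_identical_groups_give_null_f(self):
        """Group B is a literal copy of group A: group/interaction F ~ 0."""
        truth = truth_frame({"A": 12})
        eff = [spec({"A": 3.0})]
        out = generate_outcomes(truth, effects=eff, seed=0)
        copy = out.copy()
        copy["user_id"] = copy["user_id"] + "x"
        copy["group"] = "B"
        res = fit_group_time_model(pd.concat([out, copy], ignore_index=True), "Y")
        assert res.f_tests["group"].f_stat == pytest.approx(0.0, abs=1e-8)
        assert res.f_tests["group:time"].f_stat == pytest.approx(0.0, abs=1e-8)

    def test_zero_residual_shift_recovered_exactly(self):
        truth = truth_frame({"A": 10, "B": 10})
        eff = [spec({"A": 5.0, "B": 5.0}, residual_sd=0.0, ri_sd=3.0)]
        out = generate_outcomes(truth, effects=eff, seed=0)
        res = fit_group_time_model(out, "Y")
        contrast = posthoc_time_within_group(res, "A")
        assert contrast.estimate == pytest.approx(5.0, abs=1e-6)

    def test_contrast_equals_cell_mean_difference(self):
        truth = truth_frame({"A": 20, "B": 15, "C": 10})
        out = generate_outcomes(
            truth, effects=[spec({"A": 1.0, "B": -2.0, "C": 4.0})], seed=3)
        res = fit_group_time_model(out, "Y")
        cells = res.cell_means.set_index(["group", "timepoint"])["mean"]
        for g in res.groups:
            contrast = posthoc_time_within_group(res, g)
            assert contrast.estimate == pytest.approx(
                cells[g, 6] - cells[g, 0], abs=1e-9)

    def test_zero_intercept_variance_matches_ols(self):
        """Balanced panel with no between-user variance: REML fixed effects
        coincide with ordinary least squares."""
        truth = truth_frame({"A": 15, "B": 15})
        out = generate_outcomes(
            truth, effects=[spec({"A": 2.0, "B": -1.0}, ri_sd=0.0)], seed=1)
        res = fit_group_time_model(out, "Y")
        sub = out[out.outcome_name == "Y"]
        gcodes = sub["group"].map(
            {g: i for i, g in enumerate(res.groups)}).to_numpy()
        tcodes = (sub["timepoint"] == 6).astype(int).to_numpy()
        cov = np.column_stack([
            sub.sex - sub.sex.mean(),
            sub.age - sub.age.mean(),
            np.log(sub.dup_days) - np.log(sub.dup_days).mean(),
        ])
        X = res.design.rows(gcodes, tcodes, cov)
        ols = sm.OLS(sub.value.to_numpy(), X).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params, atol=1e-6)

    def test_f_invariant_to_group_label_permutation(self):
        truth = truth_frame({"A": 20, "B": 12, "C": 9})
        out = generate_outcomes(
            truth, effects=[spec({"A": 0.0, "B": 3.0, "C": -2.0})], seed=5)
        res1 = fit_group_time_model(out, "Y")
        swapped = out.copy()
        swapped["group"] = swapped["group"].map({"A": "zzz", "B": "B", "C": "C"})
        res2 = fit_group_time_model(swapped, "Y")
        for term in ("group", "time", "group:time"):
            assert res1.f_tests[term].f_stat == pytest.approx(
                res2.f_tests[term].f_stat, rel=1e-8)

    def test_interaction_matches_change_score_anova(self):
        """With a balanced two-timepoint panel the group x time mixed-model
        F equals the exact one-way ANOVA on user change scores."""
        truth = truth_frame({"A": 25, "B": 14, "C": 11})
        out = generate_outcomes(
            truth, effects=[spec({"A": 0.0, "B": 1.0, "C": 6.0})], seed=6)
        res = fit_group_time_model(out, "Y")
        wide = out.pivot_table(index=["user_id", "group"], columns="timepoint",
                               values="value").reset_index()
        wide["chg"] = wide[6] - wide[0]
        F, _ = stats.f_oneway(
            *[wide.loc[wide.group == g, "chg"] for g in res.groups])
        test = res.f_tests["group:time"]
        assert test.f_stat == pytest.approx(F, rel=1e-5)
        assert test.df2 == pytest.approx(len(truth) - 3, rel=1e-6)

    def test_cis_contain_point_estimates(self):
        truth = truth_frame({"A": 15, "B": 15})
        out = generate_outcomes(truth, effects=[spec({"A": 0.0, "B": 2.0})],
                                seed=7)
        res = fit_group_time_model(out, "Y")
        cm = res.cell_means
        assert (cm.ci_low <= cm["mean"]).all()
        assert (cm["mean"] <= cm.ci_high).all()

    def test_missing_covariate_rows_dropped_and_counted(self):
        truth = truth_frame({"A": 12, "B": 12})
        out = generate_outcomes(truth, effects=[spec({"A": 0.0, "B": 0.0})],
                                seed=8)
        out.loc[out.index[:3], "dup_days"] = np.nan
        res = fit_group_time_model(out, "Y")
        assert res.n_dropped == 3
        assert res.n_obs == len(out[out.outcome_name == "Y"]) - 3

    def test_requires_two_groups_and_two_timepoints(self):
        truth = truth_frame({"A": 10})
        out = generate_outcomes(truth, effects=[spec({"A": 0.0})], seed=9)
        with pytest.raises(ValueError, match="two groups"):
            fit_group_time_model(out, "Y")
        truth2 = truth_frame({"A": 6, "B": 6})
        out2 = generate_outcomes(truth2, effects=[spec({"A": 0, "B": 0})],
                                 seed=9)
        with pytest.raises(ValueError, match="timepoints"):
            fit_group_time_model(out2[out2.timepoint == 0], "Y")

    def test_ancova_variant_reports_group_given_baseline(self):
        truth = truth_frame({"A": 20, "B": 20})
        out = generate_outcomes(truth, effects=[spec({"A": 0.0, "B": 6.0})],
                                seed=10)
        res = fit_group_time_model(out, "Y", baseline_covariate=True)
        assert "group|baseline" in res.f_tests
        assert res.f_tests["group|baseline"].p_value < 0.05


class TestPosthoc:
    def test_unknown_group_or_time_rejected(self):
        truth = truth_frame({"A": 10, "B": 10})
        out = generate_outcomes(truth, effects=[spec({"A": 0.0, "B": 0.0})],
                                seed=0)
        res = fit_group_time_model(out, "Y")
        with pytest.raises(ValueError, match="unknown group"):
            posthoc_time_within_group(res, "nope")
        with pytest.raises(ValueError, match="unknown timepoint"):
            posthoc_group_at_time(res, 12)

    def test_pairwise_contrasts_cover_all_group_pairs(self):
        truth = truth_frame({"A": 10, "B": 10, "C": 10})
        out = generate_outcomes(
            truth, effects=[spec({"A": 0.0, "B": 0.0, "C": 0.0})], seed=1)
        res = fit_group_time_model(out, "Y")
        contrasts = posthoc_group_at_time(res, 6)
        assert len(contrasts) == 3
        names = {c.name for c in contrasts}
        assert any("A - B" in n for n in names)

    def test_null_time_contrast_p_values_uniform(self):
        """Within-group change test: p uniform under a flat null (KS)."""
        truth = truth_frame({"A": 30, "B": 20})
        pvals = []
        for s in range(80):
            out = generate_outcomes(
                truth, effects=[spec({"A": 0.0, "B": 0.0})], seed=40_000 + s)
            res = fit_group_time_model(out, "Y")
            pvals.append(posthoc_time_within_group(res, "A").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCharacterization:
    @staticmethod
    def exact_moments(n, mean, sd, seed):
        x = np.random.default_rng(seed).normal(size=n)
        return (x - x.mean()) / x.std(ddof=1) * sd + mean

    def test_identical_means_give_zero_f(self):
        base = pd.DataFrame({
            "user_id": [f"U{i}" for i in range(9)],
            "score": [1.0, 2.0, 3.0] * 3,
        })
        labels = pd.DataFrame({"user_id": base.user_id,
                               "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3})
        res = characterize_profiles(base, labels, continuous=["score"])
        assert res.anova["score"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_summary_anova_matches_raw_data_oracle(self):
        """Summary-statistic F for the baseline negative-symptom pattern
        (groups 49/19/14, means 11.05/10.48/14.36, SDs 3.55/3.14/4.99)
        equals scipy's ANOVA on raw data constructed with those exact
        moments."""
        ns, means, sds = (49, 19, 14), (11.05, 10.48, 14.36), (3.55, 3.14, 4.99)
        groups = [self.exact_moments(n, m, s, i)
                  for i, (n, m, s) in enumerate(zip(ns, means, sds))]
        F_raw, p_raw = stats.f_oneway(*groups)
        F, df1, df2, p = anova_from_summary(ns, means, sds)
        assert F == pytest.approx(F_raw, rel=1e-10)
        assert (df1, df2) == (2, 79)
        assert p == pytest.approx(p_raw, rel=1e-9)

    def test_chi_square_matches_hand_computation(self):
        """2x3 table: chi2 = sum (O-E)^2/E with E from the margins."""
        base = pd.DataFrame({
            "user_id": [f"U{i}" for i in range(30)],
            "status": ["yes"] * 12 + ["no"] * 18,
        })
        labels = pd.DataFrame({
            "user_id": base.user_id,
            "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
        })
        res = characterize_profiles(base, labels, continuous=[],
                                    categorical=["status"])
        table = pd.crosstab(labels.group, base.status).to_numpy()
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = (((table - expected) ** 2) / expected).sum()
        assert res.chi_square["status"]["chi2"] == pytest.approx(hand, rel=1e-10)
        assert res.chi_square["status"]["df"] == 2

    def test_tukey_only_when_omnibus_significant(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame({
            "user_id": [f"U{i}" for i in range(60)],
            "flat": rng.normal(0, 1, 60),
            "shifted": np.concatenate([rng.normal(0, 1, 30),
                                       rng.normal(4, 1, 30)]),
        })
        labels = pd.DataFrame({"user_id": base.user_id,
                               "group": ["a"] * 30 + ["b"] * 30})
        res = characterize_profiles(base, labels,
                                    continuous=["flat", "shifted"])
        assert res.anova["shifted"]["tukey"] is not None
        assert res.anova["shifted"]["tukey"][0]["p"] < 0.05
        assert res.anova["flat"]["tukey"] is None

    def test_small_group_variable_skipped(self):
        base = pd.DataFrame({"user_id": ["U1", "U2", "U3"],
                             "score": [1.0, 2.0, 3.0]})
        labels = pd.DataFrame({"user_id": base.user_id,
                               "group": ["a", "a", "b"]})
        res = characterize_profiles(base, labels, continuous=["score"])
        assert "score" in res.skipped


@pytest.fixture(scope="module")
def cohort_outcomes():
    truth = truth_frame({"p0": 20, "p1": 15, "TAU": 18})
    eff = [
        OutcomeEffectSpec("PSP", 66.0, 0.0,
                          {"p0": 0.0, "p1": 10.0, "TAU": 1.0},
                          residual_sd=5.0, random_intercept_sd=5.0),
        OutcomeEffectSpec("CDSS", 4.0, 0.0,
                          {"p0": 0.0, "p1": 0.0, "TAU": 0.0},
                          residual_sd=2.0, random_intercept_sd=2.0),
    ]
    return generate_outcomes(truth, effects=eff, seed=21)


class TestAnalyzeOutcomes:
    def test_profiles_mode_structure(self, cohort_outcomes):
        res = analyze_outcomes(cohort_outcomes, mode="profiles")
        assert set(res["outcomes"]) == {"PSP", "CDSS"}
        psp = res["outcomes"]["PSP"]["profiles"]
        assert psp["f_tests"]["group:time"]["p"] < 0.05
        assert "posthoc_time_within_group" in psp
        assert res["caveat"] == MULTIPLICITY_CAVEAT

    def test_each_vs_tau_mode(self, cohort_outcomes):
        res = analyze_outcomes(cohort_outcomes, mode="each-vs-tau")
        assert set(res["outcomes"]["PSP"]) == {"p0", "p1"}
        assert res["outcomes"]["PSP"]["p1"]["groups"] == ["TAU", "p1"]

    def test_fdr_adjustment_reported(self, cohort_outcomes):
        res = analyze_outcomes(cohort_outcomes, mode="profiles", fdr=True)
        assert set(res["fdr_bh"]) == {"PSP/profiles", "CDSS/profiles"}
        raw = res["outcomes"]["CDSS"]["profiles"]["f_tests"]["group:time"]["p"]
        assert res["fdr_bh"]["CDSS/profiles"] >= raw - 1e-12

    def test_labels_override_groups(self, cohort_outcomes):
        relabel = cohort_outcomes[["user_id"]].drop_duplicates()
        rng = np.random.default_rng(1)
        relabel["group"] = np.where(rng.random(len(relabel)) < 0.5, "x", "y")
        res = analyze_outcomes(cohort_outcomes, labels=relabel,
                               mode="profiles")
        assert res["outcomes"]["PSP"]["profiles"]["groups"] == ["x", "y"]
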