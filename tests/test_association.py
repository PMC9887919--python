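"""Quartile assignment, logistic ORs, trend test, ANOVA/ANCOVA, chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbiso import association as a
from tests.conftest import make_2x2


class TestQuartiles:
    def test_printed_cutpoint_assignment(self):
        labels = a.assign_quartiles([60, 63, 64, 66, 70], a.QuartileScheme())
        assert list(labels) == ["Q1", "Q2", "Q2", "Q3", "Q4"]

    @pytest.mark.parametrize("score,expected", [(62.999, "Q1"), (63, "Q2"), (65, "Q3"), (68, "Q4")])
    def test_boundaries_right_inclusive_at_top(self, score, expected):
        assert list(a.assign_quartiles([score], a.QuartileScheme()))[0] == expected

    def test_all_below_first_cut(self):
        assert set(a.assign_quartiles([10, 20, 30], a.QuartileScheme())) == {"Q1"}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(65.12, 4.40, 500).clip(0, 90)
        labels = a.assign_quartiles(scores, a.QuartileScheme())
        assert len(labels) == len(scores) and not pd.isna(labels).any()
        counts = pd.Series(labels).value_counts()
        assert (counts > 0).all()  # non-degenerate at the calibrated score distribution

    def test_scores_above_max_rejected(self):
        with pytest.raises(ValueError):
            a.assign_quartiles([95.0], a.QuartileScheme(), max_valid=90.0)

    def test_data_driven_mode_uses_sample_quartiles(self):
        scores = np.arange(1.0, 101.0)
        scheme = a.QuartileScheme.from_scores(scores)
        assert scheme.cutpoints == (pytest.approx(25.75), pytest.approx(50.5), pytest.approx(75.25))

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            a.QuartileScheme((65.0, 63.0, 68.0))


class TestLogistic:
    def test_identical_odds_gives_or_one(self):
        df = make_2x2(10, 20, 10, 20)
        fit = a.fit_logistic(df["y"], df[["x"]])
        assert np.exp(fit.params["x"]) == pytest.approx(1.0, abs=1e-9)

    def test_mle_matches_cross_product_ratio(self):
        df = make_2x2(10, 20, 20, 10)
        fit = a.fit_logistic(df["y"], df[["x"]])
        assert np.exp(fit.params["x"]) == pytest.approx(0.25, abs=1e-6)

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 0, 0, 0], "x": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="both classes"):
            a.fit_logistic(df["y"], df[["x"]])

    def test_rank_deficiency_names_columns(self):
        df = make_2x2(10, 20, 20, 10)
        design = df[["x"]].assign(x_copy=df["x"])
        with pytest.raises(ValueError, match="x_copy"):
            a.fit_logistic(df["y"], design)

    def test_separation_flagged(self):
        df = make_2x2(15, 0, 0, 15)  # perfectly separated
        with pytest.warns(a.SeparationWarning):
            fit = a.fit_logistic(df["y"], df[["x"]])
        assert fit.separation

    def test_loglik_nesting(self, analyzed_cohort):
        """Richer adjustment sets cannot lower the maximized log-likelihood."""
        frames = {}
        for name in ("crude", "model1", "model2"):
            spec = a.MODEL_SPECS[name]
            cols = ["so", "hbi_quartile", *spec.covariates]
            frame = analyzed_cohort[cols].dropna()
            qdum = pd.get_dummies(frame["hbi_quartile"], prefix="q", drop_first=True, dtype=float)
            cov = a._dummy_code(frame, spec.covariates)
            fit = a.fit_logistic(frame["so"].astype(float), pd.concat([qdum, cov], axis=1))
            frames[name] = fit.llf
        assert frames["model2"] >= frames["model1"] - 1e-8 >= frames["crude"] - 2e-8


class TestOddsRatios:
    def test_closed_form_wald_interval(self):
        fit = a.LogisticFit(
            params=pd.Series({"const": 0.0, "x": 0.0}),
            bse=pd.Series({"const": 0.1, "x": 0.5}),
            llf=0.0, converged=True, separation=False, n=10, term_names=("x",),
        )
        res = a.odds_ratios(fit).loc["x"]
        assert res["or"] == pytest.approx(1.0)
        assert res["ci_low"] == pytest.approx(np.exp(-1.959964 * 0.5), abs=1e-3)
        assert res["ci_high"] == pytest.approx(np.exp(1.959964 * 0.5), abs=1e-3)
        assert (res["ci_low"], res["ci_high"]) == (pytest.approx(0.375, abs=5e-4), pytest.approx(2.664, abs=5e-4))
        assert res["p"] == pytest.approx(1.0)

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(1, 30, size=4)
            df = make_2x2(*counts)
            fit = a.fit_logistic(df["y"], df[["x"]])
            res = a.odds_ratios(fit).loc["x"]
            assert res["ci_low"] <= res["or"] <= res["ci_high"]

    def test_wider_se_wider_ci(self):
        def ci(se):
            fit = a.LogisticFit(pd.Series({"x": 0.3}), pd.Series({"x": se}), 0.0, True, False, 10, ("x",))
            r = a.odds_ratios(fit).loc["x"]
            return r["ci_high"] - r["ci_low"], r["or"]
        w1, or1 = ci(0.2)
        w2, or2 = ci(0.8)
        assert w2 > w1 and or1 == or2

    def test_nonconverged_refused(self):
        fit = a.LogisticFit(pd.Series({"x": 0.0}), pd.Series({"x": 1.0}), 0.0, False, False, 10, ("x",))
        with pytest.raises(ValueError, match="converge"):
            a.odds_ratios(fit)


class TestTrend:
    def test_strong_dose_response(self):
        rng = np.random.default_rng(2)
        score = rng.normal(65, 4.4, 2000)
        labels = a.assign_quartiles(score, a.QuartileScheme())
        logit = -3 + 0.15 * (score - 65)
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        assert a.p_trend(y, labels, score) < 0.001

    def test_two_quartiles_identical_proportions(self):
        y = np.array([1, 0, 1, 0] * 25)
        score = np.array([60.0, 60.0, 70.0, 70.0] * 25)
        labels = a.assign_quartiles(score, a.QuartileScheme())
        assert a.p_trend(y, labels, score) == pytest.approx(1.0, abs=1e-6)

    def test_single_quartile_rejected(self):
        y = np.array([0, 1] * 10)
        score = np.full(20, 60.0)
        labels = a.assign_quartiles(score, a.QuartileScheme())
        with pytest.raises(ValueError, match="two populated quartiles"):
            a.p_trend(y, labels, score)

    def test_null_rejection_rate_near_alpha(self):
        """With outcome independent of score, the trend p-value rejects at
        the nominal 5% rate (binomial check over 200 replicates)."""
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(200):
            score = rng.normal(65, 4.4, 400)
            labels = a.assign_quartiles(score, a.QuartileScheme())
            y = rng.binomial(1, 0.3, 400)
            rejections += a.p_trend(y, labels, score) < 0.05
        assert 3 <= rejections <= 21  # central 99.9% band of Binomial(200, 0.05)


class TestPercentReduction:
    @pytest.mark.parametrize("or_,expected", [(1.0, 0.0), (0.25, 75.0), (0.29, 71.0)])
    def test_arithmetic(self, or_, expected):
        assert a.percent_odds_reduction(or_) == pytest.approx(expected)

    def test_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            a.percent_odds_reduction(1.2)


class TestAnova:
    def test_equal_groups_f_zero(self):
        y = [1.0, 2.0, 3.0] * 4
        labels = ["Q1"] * 3 + ["Q2"] * 3 + ["Q3"] * 3 + ["Q4"] * 3
        f, p, _ = a.anova_across_quartiles(y, labels)
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_group_equals_t_squared(self):
        rng = np.random.default_rng(4)
        y1, y2 = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        f, p, _ = a.anova_across_quartiles(
            np.concatenate([y1, y2]), ["A"] * 30 + ["B"] * 25
        )
        t, tp = stats.ttest_ind(y1, y2)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(tp)

    def test_small_group_excluded_with_warning(self):
        y = [1.0, 2.0, 3.0, 4.0, 10.0]
        labels = ["A", "A", "B", "B", "C"]
        with pytest.warns(UserWarning, match="excluded"):
            f, p, summary = a.anova_across_quartiles(y, labels)
        assert list(summary.index) == ["A", "B"]


class TestAncova:
    def test_orthogonal_covariate_leaves_means_unchanged(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["Q1", "Q2", "Q3", "Q4"], 40)
        cov = np.tile(np.linspace(-1, 1, 40), 4)  # identical within each group
        y = rng.normal(0, 1, 160) + np.repeat([0.0, 0.5, 1.0, 1.5], 40)
        adj, _ = a.ancova_adjusted_means(y, labels, pd.DataFrame({"c": cov}))
        raw = pd.Series(y).groupby(pd.Series(labels)).mean()
        for g in raw.index:
            assert adj[g] == pytest.approx(raw[g], abs=1e-9)

    def test_confounded_design_recovers_structural_means(self):
        """Group effect 0 with a confounder that differs by group: adjusted
        means coincide; raw means do not."""
        rng = np.random.default_rng(6)
        labels = np.repeat(["Q1", "Q2"], 400)
        conf = np.concatenate([rng.normal(0, 1, 400), rng.normal(2, 1, 400)])
        y = 3.0 + 1.5 * conf + rng.normal(0, 0.5, 800)
        adj, p = a.ancova_adjusted_means(y, labels, pd.DataFrame({"conf": conf}))
        assert abs(adj["Q1"] - adj["Q2"]) < 0.15
        raw = pd.Series(y).groupby(pd.Series(labels)).mean()
        assert abs(raw["Q1"] - raw["Q2"]) > 2.0

    def test_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 120)
        labels = np.repeat(["Q1", "Q2", "Q3"], 40)
        _, p_ancova = a.ancova_adjusted_means(y, labels, None)
        _, p_anova, _ = a.anova_across_quartiles(y, labels)
        assert p_ancova == pytest.approx(p_anova, abs=1e-9)


class TestChiSquare:
    def test_proportional_table_is_independent(self):
        cat = ["a"] * 40 + ["b"] * 40
        labels = (["Q1"] * 20 + ["Q2"] * 20) * 2
        chi2, p = a.chi_square(cat, labels)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        cat = ["a"] * 30 + ["b"] * 30
        labels = ["Q1"] * 10 + ["Q2"] * 20 + ["Q1"] * 20 + ["Q2"] * 10
        chi2, p = a.chi_square(cat, labels)
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)  # sum (O-E)^2/E with E=15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            a.chi_square([], [])


class TestTables:
    def test_association_table_shape_and_invariants(self, analyzed_cohort):
        tab = a.association_table(analyzed_cohort, models=("crude", "model1"))
        assert set(tab["model"]) == {"crude", "model1"}
        assert list(tab["quartile"].unique()) == ["Q2", "Q3", "Q4"]
        ok = tab.dropna(subset=["or"])
        assert ((ok["ci_low"] <= ok["or"]) & (ok["or"] <= ok["ci_high"])).all()
        assert (ok["or"] > 0).all()

    def test_descriptive_table_runs(self, analyzed_cohort):
        tab = a.descriptive_table(
            analyzed_cohort, ["age", "bmi", "fm"], ["education", "marital"],
            ancova_covariates=["age", "bmi", "energy", "pa"],
        )
        cont = tab[tab["type"] == "continuous"]
        assert {"p_anova", "p_ancova"} <= set(cont.columns)
        assert cont[["p_anova", "p_ancova"]].notna().all().all()
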