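"""Statistical pipeline: splits, logistic models, ROC machinery, design aids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tddmri.prediction import (
    auc_mann_whitney,
    collinearity_screen,
    compare_groups,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    kfold_cv,
    multivariable_logistic,
    pearson_correlation,
    roc_auc,
    sample_size_auc,
    stratified_split,
    subgroup_eval,
    univariable_logistic,
    youden_cutoff,
)
from tddmri.simulate import assign_labels_logistic, generate_cohort


def brute_force_auc(scores, labels):
    """Pairwise concordance count with half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive scan over every possible >= threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cands = np.concatenate([np.unique(s), [s.min() - 1, s.max() + 1]])
    best = (-np.inf, -np.inf)
    for c in cands:
        pred = s >= c
        sens = np.sum(pred & (y == 1)) / y.sum()
        spec = np.sum(~pred & (y == 0)) / (len(y) - y.sum())
        best = max(best, (sens + spec - 1.0, spec))
    return best


class TestStratifiedSplit:
    def test_published_counts_reproduced(self):
        coh = generate_cohort(n=220, responder_fraction=151 / 220, seed=0)
        split = stratified_split(coh, 0.7, seed=0)
        train = coh[split == "training"]
        assert len(train) == 154
        assert len(coh) - len(train) == 66
        assert int(train.response.sum()) == 106
        assert int((1 - train.response).sum()) == 48

    def test_even_split_small_stratum(self):
        coh = pd.DataFrame({"response": [1] * 10})
        split = stratified_split(coh, 0.5, seed=1)
        assert (split == "training").sum() == 5

    def test_boundary_ratio_rejected(self):
        coh = generate_cohort(n=50, seed=1)
        for ratio in (0.0, 1.0):
            with pytest.raises(ValueError):
                stratified_split(coh, ratio, seed=0)

    def test_partition_properties(self):
        coh = generate_cohort(n=83, responder_fraction=0.6, seed=2)
        split = stratified_split(coh, 0.7, seed=3)
        assert set(split.unique()) == {"training", "test"}
        assert len(split) == len(coh)


class TestCompareGroups:
    def test_identical_groups_mann_whitney_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0, 9.0], 2)
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "v": vals})
        out = compare_groups(df, "v", group="g")
        if out["test"] == "mann-whitney":
            assert out["p"] == pytest.approx(1.0)
        else:
            assert out["p"] > 0.99

    def test_tsr_table_chi_square_value(self, table1_training):
        out = compare_groups(
            table1_training, "tsr", group="response", kind="categorical"
        )
        assert out["test"] == "chi2"
        assert out["statistic"] == pytest.approx(5.16, abs=0.005)
        assert out["p"] < 0.05

    def test_small_table_routed_to_fisher_enumeration(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 8 + ["b"] * 7,
                "v": ["x"] * 6 + ["y"] * 2 + ["x"] * 1 + ["y"] * 6,
            }
        )
        out = compare_groups(df, "v", group="g", kind="categorical")
        assert out["test"] == "fisher"
        # exhaustive hypergeometric enumeration of tables with fixed margins
        from math import comb

        k_obs = 6  # a∩x
        n_a, n_x, n = 8, 7, 15
        probs = {
            k: comb(n_x, k) * comb(n - n_x, n_a - k) / comb(n, n_a)
            for k in range(max(0, n_a + n_x - n), min(n_a, n_x) + 1)
        }
        p_exact = sum(p for k, p in probs.items() if p <= probs[k_obs] + 1e-12)
        assert out["p"] == pytest.approx(p_exact, rel=1e-9)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 3, "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(df, "v", group="g")


class TestLogisticModels:
    def test_tsr_univariable_or_from_table1(self, table1_training):
        rep = univariable_logistic(table1_training, "tsr")
        assert rep.reference == {"tsr": ">=50%"}
        row = rep.terms.loc["tsr[<50%]"]
        assert row["or"] == pytest.approx(2.22, abs=0.005)
        assert row["ci_low"] == pytest.approx(1.10, abs=0.01)
        assert row["ci_high"] == pytest.approx(4.45, abs=0.01)
        assert row["p"] < 0.05

    @given(
        a=st.integers(5, 40), b=st.integers(5, 40),
        c=st.integers(5, 40), d=st.integers(5, 40),
    )
    @settings(max_examples=15, deadline=None)
    def test_2x2_or_equals_cross_product_ratio(self, a, b, c, d):
        df = pd.DataFrame(
            {
                "response": [1] * (a + b) + [0] * (c + d),
                "x": ["hi"] * a + ["lo"] * b + ["hi"] * c + ["lo"] * d,
            }
        )
        rep = univariable_logistic(df, "x")
        if rep.separation:
            return
        term = rep.terms.index[0]
        level = term[term.index("[") + 1 : -1]
        other = "lo" if level == "hi" else "hi"
        def odds(lvl):
            sub = df[df.x == lvl]
            return sub.response.sum() / (len(sub) - sub.response.sum())
        expect = odds(level) / odds(other)
        assert rep.terms.loc[term, "or"] == pytest.approx(expect, rel=1e-6)

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"response": rng.integers(0, 2, 4000), "x": rng.normal(0, 1, 4000)}
        )
        rep = univariable_logistic(df, "x")
        assert rep.terms.loc["x", "or"] == pytest.approx(1.0, abs=0.1)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({"response": [0] * 5 + [1] * 5, "x": np.arange(10.0)})
        rep = univariable_logistic(df, "x")
        assert rep.separation

    def test_single_predictor_multivariable_matches_univariable(self, table1_training):
        uni = univariable_logistic(table1_training, "tsr")
        multi = multivariable_logistic(table1_training, ["tsr"])
        assert multi.terms["beta"].iloc[0] == pytest.approx(
            uni.terms["beta"].iloc[0], rel=1e-6
        )

    def test_multivariable_recovers_generative_coefficients(self):
        # labels generated by a logistic model at the published multivariable
        # effect sizes; estimates should recover them over replications
        beta_true = np.array([np.log(2.37), np.log(0.67)])
        errs = []
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            tsr_hi = rng.random(154) < 0.45
            cell = rng.normal(2.45, 0.7, 154)
            X = np.stack([tsr_hi.astype(float), cell - cell.mean()], axis=1)
            y = assign_labels_logistic(X, beta_true, intercept=0.8, seed=200 + s)
            if y.sum() in (0, len(y)):
                continue
            df = pd.DataFrame(
                {"response": y, "tsr_hi": X[:, 0], "cellularity": X[:, 1]}
            )
            rep = multivariable_logistic(df, ["tsr_hi", "cellularity"])
            errs.append(rep.terms["beta"].to_numpy() - beta_true)
        mean_err = np.abs(np.mean(errs, axis=0))
        assert (mean_err < 0.35).all()

    def test_wald_type_i_error_near_nominal(self):
        rejections = 0
        n_sim = 300
        for s in range(n_sim):
            rng = np.random.default_rng(5000 + s)
            df = pd.DataFrame(
                {
                    "response": rng.integers(0, 2, 120),
                    "x": rng.normal(0, 1, 120),
                }
            )
            rep = univariable_logistic(df, "x")
            if rep.terms.loc["x", "p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.09


class TestCollinearityScreen:
    def test_derived_cellularity_excludes_diameter(self):
        rng = np.random.default_rng(0)
        n = 400
        f_in = rng.normal(0.35, 0.005, n)  # nearly constant -> cell ≈ 35/d
        d = rng.normal(14.5, 1.5, n)
        df = pd.DataFrame(
            {"d": d, "cellularity": 100 * f_in / d, "x": rng.normal(size=n)}
        )
        retained, log = collinearity_screen(df, ["d", "cellularity", "x"])
        excluded = {e["excluded"] for e in log}
        assert "d" in excluded or "cellularity" in excluded
        assert "x" in retained

    def test_orthogonal_predictors_untouched(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=["a", "b", "c"])
        retained, log = collinearity_screen(df, ["a", "b", "c"])
        assert retained == ["a", "b", "c"] and log == []

    def test_duplicate_column_removed_second_by_order(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"a": x, "b": rng.normal(0, 1, 100), "a2": x})
        retained, log = collinearity_screen(df, ["a", "b", "a2"])
        assert retained == ["a", "b"]
        assert log[0]["excluded"] == "a2"


class TestROC:
    def test_tiny_example_with_tie(self):
        assert auc_mann_whitney([2, 4, 2, 3], [1, 1, 0, 0]) == pytest.approx(0.625)

    def test_perfect_and_null(self):
        assert auc_mann_whitney([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 5000)
        y = rng.integers(0, 2, 5000)
        assert auc_mann_whitney(s, y) == pytest.approx(0.5, abs=0.03)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 50)
        s = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        assert auc_mann_whitney(s, y) == pytest.approx(
            brute_force_auc(s, y), abs=1e-12
        )

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        s = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
        y = np.array([1] * 60 + [0] * 60)
        a, (lo, hi) = roc_auc(s, y, n_boot=400, seed=1)
        assert lo < a < hi
        assert hi - lo < 0.35

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_z_zero(self):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.7])
        y = np.array([0, 0, 1, 1, 1])
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_informative_vs_noise_detected(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 150 + [0] * 150)
        good = y + rng.normal(0, 0.5, 300)
        noise = rng.normal(0, 1, 300)
        z, p = delong_test(good, noise, y)
        assert p < 1e-4

    def test_consistent_with_paired_bootstrap_oracle(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 40 + [0] * 40)
        sa = y + rng.normal(0, 1.0, 80)
        sb = y + rng.normal(0, 1.3, 80)
        z, p = delong_test(sa, sb, y)
        # paired bootstrap of the AUC difference
        diffs = []
        for _ in range(600):
            idx = np.concatenate(
                [rng.choice(40, 40), 40 + rng.choice(40, 40)]
            )
            yi = y[idx]
            diffs.append(auc_mann_whitney(sa[idx], yi) - auc_mann_whitney(sb[idx], yi))
        se_boot = np.std(diffs, ddof=1)
        d_obs = auc_mann_whitney(sa, y) - auc_mann_whitney(sb, y)
        z_boot = d_obs / se_boot
        assert z == pytest.approx(z_boot, abs=0.75)


class TestYouden:
    def test_perfectly_separated(self):
        out = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
        assert out["youden"] == pytest.approx(1.0)
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            assert out[k]["value"] == 1.0

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 50)
        s = np.round(rng.normal(0, 1, n), 1)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        out = youden_cutoff(s, y)
        j_best, spec_best = brute_force_youden(s, y)
        assert out["youden"] == pytest.approx(j_best, abs=1e-12)
        assert out["specificity"]["value"] == pytest.approx(spec_best, abs=1e-12)

    def test_confusion_matrix_margins_and_fractions(self):
        rng = np.random.default_rng(10)
        y = np.array([1] * 106 + [0] * 48)
        s = y * 0.8 + rng.normal(0, 0.5, 154)
        out = youden_cutoff(s, y)
        cm = out["confusion"]
        assert cm["tp"] + cm["fn"] == 106
        assert cm["tn"] + cm["fp"] == 48
        assert out["sensitivity"]["value"] == pytest.approx(cm["tp"] / 106)
        assert out["ppv"]["num"] == cm["tp"]
        assert out["ppv"]["den"] == cm["tp"] + cm["fp"]


class TestHosmerLemeshow:
    def test_constant_probability_computable(self):
        y = np.array([1] * 30 + [0] * 70)
        p = np.full(100, 0.3)
        stat, pval, groups = hosmer_lemeshow(p, y)
        assert np.isfinite(stat) and 0 <= pval <= 1

    def test_miscalibration_detected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 800)
        p_true = 1 / (1 + np.exp(-x))
        y = (rng.random(800) < p_true).astype(int)
        p_shift = 1 / (1 + np.exp(-(x + 1.0)))
        stat_good, p_good, _ = hosmer_lemeshow(p_true, y)
        stat_bad, p_bad, _ = hosmer_lemeshow(p_shift, y)
        assert stat_bad > stat_good
        assert p_bad < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 10), np.tile([0, 1], 5))


class TestDecisionCurve:
    def test_treat_all_zero_at_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        p = np.linspace(0.01, 0.99, 100)
        dc = decision_curve(p, y, thresholds=[0.3])
        assert dc["treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_net_benefit(self):
        # TP=80, FP=11 of n=154 at p_t=0.5 -> NB = 80/154 − 11/154
        p = np.array([0.9] * 91 + [0.1] * 63)
        y = np.array([1] * 80 + [0] * 11 + [1] * 26 + [0] * 37)
        dc = decision_curve(p, y, thresholds=[0.5])
        assert dc["net_benefit"].iloc[0] == pytest.approx(80 / 154 - 11 / 154)

    def test_perfect_predictor_plateau(self):
        y = np.array([1] * 40 + [0] * 60)
        p = y.astype(float) * 0.98 + 0.01
        dc = decision_curve(p, y, thresholds=np.linspace(0.05, 0.9, 10))
        assert np.allclose(dc["net_benefit"], 0.4)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5, 0.5], [0, 1], thresholds=[0.0])


class TestCrossValidationAndSubgroups:
    def test_fold_sizes_220_by_5(self):
        coh = generate_cohort(n=220, seed=0)
        out = kfold_cv(coh, ["cellularity"], k=5, seed=0)
        assert len(out["fold_auc"]) == 5

    def test_null_predictor_cv_auc_near_half(self):
        coh = generate_cohort(n=400, effect_scale=0.0, seed=5)
        out = kfold_cv(coh, ["age"], k=5, seed=1)
        assert out["mean_auc"] == pytest.approx(0.5, abs=0.1)

    def test_cv_auc_below_resubstitution(self):
        aucs_cv, aucs_in = [], []
        for s in range(5):
            coh = generate_cohort(n=220, seed=30 + s)
            rep = multivariable_logistic(coh, ["tsr", "cellularity"])
            aucs_in.append(auc_mann_whitney(rep.probabilities, coh.response))
            aucs_cv.append(
                kfold_cv(coh, ["tsr", "cellularity"], k=5, seed=s)["mean_auc"]
            )
        assert np.mean(aucs_cv) < np.mean(aucs_in)
        assert np.mean(aucs_cv) > 0.52

    def test_k_exceeding_minority_rejected(self):
        coh = generate_cohort(n=30, responder_fraction=0.9, seed=2)
        with pytest.raises(ValueError):
            kfold_cv(coh, ["cellularity"], k=10, seed=0)

    def test_whole_cohort_subgroup_equals_overall(self):
        coh = generate_cohort(n=220, seed=3)
        rep = multivariable_logistic(coh, ["cellularity"])
        coh2 = coh.assign(all="everyone")
        tab = subgroup_eval(coh2, rep.probabilities, "response", ["all"])
        assert tab["auc"].iloc[0] == pytest.approx(
            auc_mann_whitney(rep.probabilities, coh.response)
        )

    def test_single_class_subgroup_skipped(self):
        coh = generate_cohort(n=100, seed=4).copy()
        coh["flag"] = "a"
        coh.loc[coh.index[:3], "flag"] = "b"
        coh.loc[coh.index[:3], "response"] = 1
        rep = multivariable_logistic(coh, ["cellularity"])
        tab = subgroup_eval(coh, rep.probabilities, "response", ["flag"])
        assert tab.loc[tab.level == "b", "auc"].isna().all()


class TestDesignAids:
    def test_published_design_inputs_give_printed_scale_n(self):
        n = sample_size_auc(0.50, 0.75, 0.70, alpha=0.05, power=0.90)
        assert abs(n - 59) <= 3

    def test_monotone_in_power_and_effect(self):
        n_lo = sample_size_auc(0.5, 0.75, 0.7, power=0.5)
        n_hi = sample_size_auc(0.5, 0.75, 0.7, power=0.9)
        assert n_hi >= n_lo
        n_big_effect = sample_size_auc(0.5, 0.90, 0.7, power=0.9)
        assert n_big_effect < n_hi

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_auc(0.8, 0.7, 0.5)

    def test_pearson_trivial_cases(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 3)[0] == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            pearson_correlation(x, np.ones(4))

    def test_copula_generator_correlation_recovered(self):
        from tddmri.simulate import generate_histology_pairs

        coh = generate_cohort(n=220, seed=9)
        pairs = generate_histology_pairs(coh, seed=9)
        r, p = pearson_correlation(pairs["imaging_d"], pairs["histology_d"])
        z = np.arctanh(0.67)
        band = (np.tanh(z - 1.96 / np.sqrt(94)), np.tanh(z + 1.96 / np.sqrt(94)))
        assert band[0] <= r <= band[1]
        assert p < 0.05
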