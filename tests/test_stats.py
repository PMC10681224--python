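"""Statistical battery: grouping, ANOVA oracles, effect sizes, ICC, fits."""

import numpy as np
import pandas as pd
import pytest

from squatkin.stats import (
    assign_groups,
    boxplot_outliers,
    effect_size_label,
    eta_p2,
    eta_p2_ci,
    gg_epsilon,
    homogeneity_checks,
    icc_category,
    icc_test_retest,
    mixed_anova,
    velocity_regression,
)


def make_table(rng, n_low=10, n_high=11, cond_effect=0.0, group_effect=0.0,
               inter_effect=0.0, subj_sd=1.0, noise_sd=1.0):
    """Long-format 2x2 mixed-design table with known effects."""
    rows = []
    for i in range(n_low + n_high):
        group = "low" if i < n_low else "high"
        subj = rng.normal(0, subj_sd)
        for cond in ("nonfatigue", "fatigue"):
            mu = subj
            if cond == "fatigue":
                mu += cond_effect
            if group == "high":
                mu += group_effect
                if cond == "fatigue":
                    mu += inter_effect
            rows.append((f"P{i:02d}", group, cond, mu + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["participant_id", "group", "condition",
                                       "value"])


def anova_f_oracle(df):
    """Brute-force split-plot F values via least-squares projections.

    Independent of the cell-mean implementation: each sum of squares is
    a residual-sum difference between nested OLS fits (subject dummies
    absorb the between structure; the between part is fit on subject
    means).
    """
    piv = df.pivot_table(index="participant_id", columns="condition",
                         values="value")
    y = df["value"].to_numpy()
    subj = pd.get_dummies(df["participant_id"]).to_numpy(float)
    cond = pd.get_dummies(df["condition"]).to_numpy(float)[:, :1]
    grp = pd.get_dummies(df["group"]).to_numpy(float)[:, :1]
    inter = cond * grp

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_s = rss(subj)
    rss_sc = rss(np.hstack([subj, cond]))
    rss_full = rss(np.hstack([subj, cond, inter]))
    ss_cond = rss_s - rss_sc
    ss_inter = rss_sc - rss_full
    ss_err = rss_full

    means = piv.mean(axis=1).to_numpy()
    groups = df.groupby("participant_id")["group"].first()
    Xg = pd.get_dummies(groups).to_numpy(float)
    one = np.ones((len(means), 1))

    def rss_m(X):
        beta, *_ = np.linalg.lstsq(X, means, rcond=None)
        r = means - X @ beta
        return float(r @ r)

    k = piv.shape[1]
    ss_group = k * (rss_m(one) - rss_m(Xg))
    ss_subjw = k * rss_m(Xg)
    N, G = len(means), 2
    F_group = (ss_group / (G - 1)) / (ss_subjw / (N - G))
    df_err = (N - G) * (k - 1)
    F_cond = (ss_cond / (k - 1)) / (ss_err / df_err)
    F_inter = (ss_inter / (G - 1) / (k - 1)) / (ss_err / df_err)
    return {"group": F_group, "condition": F_cond, "interaction": F_inter}


class TestAssignGroups:
    def test_odd_cohort_splits_ten_eleven(self, rng):
        vals = np.round(np.sort(rng.uniform(32.0, 36.63, 21)), 2)
        labels = assign_groups({f"P{i}": v for i, v in enumerate(vals)})
        counts = pd.Series(labels).value_counts()
        assert counts["low"] == 10 and counts["high"] == 11
        # every low LLMR is below every high LLMR
        lo = max(v for k, v in zip(labels, vals) if labels[k] == "low")
        hi = min(v for k, v in zip(labels, vals) if labels[k] == "high")
        assert lo <= hi
        assert float(np.ptp(vals)) == pytest.approx(vals[-1] - vals[0])

    def test_two_participants_one_each(self):
        assert sorted(assign_groups({"a": 33.0, "b": 35.0}).values()) == [
            "high", "low",
        ]

    def test_tie_at_cut_warns_but_is_deterministic(self):
        with pytest.warns(UserWarning, match="ties"):
            labels = assign_groups({"a": 33.0, "b": 33.0, "c": 33.0, "d": 35.0})
        assert labels == {"a": "low", "b": "low", "c": "high", "d": "high"}


class TestBoxplotOutliers:
    def test_gross_outlier_flagged(self):
        mask = boxplot_outliers([1, 2, 3, 4, 100])
        assert list(mask) == [False, False, False, False, True]

    def test_identical_values_unflagged(self):
        assert not boxplot_outliers(np.full(10, 5.0)).any()

    def test_normal_flag_rate_near_0_7_percent(self, rng):
        x = rng.standard_normal(1000)
        rate = boxplot_outliers(x).mean()
        assert 0.001 <= rate <= 0.015  # asymptotic rate of the 1.5 IQR rule


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_random_designs(self):
        """Cell-mean SS decomposition == OLS projection oracle, 100 designs."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            df = make_table(
                rng,
                n_low=int(rng.integers(2, 7)),
                n_high=int(rng.integers(2, 7)),
                cond_effect=rng.normal(),
                group_effect=rng.normal(),
                inter_effect=rng.normal(),
            )
            ours = {r.effect: r.F for r in mixed_anova(df, compute_ci=False)}
            oracle = anova_f_oracle(df)
            for eff in ("group", "condition", "interaction"):
                assert ours[eff] == pytest.approx(oracle[eff], abs=1e-8, rel=1e-8)

    def test_matches_pingouin_cross_check(self, rng):
        import pingouin as pg

        df = make_table(rng, n_low=5, n_high=6, cond_effect=0.4)
        ours = {r.effect: r for r in mixed_anova(df)}
        ref = pg.mixed_anova(
            data=df, dv="value", within="condition", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours["condition"].F == pytest.approx(ref.loc["condition", "F"],
                                                    rel=1e-9)
        assert ours["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert ours["condition"].eta_p2 == pytest.approx(
            ref.loc["condition", "np2"], rel=1e-9
        )

    def test_eta_identity_holds_for_every_effect(self, rng):
        df = make_table(rng, cond_effect=0.5, group_effect=0.3)
        for r in mixed_anova(df):
            assert r.eta_p2 == pytest.approx(
                r.F * r.df1 / (r.F * r.df1 + r.df2), rel=1e-12
            )

    def test_two_level_within_epsilon_is_one(self, rng, caplog):
        df = make_table(rng)
        with caplog.at_level("INFO", logger="squatkin.stats"):
            res = mixed_anova(df)
        assert "epsilon = 1" in caplog.text
        assert {r.gg_epsilon for r in res if r.gg_epsilon is not None} == {1.0}
        X = rng.normal(size=(12, 2))
        assert gg_epsilon(X) == pytest.approx(1.0)

    def test_zero_noise_null_is_degenerate_f_zero(self):
        rows = []
        for i in range(6):
            g = "low" if i < 3 else "high"
            for c in ("nonfatigue", "fatigue"):
                rows.append((f"P{i}", g, c, 1.0 + i))
        df = pd.DataFrame(rows, columns=["participant_id", "group", "condition",
                                         "value"])
        with pytest.warns(UserWarning, match="zero residual"):
            res = {r.effect: r for r in mixed_anova(df)}
        assert res["condition"].F == 0.0

    def test_unbalanced_tiny_group_rejected(self, rng):
        df = make_table(rng, n_low=1, n_high=5)
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova(df)

    def test_type_one_error_rate_near_nominal(self):
        """Null condition effect rejects at ~5% over 1000 cohorts."""
        rng = np.random.default_rng(101)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            df = make_table(rng)
            res = {r.effect: r for r in mixed_anova(df, compute_ci=False)}
            rejections += res["condition"].p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F, expected", [(13.88, 0.42), (3.72, 0.16), (7.29, 0.27), (4.18, 0.18)]
    )
    def test_eta_p2_from_f_ratio(self, F, expected):
        # printed-precision slack: tables round from unrounded F values
        assert eta_p2(F, 1, 19) == pytest.approx(expected, abs=0.01)

    def test_ci_brackets_reference_interval(self):
        lo, hi = eta_p2_ci(13.88, 1, 19, 0.90)
        assert lo == pytest.approx(0.129, abs=0.005)
        assert hi == pytest.approx(0.599, abs=0.005)

    def test_ci_degenerate_and_nested(self):
        assert eta_p2_ci(0.0, 1, 19) == (0.0, 0.0)
        lo90, hi90 = eta_p2_ci(5.0, 1, 19, 0.90)
        lo95, hi95 = eta_p2_ci(5.0, 1, 19, 0.95)
        assert lo95 <= lo90 and hi95 >= hi90
        with pytest.raises(ValueError):
            eta_p2_ci(5.0, 1, 19, 1.5)

    def test_size_labels(self):
        assert effect_size_label(0.02) == "small"
        assert effect_size_label(0.10) == "medium"
        assert effect_size_label(0.42) == "large"


class TestICC:
    def test_identical_pairs_icc_one_excellent(self):
        x = np.arange(10.0)
        res = icc_test_retest(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_independent_pairs_icc_near_zero(self, rng):
        pairs = rng.standard_normal((1000, 2))
        res = icc_test_retest(pairs)
        assert abs(res.icc) < 0.07

    def test_boundary_categories(self):
        assert icc_category(0.80) == "good"
        assert icc_category(0.75) == "good"
        assert icc_category(0.49) == "poor"
        assert icc_category(0.95) == "excellent"

    def test_degenerate_and_short_inputs(self):
        res = icc_test_retest(np.full((5, 2), 3.0))
        assert res.category == "undefined" and np.isnan(res.icc)
        with pytest.raises(ValueError):
            icc_test_retest(np.zeros((2, 2)))


class TestVelocityRegression:
    def test_perfect_line(self):
        x = np.linspace(0.5, 1.5, 20)
        res = velocity_regression(x, x)
        assert res.r2_linear == pytest.approx(1.0)
        assert res.r2_poly == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_quadratic_data_prefers_polynomial(self):
        x = np.linspace(0.5, 1.5, 30)
        y = x**2
        res = velocity_regression(x, y)
        assert res.r2_poly == pytest.approx(1.0, abs=1e-9)
        assert res.r2_poly > res.r2_linear

    def test_pearson_r_squared_equals_linear_r2(self, rng):
        x = rng.uniform(0.4, 1.2, 40)
        y = 0.8 * x + rng.normal(0, 0.05, 40)
        res = velocity_regression(x, y)
        assert res.pearson_r**2 == pytest.approx(res.r2_linear, rel=1e-9)

    def test_nested_fits_property(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 1, 15)
            y = rng.normal(size=15)
            res = velocity_regression(x, y)
            assert res.r2_poly >= res.r2_linear - 1e-12

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            velocity_regression(np.ones(10), np.arange(10.0))


class TestHomogeneity:
    def test_null_levene_p_uniform(self):
        """Equal-variance groups: Levene p-values are uniform (KS check)."""
        from scipy import stats as sps

        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(500):
            a, b = rng.standard_normal((2, 20))
            pvals.append(sps.levene(a, b, center="mean").pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_variance_ratio_detected(self, rng):
        rows = []
        for i in range(40):
            g = "low" if i < 20 else "high"
            sd = 1.0 if g == "low" else 10.0
            for c in ("nonfatigue", "fatigue"):
                rows.append((f"P{i}", g, c, rng.normal(0, sd)))
        df = pd.DataFrame(rows, columns=["participant_id", "group", "condition",
                                         "value"])
        rep = homogeneity_checks(df)
        assert all(v["p"] < 0.01 for v in rep["levene"].values())

    def test_identical_groups_box_m_near_zero(self, rng):
        base = rng.standard_normal((10, 2))
        rows = []
        for g, offset in (("low", 0), ("high", 10)):
            for i in range(10):
                for j, c in enumerate(("nonfatigue", "fatigue")):
                    rows.append((f"{g}{i + offset}", g, c, base[i, j]))
        df = pd.DataFrame(rows, columns=["participant_id", "group", "condition",
                                         "value"])
        rep = homogeneity_checks(df)
        assert rep["box_m"]["Chi2"] == pytest.approx(0.0, abs=1e-8)
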