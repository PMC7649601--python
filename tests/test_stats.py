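import numpy as np
import pytest
import scipy.stats as sps

from bracemech import (
    TukeyLadderTransformer,
    normalize_if_needed,
    one_way_anova,
    pearson,
    repeatability,
    simulate_line_means,
    simulate_repeat_slopes,
    tukey_hsd,
    tukey_ladder,
    two_predictor_regression,
    two_way_anova,
)
from bracemech.errors import DegenerateFitError, InsufficientDataError, SingularDesignError
from bracemech.stats import repeatability_point


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(0)
        r, _ = pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateFitError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_all_constant_degenerate(self):
        with pytest.raises(DegenerateFitError):
            one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})

    def test_zero_within_variance_limit(self):
        f, p = one_way_anova({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        assert f == np.inf
        assert p == 0.0

    def test_group_too_small(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_agrees_with_permutation_oracle_on_rank_order(self):
        """Parametric ANOVA p-values rank identically to a permutation oracle.

        Three small datasets (k = 3, n = 5) with increasing group shifts.
        """
        rng = np.random.default_rng(1)
        shifts = [0.0, 1.0, 3.0]
        p_param, p_perm = [], []
        for s in shifts:
            groups = {f"g{i}": rng.normal(i * s, 1.0, size=5) for i in range(3)}
            f_obs, p = one_way_anova(groups)
            p_param.append(p)
            pooled = np.concatenate(list(groups.values()))
            labels = np.repeat(np.arange(3), 5)
            count = 0
            n_perm = 2000
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                f = sps.f_oneway(*(pooled[perm == i] for i in range(3))).statistic
                count += f >= f_obs
            p_perm.append((count + 1) / (n_perm + 1))
        assert np.argsort(p_param).tolist() == np.argsort(p_perm).tolist()

    def test_two_way_additive_main_effects(self):
        rng = np.random.default_rng(2)
        a = np.repeat(["x", "y"], 30)
        b = np.tile(np.repeat(["m", "n", "o"], 10), 2)
        y = rng.normal(size=60) + (a == "y") * 2.0  # only factor a matters
        table = two_way_anova(y, a, b)
        assert table.loc["C(a)", "PR(>F)"] < 1e-6
        assert table.loc["C(b)", "PR(>F)"] > 0.05


class TestTukeyHSD:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        p_tukey = tukey_hsd({"a": a, "b": b})["p_adj"].iloc[0]
        p_t = sps.ttest_ind(a, b).pvalue
        assert p_tukey == pytest.approx(p_t, rel=1e-6)

    def test_label_permutation_permutes_rows_only(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [5.0, 6.0, 7.0]}
        t1 = tukey_hsd(groups)
        t2 = tukey_hsd({"c": groups["c"], "a": groups["a"], "b": groups["b"]})
        m1 = {frozenset((r.group1, r.group2)): r.p_adj for r in t1.itertuples()}
        m2 = {frozenset((r.group1, r.group2)): r.p_adj for r in t2.itertuples()}
        assert m1 == pytest.approx(m2)

    def test_shifted_group_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
                  "c": rng.normal(2.0, 1, 20)}
        table = tukey_hsd(groups)
        worst = table.sort_values("p_adj").iloc[0]
        assert {worst.group1, worst.group2} != {"a", "b"}
        # direct studentized-range oracle for the a-b pair
        vals = list(groups.values())
        n, k = 20, 3
        mse = np.mean([np.var(v, ddof=1) for v in vals])
        q = abs(np.mean(vals[0]) - np.mean(vals[1])) / np.sqrt(mse / n)
        p_direct = sps.studentized_range.sf(q, k, k * (n - 1))
        row_ab = table[(table.group1 == "a") & (table.group2 == "b")]
        assert row_ab["p_adj"].iloc[0] == pytest.approx(p_direct, rel=1e-6)


class TestRepeatability:
    def test_zero_within_variance_gives_one(self):
        vals = [1.0, 1.0, 5.0, 5.0, 9.0, 9.0]
        ids = ["a", "a", "b", "b", "c", "c"]
        assert repeatability_point(vals, ids) == pytest.approx(1.0)

    def test_null_data_ci_covers_zero(self):
        df = simulate_repeat_slopes(50, 3, variance_share=0.0, seed=4)
        res = repeatability(df["k_true"], df["plant_id"], n_boot=300, n_permute=300, seed=5)
        assert res.ci_low <= 0.05  # R in [0,1]; interval must reach (essentially) 0
        assert res.p_value > 0.05

    def test_affine_invariance(self):
        df = simulate_repeat_slopes(20, 3, variance_share=0.7, seed=6)
        r1 = repeatability_point(df["k_true"], df["plant_id"])
        r2 = repeatability_point(5.0 * df["k_true"] - 100.0, df["plant_id"])
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_recovers_design_variance_share(self):
        df = simulate_repeat_slopes(200, 4, variance_share=0.6, seed=7)
        assert repeatability_point(df["k_true"], df["plant_id"]) == pytest.approx(0.6, abs=0.08)

    def test_strong_grouping_detected(self):
        df = simulate_repeat_slopes(23, 3, variance_share=0.876, seed=8)
        res = repeatability(df["k_true"], df["plant_id"], n_boot=500, n_permute=500, seed=9)
        assert res.ci_low <= res.R <= res.ci_high
        assert res.p_value < 0.01
        assert res.SE < 0.15

    def test_too_few_groups(self):
        with pytest.raises(InsufficientDataError):
            repeatability([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestTukeyLadder:
    def test_gaussian_data_selects_identity_power(self):
        rng = np.random.default_rng(11)
        t = tukey_ladder(rng.normal(50, 5, size=200))
        assert abs(t.lam - 1.0) <= 0.1

    def test_lognormal_data_recovers_log(self):
        rng = np.random.default_rng(12)
        t = tukey_ladder(np.exp(rng.normal(size=200)))
        assert abs(t.lam) <= 0.1

    def test_identity_power_matches_raw_shapiro(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(2.0, size=100)
        t = tukey_ladder(x, grid=np.array([1.0]))
        assert t.W == pytest.approx(sps.shapiro(x).statistic)
        assert np.allclose(t.transformed, x)

    def test_never_below_identity_W(self):
        rng = np.random.default_rng(14)
        x = rng.gamma(1.5, size=150)
        assert tukey_ladder(x).W >= sps.shapiro(x).statistic

    def test_gate_directions(self):
        rng = np.random.default_rng(15)
        skewed = rng.lognormal(size=150)
        out_lt, res_lt = normalize_if_needed(skewed, normalize_when="p_lt")
        assert res_lt is not None  # normality rejected -> transformed
        normal = rng.normal(50.0, 5.0, size=150)
        out_def, res_def = normalize_if_needed(normal, normalize_when="p_lt")
        assert res_def is None and np.allclose(out_def, normal)
        _, res_ge = normalize_if_needed(normal, normalize_when="p_ge")
        assert res_ge is not None  # literal gate transforms normal data

    def test_transformer_roundtrip(self):
        rng = np.random.default_rng(16)
        x = rng.lognormal(size=120)
        tf = TukeyLadderTransformer().fit(x)
        assert tf.lambda_ != 1.0
        out = tf.transform(x)
        assert out.shape == x.shape
        assert sps.shapiro(out).pvalue > sps.shapiro(x).pvalue


class TestTwoPredictorRegression:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(20)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = 3.0 + 2.0 * x1 - 1.0 * x2
        res = two_predictor_regression(y, x1, x2)
        assert (res["b0"], res["b1"], res["b2"]) == pytest.approx((3.0, 2.0, -1.0))
        assert res["r_squared"] == pytest.approx(1.0)

    def test_collinear_predictors_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(SingularDesignError):
            two_predictor_regression(x, x, 2 * x)

    def test_sign_recovery_with_correlated_predictors(self):
        """Line-mean design (n = 26, predictor r = 0.8, +DTS/-PH effects):
        both coefficient signs recovered in >= 95% of replicates."""
        hits = 0
        n_rep = 500
        for i in range(n_rep):
            df = simulate_line_means(seed=1000 + i)
            res = two_predictor_regression(df["fd_slope"], df["dts"], df["ph"])
            hits += res["b1"] > 0 and res["b2"] < 0
        assert hits / n_rep >= 0.95
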