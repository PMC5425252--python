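"""Group-level statistics: ANOVA, t-tests, ANCOVA, mixed ANOVA, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import invgamma

from metacog.inference import (
    ancova_group_effect,
    bayes_factor_t,
    bf01_from_t,
    mixed_anova_confidence,
    one_way_anova,
    two_sample_t,
)


class TestOneWayAnova:
    def test_hand_computed_anova_table(self):
        # 3 groups x 3 values: SS_b = 24, SS_w = 6 -> F = 12, eta2 = 0.8
        values = [1, 2, 3, 3, 4, 5, 5, 6, 7]
        group = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r = one_way_anova(values, group)
        assert r.statistic == pytest.approx(12.0)
        assert r.df == (2, 6)
        assert r.p == pytest.approx(stats.f.sf(12.0, 2, 6))
        assert r.effect_size == pytest.approx(24.0 / 30.0)

    def test_equal_group_means_give_zero_f(self):
        values = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        group = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r = one_way_anova(values, group)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        group = np.repeat(["a", "b", "c"], 10)
        r = one_way_anova(values, group)
        ref = stats.f_oneway(*(values[group == g] for g in "abc"))
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestTwoSampleT:
    def test_identical_samples_give_zero(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.effect_size == 0.0

    def test_hand_computation_with_unit_pooled_sd(self):
        r = two_sample_t([1, 2, 3], [2, 3, 4])
        assert r.statistic == pytest.approx(-1 / np.sqrt(2 / 3))
        assert r.df == (4,)
        assert r.effect_size == pytest.approx(-1.0)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, size=20)
        r = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_two_group_anova_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(0.7, 1, size=14)
        t = two_sample_t(a, b).statistic
        f = one_way_anova(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 14).statistic
        assert f == pytest.approx(t**2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


def _lstsq_group_f(y, X_full, X_reduced, q):
    """Normal-equations oracle for the partial group F."""
    ssr = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    ssr_f, ssr_r = ssr(X_full), ssr(X_reduced)
    df_resid = len(y) - X_full.shape[1]
    return ((ssr_r - ssr_f) / q) / (ssr_f / df_resid)


class TestAncova:
    def test_orthogonal_covariate_reduces_to_plain_anova(self):
        rng = np.random.default_rng(6)
        n = 60
        group = np.repeat(["a", "b", "c"], n // 3)
        y = rng.normal(size=n) + (group == "b") * 0.8
        raw = rng.normal(size=n)
        D = np.column_stack([np.ones(n), group == "a", group == "b", y])
        cov = raw - D @ np.linalg.lstsq(D, raw, rcond=None)[0]  # exactly orthogonal
        plain = one_way_anova(y, group)
        adj = ancova_group_effect(y, group, {"cov": cov})
        assert adj.statistic == pytest.approx(plain.statistic, rel=0.05)
        assert adj.df == (2, n - 4)

    def test_nine_row_dataset_matches_normal_equations(self):
        y = np.array([1.0, 2.0, 1.5, 3.0, 3.5, 2.8, 5.0, 4.2, 4.8])
        group = np.repeat(["a", "b", "c"], 3)
        cov = np.array([0.1, 0.5, 0.3, 0.2, 0.9, 0.4, 0.6, 0.7, 0.8])
        r = ancova_group_effect(y, group, {"x": cov})
        n = 9
        X_full = np.column_stack([np.ones(n), group == "a", group == "b", cov])
        X_red = np.column_stack([np.ones(n), cov])
        assert r.statistic == pytest.approx(_lstsq_group_f(y, X_full, X_red, 2))
        assert r.df == (2, 5)

    def test_collinear_design_rejected(self):
        y = np.arange(12.0)
        group = np.repeat(["a", "b"], 6)
        cov = (group == "a").astype(float)  # duplicates the group contrast
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(y, group, {"dup": cov})


def _split_plot_ss(df: pd.DataFrame) -> dict:
    """Hand sums-of-squares decomposition for the balanced 2x2 mixed design."""
    grand = df["value"].mean()
    ss = lambda x: float(((x - grand) ** 2).sum())
    subj = df.groupby("subject_id")["value"].mean()
    groups = df.groupby("subject_id")["group"].first()
    ss_between_subj = 2 * float(((subj - grand) ** 2).sum())
    gm = df.groupby("group")["value"].mean()
    ng = groups.value_counts()
    ss_group = 2 * float(sum(ng[g] * (gm[g] - grand) ** 2 for g in gm.index))
    ss_subj_within = ss_between_subj - ss_group
    cm = df.groupby("correctness")["value"].mean()
    n_subj = len(subj)
    ss_cond = float(sum(n_subj * (cm[c] - grand) ** 2 for c in cm.index))
    cell = df.groupby(["group", "correctness"])["value"].mean()
    ss_inter = float(
        sum(
            ng[g] * (cell[g, c] - gm[g] - cm[c] + grand) ** 2
            for g in gm.index
            for c in cm.index
        )
    )
    ss_total = ss(df["value"])
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter
    df_g, df_err_b, df_w = 1, n_subj - 2, n_subj - 2
    return {
        "group": (ss_group / df_g) / (ss_subj_within / df_err_b),
        "correctness": (ss_cond / 1) / (ss_err_within / df_w),
        "interaction": (ss_inter / 1) / (ss_err_within / df_w),
        "ss": dict(group=ss_group, cond=ss_cond, inter=ss_inter, total=ss_total),
    }


def _mixed_frame(values: dict[str, tuple[float, float]], groups: dict[str, str]) -> pd.DataFrame:
    rows = []
    for sid, (vc, ve) in values.items():
        rows.append(dict(subject_id=sid, group=groups[sid], correctness="correct", value=vc))
        rows.append(dict(subject_id=sid, group=groups[sid], correctness="error", value=ve))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_null_pattern_gives_zero_effects(self):
        # correctness deviations +/-e cancel within each group; groups share bases
        values = {
            "a1": (0.6, 0.4), "a2": (0.5, 0.7), "b1": (0.6, 0.4), "b2": (0.5, 0.7),
        }
        groups = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}
        out = {r.name.split("_")[-1]: r for r in mixed_anova_confidence(_mixed_frame(values, groups))}
        for eff in ("group", "correctness", "interaction"):
            assert out[eff].statistic == pytest.approx(0.0, abs=1e-10)

    def test_pure_interaction_pattern(self):
        # crossed cell means: group g1 confident when correct, g2 when wrong
        rng = np.random.default_rng(7)
        values, groups = {}, {}
        for j in range(4):
            e = 1e-3 * rng.normal(size=2)
            values[f"a{j}"] = (0.7 + e[0], 0.3 + e[1])
            groups[f"a{j}"] = "g1"
            e = 1e-3 * rng.normal(size=2)
            values[f"b{j}"] = (0.3 + e[0], 0.7 + e[1])
            groups[f"b{j}"] = "g2"
        frame = _mixed_frame(values, groups)
        res = {r.name.split("_")[-1]: r for r in mixed_anova_confidence(frame)}
        oracle = _split_plot_ss(frame)
        assert res["interaction"].statistic > 100 * max(
            res["group"].statistic, res["correctness"].statistic
        )
        for eff in ("group", "correctness", "interaction"):
            assert res[eff].statistic == pytest.approx(oracle[eff], rel=1e-8)
            assert 0 <= res[eff].effect_size <= 1

    def test_random_balanced_data_match_hand_decomposition(self):
        rng = np.random.default_rng(8)
        values = {f"s{j}": tuple(rng.uniform(0.2, 0.9, 2)) for j in range(12)}
        groups = {f"s{j}": ("g1" if j < 6 else "g2") for j in range(12)}
        frame = _mixed_frame(values, groups)
        res = {r.name.split("_")[-1]: r for r in mixed_anova_confidence(frame)}
        oracle = _split_plot_ss(frame)
        for eff in ("group", "correctness", "interaction"):
            assert res[eff].statistic == pytest.approx(oracle[eff], rel=1e-8)
            assert res[eff].effect_size == pytest.approx(
                oracle["ss"]["group" if eff == "group" else "cond" if eff == "correctness" else "inter"]
                / oracle["ss"]["total"],
                rel=1e-8,
            )
        assert res["group"].df == (1, 10) and res["interaction"].df == (1, 10)

    def test_missing_cell_rejected(self):
        frame = _mixed_frame(
            {"a1": (0.5, 0.4), "a2": (0.6, 0.5), "b1": (0.5, 0.4), "b2": (0.6, 0.5)},
            {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"},
        ).drop(index=[1])
        with pytest.raises(ValueError, match="missing"):
            mixed_anova_confidence(frame)


def bf01_grid_oracle(t: float, n1: int, n2: int, r: float, n_grid: int = 200_001) -> float:
    """Fine-grid trapezoid quadrature of the JZS integral (independent path)."""
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    u = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    s = 1 + n_eff * g
    marg = s**-0.5 * (1 + t * t / (s * nu)) ** (-(nu + 1) / 2)
    dens = invgamma.pdf(g, 0.5, scale=r**2 / 2)
    alt = np.trapezoid(marg * dens * jac, u)
    null = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return null / alt


class TestBayesFactor:
    @pytest.mark.parametrize("t", [0.0, 1.0, 2.5, 4.0])
    @pytest.mark.parametrize("n", [10, 24])
    @pytest.mark.parametrize("r", [np.sqrt(2) / 2, 1.0])
    def test_matches_fine_grid_quadrature_to_4_sig_figs(self, t, n, r):
        bf = bf01_from_t(t, n, n, r_scale=r)
        assert bf == pytest.approx(bf01_grid_oracle(t, n, n, r), rel=5e-5)

    def test_null_data_favour_null(self):
        assert bf01_from_t(0.0, 20, 20, r_scale=1.0) > 3

    def test_tiny_prior_scale_collapses_to_unity(self):
        assert bf01_from_t(1.5, 20, 20, r_scale=1e-5) == pytest.approx(1.0, abs=1e-3)

    def test_normal_prior_closed_form(self):
        t, n, r = 1.2, 15, 1.0
        nu, n_eff = 2 * n - 2, n / 2
        s = 1 + n_eff * r**2
        expected = (1 + t * t / nu) ** (-(nu + 1) / 2) / (
            s**-0.5 * (1 + t * t / (s * nu)) ** (-(nu + 1) / 2)
        )
        assert bf01_from_t(t, n, n, r_scale=r, prior="normal") == pytest.approx(expected)

    def test_from_samples_wires_t_and_bf(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=20), rng.normal(size=20)
        res = bayes_factor_t(a, b, r_scale=1.0)
        assert res.bf01 == pytest.approx(
            bf01_from_t(res.statistic, 20, 20, r_scale=1.0), rel=1e-10
        )

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            bf01_from_t(1.0, 10, 10, r_scale=0.0)
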