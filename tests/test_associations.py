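"""Regression layer: transforms, standardized betas, group tests,
multiplicity control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chronomeal.associations import (
    adjust_pvalues,
    association_table,
    multiple_regression,
    sex_comparison_anova,
    simple_regression,
    transform_outcomes,
    welch_t_test,
)
from chronomeal.errors import CollinearityError, DegenerateInputError, InputError


class TestTransformOutcomes:
    def test_log10_applied_to_exactly_the_five_outcomes(self):
        df = pd.DataFrame(
            {
                "homa_ir": [1.0, 10.0],
                "triglycerides": [70.0, 100.0],
                "total_chol": [150.0, 200.0],
                "hdl": [50.0, 60.0],
                "ldl": [90.0, 110.0],
                "mean_bp": [85.0, 90.0],
                "risk_z": [0.1, -0.1],
            }
        )
        out = transform_outcomes(df)
        assert out["homa_ir"].tolist() == pytest.approx([0.0, 1.0])
        assert out["triglycerides"].iloc[0] == pytest.approx(np.log10(70.0), abs=1e-6)
        # mean BP and the risk score stay on their original scales
        assert out["mean_bp"].tolist() == [85.0, 90.0]
        assert out["risk_z"].tolist() == [0.1, -0.1]

    def test_nonpositive_values_become_missing(self):
        df = pd.DataFrame({"homa_ir": [1.0, 0.0, -2.0]})
        out = transform_outcomes(df)
        assert out["homa_ir"].iloc[0] == 0.0
        assert out["homa_ir"].iloc[1:].isna().all()


class TestSimpleRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = simple_regression(x, 2 * x + 1)
        assert res.beta_std == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.n == 10

    def test_null_relation_beta_near_zero(self):
        rng = np.random.default_rng(42)
        x, y = rng.standard_normal((2, 20000))
        res = simple_regression(x, y)
        assert abs(res.beta_std) < 0.02

    def test_beta_std_equals_pearson_r(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(150)
        y = 0.4 * x + rng.standard_normal(150)
        res = simple_regression(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.beta_std == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = simple_regression(x, y)
        r = stats.pearsonr(x, y).statistic
        assert res.adj_r2 == pytest.approx(1 - (1 - r**2) * 39 / 38, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            simple_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            simple_regression([1.0] * 10, np.arange(10.0))


class TestMultipleRegression:
    def test_constant_covariates_match_simple_regression(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        y = 0.6 * x + rng.standard_normal(100)
        cov = pd.DataFrame({"c1": np.ones(100), "c2": np.full(100, 3.0)})
        full = multiple_regression(y, x, cov)
        simple = simple_regression(x, y)
        assert full.beta_std == pytest.approx(simple.beta_std, abs=1e-12)
        assert full.p == pytest.approx(simple.p, rel=1e-9)
        assert full.adj_r2 == pytest.approx(simple.adj_r2, abs=1e-12)

    def test_partial_effect_recovered_with_confounder(self):
        rng = np.random.default_rng(8)
        n = 5000
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = 0.3 * x + 0.8 * z + 0.5 * rng.standard_normal(n)
        res = multiple_regression(y, x, pd.DataFrame({"z": z}))
        raw_slope = res.beta_std * np.std(y, ddof=1) / np.std(x, ddof=1)
        assert raw_slope == pytest.approx(0.3, abs=0.05)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        cov = pd.DataFrame({"z": z, "z_twice": 2 * z})
        with pytest.raises(CollinearityError) as err:
            multiple_regression(rng.standard_normal(50), x, cov)
        assert "z_twice" in err.value.columns


class TestGroupComparisons:
    def test_welch_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_large_shift_significant(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01

    def test_welch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(1.0, 2.0, 15)
        _, p = welch_t_test(a, b)
        perm = stats.permutation_test(
            (a, b),
            lambda u, v: stats.ttest_ind(u, v, equal_var=False).statistic,
            n_resamples=4000,
            random_state=0,
        )
        assert p == pytest.approx(perm.pvalue, abs=0.03)

    def test_welch_requires_two_per_group(self):
        with pytest.raises(InputError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_anova_equal_means_f_near_zero(self):
        f, p = sex_comparison_anova([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["m"] * 3 + ["w"] * 3)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_anova_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(13)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)])
        groups = np.array(["m"] * 20 + ["w"] * 25)
        f, p_f = sex_comparison_anova(values, groups)
        t, p_t = stats.ttest_ind(values[:20], values[20:], equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_anova_single_group_errors(self):
        with pytest.raises(InputError):
            sex_comparison_anova([1.0, 2.0], ["m", "m"])


class TestAdjustPvalues:
    def test_bh_step_up_hand_enumeration(self):
        # sorted p*(m/rank) = .04,.04,.04,.04 -> cumulative min from top
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_strong_single_signal(self):
        out = adjust_pvalues([0.001] + [1.0] * 9, "bh")
        assert out[0] == pytest.approx(0.01)  # 0.001 * 10 / 1
        assert out[1:] == pytest.approx([1.0] * 9)

    def test_single_p_unchanged(self):
        for method in ("bh", "hochberg"):
            assert adjust_pvalues([0.034], method) == pytest.approx([0.034])

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            adjust_pvalues([0.5, 1.5], "bh")

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        method=st.sampled_from(["bh", "hochberg"]),
    )
    @settings(derandomize=True, max_examples=150)
    def test_monotone_and_capped(self, ps, method):
        adj = adjust_pvalues(ps, method)
        assert np.all(adj >= np.asarray(ps) - 1e-12)  # p_adj >= p
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


def test_association_table_families_and_flags(derived_small):
    df = transform_outcomes(derived_small)
    table = association_table(
        df,
        exposures=["eating_window", "msp_to_first"],
        outcomes=["homa_ir", "risk_z"],
        adjusted=False,
    )
    assert set(table["stratum"]) == {"all", "men", "women"}
    assert (table["p_adj"] >= table["p"] - 1e-12).all()
    # planted male-only effect shows up in the men stratum
    men_window = table.query("stratum == 'men' and exposure == 'eating_window' and outcome == 'homa_ir'")
    assert men_window["beta_std"].iloc[0] < -0.3
    women_window = table.query("stratum == 'women' and exposure == 'eating_window' and outcome == 'homa_ir'")
    assert abs(women_window["beta_std"].iloc[0]) < 0.25


def test_adjusted_table_uses_configured_confounder_sets(derived_small):
    df = transform_outcomes(derived_small)
    table = association_table(
        df,
        exposures=["eating_window", "msp_to_first"],
        outcomes=["homa_ir"],
        strata=("all", "men"),
        adjusted=True,
    )
    by = table.set_index(["stratum", "exposure"])["adjusted_for"]
    assert "sex_man" in by[("all", "eating_window")]
    assert "sex_man" not in by[("men", "eating_window")]
    # clock-time exposures adjust for midsleep; midsleep-anchored ones for duration
    assert "midsleep_week" in by[("men", "eating_window")]
    assert "sleep_duration_week" in by[("men", "msp_to_first")]
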