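"""First-level estimation, contrasts, rm-ANOVA, FDR, post-hoc tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqreg.design_builder import DesignMatrix, assemble_design
from seqreg.glm_engine import (
    bh_fdr,
    contrast,
    fit_first_level,
    group_window_stats,
    lag1_autocorr,
    posthoc_paired_t,
    rm_anova_window,
)
from seqreg.info_measures import randomness_table
from seqreg.sequence_sim import ExperimentConfig, generate_session


def make_design(matrix: np.ndarray, names=None) -> DesignMatrix:
    """Wrap a plain matrix as a DesignMatrix for estimator tests."""
    names = names or [f"c{j}" for j in range(matrix.shape[1])]
    n = matrix.shape[0]
    return DesignMatrix(
        frame=pd.DataFrame(matrix, columns=names),
        tr=2.0,
        n_volumes=n,
        trim_mask=np.ones(n, dtype=bool),
        provenance={},
    )


@pytest.fixture(scope="module")
def assembled():
    session = generate_session(ExperimentConfig(n_trials=300), seed=33)
    return assemble_design(
        session, randomness_table(session, 25), tr=2.0, n_volumes=380
    )


class TestFirstLevel:
    def test_noiseless_recovery_on_assembled_design(self, assembled):
        rng = np.random.default_rng(0)
        beta_true = rng.normal(size=len(assembled.columns))
        y = assembled.matrix @ beta_true
        fit = fit_first_level(assembled, y)
        np.testing.assert_allclose(fit.betas.iloc[:, 0], beta_true, atol=1e-8)
        assert fit.df == assembled.matrix.shape[0] - len(assembled.columns)

    def test_orthonormal_design_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(100, 5)))
        y = rng.normal(size=100)
        fit = fit_first_level(make_design(Q), y)
        np.testing.assert_allclose(fit.betas.iloc[:, 0], Q.T @ y, atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        fit = fit_first_level(make_design(X), y)
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.betas.iloc[:, 0], expected, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(ValueError, match="rank"):
            fit_first_level(make_design(X), rng.normal(size=40))

    def test_ar1_with_phi_zero_equals_ols(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.normal(size=80)
        ols = fit_first_level(make_design(X), y)
        white = fit_first_level(make_design(X), y, whitening="ar1", ar1_phi=0.0)
        np.testing.assert_array_equal(
            ols.betas.to_numpy(), white.betas.to_numpy()
        )

    def test_ar1_prewhitening_reduces_residual_autocorrelation(self, assembled):
        rng = np.random.default_rng(5)
        from seqreg.bold_sim import NoiseModel

        y = NoiseModel(phi=0.5, sigma=1.0).sample(assembled.matrix.shape[0], rng)
        fit = fit_first_level(assembled, y, whitening="ar1")
        assert fit.phi[0] == pytest.approx(0.5, abs=0.15)


class TestContrast:
    def test_unit_weight_extracts_single_beta(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        fit = fit_first_level(make_design(X), y)
        res = contrast(fit, {"c1": 1.0})
        assert res["estimate"].iloc[0] == pytest.approx(
            float(fit.betas.loc["c1"].iloc[0]), abs=1e-12
        )

    def test_sign_flip_negates_t(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        fit = fit_first_level(make_design(X), y)
        c = np.array([1.0, -2.0, 0.5])
        plus = contrast(fit, c)
        minus = contrast(fit, -c)
        assert plus["t"].iloc[0] == pytest.approx(-minus["t"].iloc[0], abs=1e-12)

    def test_matches_covariance_solve_oracle(self, rng):
        X = rng.normal(size=(70, 4))
        y = rng.normal(size=70)
        fit = fit_first_level(make_design(X), y)
        c = np.array([0.0, 1.0, -1.0, 2.0])
        res = contrast(fit, c)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (70 - 4)
        se = np.sqrt(c @ np.linalg.solve(X.T @ X, c) * sigma2)
        assert res["estimate"].iloc[0] == pytest.approx(c @ beta, abs=1e-10)
        assert res["t"].iloc[0] == pytest.approx(c @ beta / se, abs=1e-10)

    def test_unknown_column_weights_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        fit = fit_first_level(make_design(X), rng.normal(size=30))
        with pytest.raises(ValueError, match="unknown"):
            contrast(fit, {"nope": 1.0})


def oracle_rm_anova(table):
    """Sum-of-squares decomposition computed independently, cell by cell."""
    arr = np.asarray(table, float)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = sum(n * (arr[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (arr[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (arr[i, j] - arr[i].mean() - arr[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRmAnova:
    def test_sixteen_subjects_six_windows_df(self, rng):
        table = rng.normal(size=(16, 6))
        _, (df1, df2), _ = rm_anova_window(table)
        assert (df1, df2) == (5, 75)

    def test_no_window_effect_gives_zero_f(self):
        table = np.tile(np.arange(4.0)[:, None], (1, 3))  # subjects differ, windows don't
        F, _, p = rm_anova_window(table)
        assert F == 0.0 and p == 1.0

    def test_matches_sum_of_squares_oracle(self, rng):
        table = rng.normal(size=(4, 3))
        F, _, _ = rm_anova_window(table)
        assert F == pytest.approx(oracle_rm_anova(table), abs=1e-10)

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        table = rng.normal(size=(8, 4))
        F, (df1, df2), p = rm_anova_window(table)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 4),
                "window": np.tile(np.arange(4), 8),
                "beta": table.ravel(),
            }
        )
        res = AnovaRM(long, "beta", "subject", within=["window"]).fit()
        row = res.anova_table.iloc[0]
        assert F == pytest.approx(row["F Value"], abs=1e-8)
        assert p == pytest.approx(row["Pr > F"], abs=1e-10)
        assert (df1, df2) == (int(row["Num DF"]), int(row["Den DF"]))

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_window(table)


class TestBHFDR:
    def test_all_ones_reject_nothing(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_step_up_rule_by_hand(self):
        reject, p_adj = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_single_test_reduces_to_threshold(self):
        assert bh_fdr([0.04], q=0.05)[0][0]
        assert not bh_fdr([0.06], q=0.05)[0][0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(derandomize=True, max_examples=50)
    def test_rejections_are_prefix_of_sorted_p(self, ps):
        reject, p_adj = bh_fdr(ps)
        order = np.argsort(ps)
        flags = reject[order]
        # no accepted p may precede a rejected one after sorting
        assert not np.any(np.diff(flags.astype(int)) > 0)
        assert np.all((p_adj >= np.asarray(ps) - 1e-12) | (p_adj >= 0))


class TestPosthocPairedT:
    def test_sixteen_subjects_df(self, rng):
        a, b = rng.normal(size=(2, 16))
        _, df, _ = posthoc_paired_t(a, b)
        assert df == 15

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            posthoc_paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_equals_one_sample_t_on_differences(self, rng):
        import scipy.stats

        a, b = rng.normal(size=(2, 10))
        t, df, p = posthoc_paired_t(a, b)
        ref = scipy.stats.ttest_1samp(a - b, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestGroupWindowStats:
    def test_tidy_pipeline_and_fdr_monotone(self, rng):
        rows = []
        for roi in ("r1", "r2", "r3"):
            shift = {"r1": 0.0, "r2": 0.5, "r3": 0.0}[roi]
            for subj in range(8):
                for w in (25, 50):
                    rows.append(
                        {
                            "subject": subj,
                            "window": w,
                            "roi": roi,
                            "measure": "TE",
                            "beta": rng.normal() + (shift if w == 50 else 0.0),
                        }
                    )
        result = group_window_stats(pd.DataFrame(rows))
        assert set(result.anova["roi"]) == {"r1", "r2", "r3"}
        assert (result.anova["df1"] == 1).all()
        assert (result.anova["df2"] == 7).all()
        sorted_p = result.anova.sort_values("p")
        flags = sorted_p["significant_fdr"].astype(int).to_numpy()
        assert not np.any(np.diff(flags) > 0)
        assert set(result.posthoc["window_pair"]) == {"50-25"}
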