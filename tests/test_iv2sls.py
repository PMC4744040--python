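import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mrlipids import iv2sls

COVS = ("sex_male", "age", "PC1", "PC2")


def random_frame(rng, n=300, score_effect=0.1):
    df = pd.DataFrame({
        "sex_male": rng.integers(0, 2, n).astype(float),
        "age": rng.normal(55, 6, n),
        "PC1": rng.normal(0, 1, n),
        "PC2": rng.normal(0, 1, n),
        "score_unweighted": rng.binomial(10, 0.3, n).astype(float),
    })
    df["log_alcohol"] = (
        1.0 + score_effect * df["score_unweighted"] + 0.3 * df["sex_male"]
        - 0.01 * df["age"] + rng.normal(0, 1, n)
    )
    df["y"] = 2.0 - 0.4 * df["log_alcohol"] + 0.1 * df["sex_male"] + rng.normal(0, 1, n)
    return df


class TestFirstStage:
    def test_f_partial_r2_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df = random_frame(rng, n=int(rng.integers(50, 500)))
            fs = iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)
            implied = fs.partial_r2 / (1 - fs.partial_r2) * (fs.n - fs.k)
            assert fs.f_statistic == pytest.approx(implied, abs=1e-8)
            assert 0.0 <= fs.partial_r2 <= 1.0
            assert fs.f_statistic >= 0.0

    def test_null_score_gives_small_f(self):
        rng = np.random.default_rng(1)
        fvals = [
            iv2sls.fit_first_stage(
                random_frame(rng, n=500, score_effect=0.0),
                "log_alcohol", "score_unweighted", COVS,
            ).f_statistic
            for _ in range(40)
        ]
        # F is ~F(1, n-k) under the null: mean close to 1
        assert np.mean(fvals) == pytest.approx(1.0, abs=0.6)

    def test_rank_deficient_design_reported(self):
        rng = np.random.default_rng(2)
        df = random_frame(rng)
        df["PC2"] = df["PC1"]
        with pytest.raises(np.linalg.LinAlgError, match="PC"):
            iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        df = random_frame(rng, n=400)
        fs = iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)
        X = sm.add_constant(df[["score_unweighted", *COVS]])
        ref = sm.OLS(df["log_alcohol"], X).fit()
        assert fs.coefficients["score_unweighted"] == pytest.approx(
            ref.params["score_unweighted"], abs=1e-10)
        # nested-model F for the single added regressor equals its t^2
        assert fs.f_statistic == pytest.approx(
            float(ref.tvalues["score_unweighted"] ** 2), abs=1e-6)


class TestQuartiles:
    def _fs(self, fitted):
        s = pd.Series(fitted, dtype=float)
        return iv2sls.FirstStageFit(
            coefficients=pd.Series(dtype=float), fitted=s, rss_full=1.0,
            rss_reduced=2.0, n=len(s), k=2, f_statistic=1.0, partial_r2=0.1)

    def test_even_split(self):
        qa = iv2sls.assign_quartiles(self._fs(range(1, 9)))
        assert qa.labels.value_counts().to_dict() == {1: 2, 2: 2, 3: 2, 4: 2}

    def test_boundary_ties_go_low(self):
        vals = [1, 1, 2, 2, 3, 3, 4, 4]
        qa = iv2sls.assign_quartiles(self._fs(vals))
        # the 25th percentile is between the tied groups; values equal to
        # a boundary stay in the lower quartile
        assert (qa.labels[np.array(vals) == 2].max()) <= 2

    def test_degenerate_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError):
            iv2sls.assign_quartiles(self._fs([3.0] * 100))
        with pytest.raises(ValueError):
            iv2sls.assign_quartiles(self._fs([1, 2, 3]))

    def test_back_transform_to_grams(self):
        qa = iv2sls.assign_quartiles(self._fs(np.linspace(0.5, 3.0, 100)))
        for b_log, b_g in zip(qa.boundaries_log, qa.boundaries_g_wk):
            assert b_g == pytest.approx(np.expm1(b_log))


class TestSecondStage:
    def test_overall_wald_matches_brute_force(self):
        rng = np.random.default_rng(4)
        df = random_frame(rng, n=600)
        fs = iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)
        qa = iv2sls.assign_quartiles(fs)
        row = iv2sls.fit_second_stage(df, "y", qa, COVS, cov_type="HC1")
        # independent recomputation with statsmodels
        data = df.loc[qa.labels.index].copy()
        X = pd.DataFrame({"const": 1.0}, index=data.index)
        for q in (2, 3, 4):
            X[f"q{q}"] = (qa.labels == q).astype(float)
        for c in COVS:
            X[c] = data[c]
        ref = sm.OLS(data["y"], X).fit(cov_type="HC1")
        c_hat = ref.params[["q2", "q3", "q4"]].to_numpy()
        V = ref.cov_params().loc[["q2", "q3", "q4"], ["q2", "q3", "q4"]].to_numpy()
        wald = c_hat @ np.linalg.inv(V) @ c_hat
        assert row.p_overall == pytest.approx(float(stats.chi2.sf(wald, 3)), abs=1e-10)
        for e in row.effects:
            assert e.ci_low < e.beta < e.ci_high

    def test_null_lipid_gives_flat_betas(self):
        rng = np.random.default_rng(5)
        df = random_frame(rng, n=2000)
        df["y"] = rng.normal(0, 1, len(df))
        fs = iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)
        qa = iv2sls.assign_quartiles(fs)
        row = iv2sls.fit_second_stage(df, "y", qa, COVS)
        for e in row.effects:
            assert abs(e.beta) < 4 * e.se

    def test_exposure_shift_invariance(self):
        """Adding a constant to the exposure moves only intercepts:
        quartile labels and second-stage effects are unchanged."""
        rng = np.random.default_rng(6)
        df = random_frame(rng, n=500)
        shifted = df.copy()
        shifted["log_alcohol"] = shifted["log_alcohol"] + 5.0
        rows = []
        for frame in (df, shifted):
            fs = iv2sls.fit_first_stage(frame, "log_alcohol", "score_unweighted", COVS)
            qa = iv2sls.assign_quartiles(fs)
            rows.append((qa, iv2sls.fit_second_stage(frame, "y", qa, COVS)))
        pd.testing.assert_series_equal(rows[0][0].labels, rows[1][0].labels)
        for e0, e1 in zip(rows[0][1].effects, rows[1][1].effects):
            assert e0.beta == pytest.approx(e1.beta, abs=1e-8)

    def test_empty_quartile_reported(self):
        rng = np.random.default_rng(7)
        df = random_frame(rng, n=100)
        fs = iv2sls.fit_first_stage(df, "log_alcohol", "score_unweighted", COVS)
        qa = iv2sls.assign_quartiles(fs)
        df.loc[qa.labels[qa.labels == 3].index, "y"] = np.nan
        with pytest.raises(ValueError, match="q3"):
            iv2sls.fit_second_stage(df, "y", qa, COVS)


class TestLinear2SLS:
    def test_identity_instrument_equals_ols(self):
        rng = np.random.default_rng(8)
        df = random_frame(rng, n=400)
        df["score_unweighted"] = df["log_alcohol"]
        fit = iv2sls.fit_linear_2sls(df, "y", "log_alcohol", "score_unweighted", COVS)
        X = sm.add_constant(df[[*COVS, "log_alcohol"]])
        ols = sm.OLS(df["y"], X).fit()
        assert fit.beta == pytest.approx(float(ols.params["log_alcohol"]), abs=1e-8)

    def test_wald_ratio_closed_form(self):
        rng = np.random.default_rng(9)
        n = 500
        z = rng.binomial(2, 0.3, n).astype(float)
        x = 0.4 * z + rng.normal(0, 1, n)
        y = -0.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"score_unweighted": z, "log_alcohol": x, "y": y})
        fit = iv2sls.fit_linear_2sls(df, "y", "log_alcohol", "score_unweighted", covariates=())
        zc, yc, xc = z - z.mean(), y - y.mean(), x - x.mean()
        wald_ratio = (zc @ yc) / (zc @ xc)
        assert fit.beta == pytest.approx(wald_ratio, abs=1e-10)

    def test_two_step_equals_closed_form_with_covariates(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            df = random_frame(rng, n=200)
            fit = iv2sls.fit_linear_2sls(df, "y", "log_alcohol", "score_unweighted", COVS)
            W = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in COVS])
            oracle = iv2sls.closed_form_iv(
                df["y"], df["log_alcohol"], df["score_unweighted"], W)
            assert fit.beta == pytest.approx(oracle, abs=1e-8)

    def test_se_uses_observed_exposure_residuals(self):
        # the naive second-stage OLS SE (with fitted exposure residuals)
        # differs from the corrected 2SLS SE; check we report the latter
        rng = np.random.default_rng(11)
        df = random_frame(rng, n=800)
        fit = iv2sls.fit_linear_2sls(df, "y", "log_alcohol", "score_unweighted", COVS)
        W = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in COVS])
        xhat = fit.first_stage.fitted.to_numpy()
        X2 = np.column_stack([W, xhat])
        beta = np.asarray(fit.coefficients)
        resid_obs = df["y"].to_numpy() - np.column_stack(
            [W, df["log_alcohol"].to_numpy()]) @ beta
        sigma2 = resid_obs @ resid_obs / (len(df) - X2.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X2.T @ X2)[-1, -1])
        assert fit.se == pytest.approx(float(se), rel=1e-10)


class TestPCs:
    def test_two_population_fixture_separated(self):
        rng = np.random.default_rng(12)
        n1, n2, m = 100, 100, 40
        p1 = rng.uniform(0.1, 0.5, m)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m), 0.05, 0.95)
        G = np.vstack([
            rng.binomial(2, p1, size=(n1, m)),
            rng.binomial(2, p2, size=(n2, m)),
        ])
        pcs = iv2sls.compute_pcs(G)
        pop = np.array([0] * n1 + [1] * n2)
        assert abs(np.corrcoef(pcs[:, 0], pop)[0, 1]) > 0.9

    def test_orthonormal(self):
        rng = np.random.default_rng(13)
        G = rng.binomial(2, 0.3, size=(60, 10))
        pcs = iv2sls.compute_pcs(G)
        gram = pcs.T @ pcs
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)

    def test_sign_convention_stable_under_row_permutation(self):
        rng = np.random.default_rng(14)
        G = rng.binomial(2, 0.4, size=(50, 8))
        perm = rng.permutation(50)
        pcs = iv2sls.compute_pcs(G)
        pcs_perm = iv2sls.compute_pcs(G[perm])
        np.testing.assert_allclose(pcs_perm, pcs[perm], atol=1e-8)

    def test_constant_columns_dropped_and_all_constant_rejected(self):
        rng = np.random.default_rng(15)
        G = rng.binomial(2, 0.3, size=(30, 4)).astype(float)
        G[:, 1] = 2.0
        pcs = iv2sls.compute_pcs(G)
        assert pcs.shape == (30, 2)
        with pytest.raises(ValueError):
            iv2sls.compute_pcs(np.ones((10, 3)))
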