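"""Statistical layer: cell means, orthogonal polynomials, OLS, model
comparison, within-subjects ANOVA, pairwise t tests, ICC and Pearson r —
each checked against a brute-force oracle (normal equations, cell-mean
decomposition, explicit mean squares) and, where available, pingouin."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from curvilinea import stats as st


def make_ratings(matrix: np.ndarray) -> pd.DataFrame:
    """Long-format table from a stimulus x rater matrix."""
    n, k = matrix.shape
    rows = [(f"r{j}", f"s{i:02d}", matrix[i, j])
            for i in range(n) for j in range(k)]
    return pd.DataFrame(rows, columns=["rater_id", "stimulus_id", "rating"])


def random_ratings(rng, n_stim=8, n_raters=5) -> pd.DataFrame:
    return make_ratings(rng.uniform(1, 100, size=(n_stim, n_raters)))


class TestCellMeans:
    def test_single_rater_identity(self):
        mat = np.array([[40.0], [61.0], [13.0]])
        cm = st.cell_means(make_ratings(mat))
        assert np.array_equal(cm.per_stimulus.to_numpy(), mat.ravel())

    def test_two_raters_average(self):
        cm = st.cell_means(make_ratings(np.array([[40.0, 60.0]])))
        assert cm.per_stimulus.iloc[0] == 50.0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(7)
        ratings = random_ratings(rng)
        cm = st.cell_means(ratings)
        for sid, group in ratings.groupby("stimulus_id"):
            assert cm.per_stimulus[sid] == pytest.approx(
                group["rating"].sum() / len(group), rel=1e-12)

    def test_missing_stimulus_named(self):
        ratings = make_ratings(np.array([[40.0, 60.0]]))
        with pytest.raises(ValueError, match="s99"):
            st.cell_means(ratings, stimulus_ids=["s00", "s99"])

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            st.validate_ratings(make_ratings(np.array([[140.0]])))


class TestOrthogonalPoly:
    def test_orthonormal_columns(self):
        z = st.orthogonal_poly([1.0, 2.0, 3.0], 2)
        assert z.shape == (3, 2)
        assert np.allclose(z.T @ z, np.eye(2), atol=1e-12)
        assert np.allclose(z.sum(axis=0), 0.0, atol=1e-12)

    def test_linear_column_proportional_to_centered_x(self):
        x = np.array([2.0, 5.0, 6.0, 11.0])
        z = st.orthogonal_poly(x, 2)
        xc = x - x.mean()
        assert abs(abs(np.corrcoef(z[:, 0], xc)[0, 1]) - 1.0) < 1e-12
        assert np.corrcoef(z[:, 0], xc)[0, 1] > 0

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError):
            st.orthogonal_poly([1.0, 1.0, 2.0], 2)


def brute_force_ols(y, X):
    """Normal-equations oracle: beta = (X'X)^-1 X'y with explicit inverse."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se, resid


class TestOlsFit:
    def test_exact_linear_fit(self):
        x = np.arange(1.0, 6.0)
        fit = st.ols_fit(2.0 * x, pd.DataFrame({"x": x}))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.terms.loc["x", "estimate"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 12
            X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            y = rng.normal(size=n)
            fit = st.ols_fit(y, X)
            Xi = np.column_stack([np.ones(n), X.to_numpy()])
            beta, se, resid = brute_force_ols(y, Xi)
            assert np.allclose(fit.terms["estimate"], beta, atol=1e-8)
            assert np.allclose(fit.terms["se"], se, atol=1e-8)
            # AIC under the full Gaussian convention
            rss = resid @ resid
            aic = n * np.log(2 * np.pi * rss / n) + n + 2 * (3 + 1)
            assert fit.aic == pytest.approx(aic, rel=1e-12)

    def test_residuals_sum_to_zero_and_df(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=10)})
        fit = st.ols_fit(rng.normal(size=10), X)
        assert abs(fit.resid.sum()) < 1e-9
        assert fit.df_model + fit.df_resid + 1 == fit.nobs

    def test_collinearity_named(self):
        x = np.arange(6.0)
        X = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.raises(st.CollinearityError):
            st.ols_fit(np.ones(6), X)


def synthetic_cells(noise=0.0, seed=0, interaction=0.0):
    """A 5x5 cell-mean table from a known quadratic-in-C + width surface."""
    rng = np.random.default_rng(seed)
    c_levels = np.array([0.012, 0.009, 0.0065, 0.0045, 0.003])
    widths = np.array([210.0, 233.0, 262.0, 300.0, 350.0])
    rows = []
    for i, c in enumerate(c_levels, 1):
        for j, w in enumerate(widths, 1):
            mu = 95.0 - 6.0e5 * (c - 0.0065) ** 2 - 0.185 * w \
                + interaction * (c - 0.0065) * w
            rows.append({"stimulus_id": f"c{i}w{j}", "curv_level": i,
                         "width_level": j, "hip_width_px": w,
                         "whr": 1.0 - 2 * 4360.0 * c / w,  # monotone in C
                         "mean_abs_curvature": c,
                         "rating": mu + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestHypothesisModels:
    def test_noise_free_curviness_surface_recovered(self):
        cells = synthetic_cells()
        fit = st.fit_curviness_model(cells)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.terms.loc["W", "estimate"] == pytest.approx(-0.185, abs=1e-9)

    def test_rival_model_fits_worse(self):
        cells = synthetic_cells()
        assert st.fit_whr_model(cells).r_squared < 0.999

    def test_basis_invariance(self):
        cells = synthetic_cells(noise=5.0, seed=2)
        for fitter in (st.fit_whr_model, st.fit_curviness_model):
            f_orth = fitter(cells, basis="orthogonal")
            f_raw = fitter(cells, basis="raw")
            assert np.allclose(f_orth.fittedvalues, f_raw.fittedvalues,
                               atol=1e-10)
            assert f_orth.r_squared == pytest.approx(f_raw.r_squared, abs=1e-10)
            assert f_orth.aic == pytest.approx(f_raw.aic, abs=1e-10)
            assert f_orth.terms.loc["W", "estimate"] == pytest.approx(
                f_raw.terms.loc["W", "estimate"], abs=1e-10)

    def test_orthogonal_basis_equal_polynomial_ses(self):
        cells = synthetic_cells(noise=5.0, seed=4)
        fit = st.fit_curviness_model(cells)
        assert fit.terms.loc["C", "se"] == pytest.approx(
            fit.terms.loc["C^2", "se"], rel=1e-9)

    def test_suppressor_behavior_dropping_linear_term(self):
        # removing the linear WHR column changes R^2 even though the linear
        # coefficient itself may be non-significant
        cells = synthetic_cells(noise=5.0, seed=6)
        full = st.fit_whr_model(cells)
        z = st.orthogonal_poly(cells["whr"].to_numpy(), 2)
        reduced = st.ols_fit(
            cells["rating"].to_numpy(),
            pd.DataFrame({"WHR^2": z[:, 1],
                          "W": cells["hip_width_px"].to_numpy()}))
        assert full.r_squared - reduced.r_squared > 0.01

    def test_fitted_values_invariant_to_affine_predictor_rescale(self):
        cells = synthetic_cells(noise=5.0, seed=8)
        fit = st.fit_curviness_model(cells)
        rescaled = cells.copy()
        rescaled["mean_abs_curvature"] = \
            1000.0 * rescaled["mean_abs_curvature"] + 3.0
        fit2 = st.fit_curviness_model(rescaled)
        assert np.allclose(fit.fittedvalues, fit2.fittedvalues, atol=1e-9)

    def test_interaction_nests_additive(self):
        cells = synthetic_cells(noise=5.0, seed=10)
        add = st.fit_curviness_model(cells)
        inter = st.fit_interaction_variant(cells, "C")
        assert inter.r_squared >= add.r_squared
        assert np.isfinite(inter.condition_number)

    def test_interaction_equals_explicit_products(self):
        cells = synthetic_cells(noise=5.0, seed=12)
        inter = st.fit_interaction_variant(cells, "C")
        z = st.orthogonal_poly(cells["mean_abs_curvature"].to_numpy(), 2)
        w = cells["hip_width_px"].to_numpy()
        X = pd.DataFrame({"C": z[:, 0], "C^2": z[:, 1], "W": w,
                          "C:W": z[:, 0] * w, "C^2:W": z[:, 1] * w})
        brute = st.ols_fit(cells["rating"].to_numpy(), X)
        assert inter.r_squared == pytest.approx(brute.r_squared, abs=1e-12)
        assert np.allclose(inter.terms["estimate"], brute.terms["estimate"],
                           atol=1e-9)

    def test_interaction_recovers_generating_slope(self):
        cells = synthetic_cells(interaction=0.05)
        inter = st.fit_interaction_variant(cells, "C", basis="raw")
        assert inter.r_squared == pytest.approx(1.0, abs=1e-10)


class TestAugmentedPredictionTest:
    def test_donor_equals_base_flagged(self):
        cells = synthetic_cells(noise=5.0, seed=14)
        fit = st.fit_whr_model(cells)
        comp = st.augmented_prediction_test(fit, fit)
        assert comp.degenerate

    def test_delta_r_squared_nonnegative(self):
        cells = synthetic_cells(noise=5.0, seed=16)
        comp = st.augmented_prediction_test(st.fit_whr_model(cells),
                                            st.fit_curviness_model(cells))
        assert comp.delta_r_squared >= 0.0
        assert comp.df_num == 1
        assert comp.df_den == len(cells) - 3 - 2

    def test_misspecified_base_yields_large_f(self):
        # y generated from the curviness surface: the F for adding the
        # curviness model's predictions to the WHR model should exceed the
        # null 99th percentile estimated by simulation
        rng = np.random.default_rng(42)
        null_f = []
        for _ in range(200):
            cells = synthetic_cells(noise=5.0, seed=rng.integers(2**31))
            # null: response unrelated to curviness beyond the WHR fit
            cells = cells.assign(rating=rng.normal(50.0, 10.0, len(cells)))
            comp = st.augmented_prediction_test(
                st.fit_whr_model(cells), st.fit_curviness_model(cells))
            null_f.append(comp.f_statistic)
        threshold = np.quantile(null_f, 0.99)
        cells = synthetic_cells(noise=5.0, seed=1)
        comp = st.augmented_prediction_test(
            st.fit_whr_model(cells), st.fit_curviness_model(cells))
        assert comp.f_statistic > threshold


def brute_force_two_way_within(cube):
    """Cell-mean decomposition oracle for a fully-within two-way design."""
    r, a, b = cube.shape
    grand = cube.mean()
    alpha = cube.mean(axis=(0, 2)) - grand
    beta = cube.mean(axis=(0, 1)) - grand
    subj = cube.mean(axis=(1, 2)) - grand
    ab = cube.mean(axis=0) - grand - alpha[:, None] - beta[None, :]
    ss = {"A": r * b * (alpha**2).sum(), "B": r * a * (beta**2).sum(),
          "AB": r * (ab**2).sum(), "S": a * b * (subj**2).sum()}
    resid_as = cube.mean(axis=2) - grand - subj[:, None] - alpha[None, :]
    resid_bs = cube.mean(axis=1) - grand - subj[:, None] - beta[None, :]
    ss["AS"] = b * (resid_as**2).sum()
    ss["BS"] = a * (resid_bs**2).sum()
    ss["total"] = ((cube - grand) ** 2).sum()
    ss["ABS"] = ss["total"] - sum(ss[k] for k in ("A", "B", "AB", "S", "AS", "BS"))
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (r - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (r - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / \
        (ss["ABS"] / ((a - 1) * (b - 1) * (r - 1)))
    return ss, (f_a, f_b, f_ab)


def ratings_from_cube(cube):
    r, a, b = cube.shape
    rows = []
    for i in range(r):
        for x in range(a):
            for y in range(b):
                rows.append((f"r{i}", f"s{x}{y}", cube[i, x, y]))
    ratings = pd.DataFrame(rows, columns=["rater_id", "stimulus_id", "rating"])
    cell_of = {f"s{x}{y}": (x, y) for x in range(a) for y in range(b)}
    return ratings, cell_of


class TestRmAnova:
    def test_constant_factor_gives_zero_f(self):
        rng = np.random.default_rng(0)
        cube = np.tile(rng.uniform(20, 80, size=(4, 1, 3)), (1, 2, 1))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.rm_anova(ratings, cell_of).set_index("effect")
        assert table.loc["A", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_two_level_factor_epsilon_one(self):
        rng = np.random.default_rng(1)
        cube = rng.uniform(1, 100, size=(6, 2, 3))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.rm_anova(ratings, cell_of).set_index("effect")
        assert table.loc["A", "eps"] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        cube = rng.uniform(1, 100, size=(4, 2, 3))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.rm_anova(ratings, cell_of).set_index("effect")
        ss, (f_a, f_b, f_ab) = brute_force_two_way_within(cube)
        assert table.loc["A", "ss"] == pytest.approx(ss["A"], rel=1e-8)
        assert table.loc["B", "ss"] == pytest.approx(ss["B"], rel=1e-8)
        assert table.loc["A * B", "ss"] == pytest.approx(ss["AB"], rel=1e-8)
        assert table.loc["A", "F"] == pytest.approx(f_a, rel=1e-8)
        assert table.loc["B", "F"] == pytest.approx(f_b, rel=1e-8)
        assert table.loc["A * B", "F"] == pytest.approx(f_ab, rel=1e-8)
        # decomposition: SS_total = sum of all effect + error terms
        parts = ss["A"] + ss["B"] + ss["AB"] + ss["S"] + ss["AS"] + ss["BS"] \
            + ss["ABS"]
        assert parts == pytest.approx(ss["total"], rel=1e-8)
        # generalized eta squared: effect over effect + all subject terms
        denom = ss["S"] + ss["AS"] + ss["BS"] + ss["ABS"]
        assert table.loc["A", "ges"] == pytest.approx(
            ss["A"] / (ss["A"] + denom), rel=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        cube = rng.uniform(1, 100, size=(8, 3, 4))
        ratings, cell_of = ratings_from_cube(cube)
        ours = st.rm_anova(ratings, cell_of).set_index("effect")
        df = ratings.copy()
        df["A"] = df["stimulus_id"].map(lambda s: cell_of[s][0])
        df["B"] = df["stimulus_id"].map(lambda s: cell_of[s][1])
        with np.errstate(invalid="ignore"):
            theirs = pg.rm_anova(dv="rating", within=["A", "B"],
                                 subject="rater_id", data=df, detailed=True,
                                 effsize="ng2").set_index("Source")
        for key in ("A", "B", "A * B"):
            assert ours.loc[key, "F"] == pytest.approx(
                theirs.loc[key, "F"], rel=1e-9)
            assert ours.loc[key, "ges"] == pytest.approx(
                theirs.loc[key, "ng2"], rel=1e-9)
        # epsilon: pingouin's two-way rm_anova warns that its own epsilon is
        # unreliable; check ours against pg.epsilon on the per-effect
        # collapsed subject x level matrices instead
        assert ours.loc["A", "eps"] == pytest.approx(
            pg.epsilon(pd.DataFrame(cube.mean(axis=2)), correction="gg"),
            rel=1e-9)
        assert ours.loc["B", "eps"] == pytest.approx(
            pg.epsilon(pd.DataFrame(cube.mean(axis=1)), correction="gg"),
            rel=1e-9)

    def test_incomplete_design_lists_cells(self):
        rng = np.random.default_rng(4)
        cube = rng.uniform(1, 100, size=(4, 2, 2))
        ratings, cell_of = ratings_from_cube(cube)
        ratings = ratings[ratings["stimulus_id"] != "s11"]
        with pytest.raises(ValueError, match="missing cells"):
            st.rm_anova(ratings, cell_of)


class TestBonferroniPairwise:
    def test_identical_levels_t_zero_p_one(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(10, 90, size=(5, 1, 1))
        cube = np.tile(col, (1, 3, 1))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.bonferroni_pairwise(ratings, cell_of)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p_bonferroni"], 1.0)

    def test_adjustment_is_m_times_raw_capped(self):
        rng = np.random.default_rng(6)
        cube = rng.uniform(1, 100, size=(6, 4, 2))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.bonferroni_pairwise(ratings, cell_of)
        m = 4 * 3 // 2
        assert np.allclose(table["p_bonferroni"],
                           np.minimum(1.0, m * table["p_raw"]))

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(7)
        cube = rng.uniform(1, 100, size=(9, 3, 2))
        ratings, cell_of = ratings_from_cube(cube)
        table = st.bonferroni_pairwise(ratings, cell_of)
        row = table[(table["B"] == 1) & (table["level_1"] == 0)
                    & (table["level_2"] == 2)].iloc[0]
        t, p = sps.ttest_rel(cube[:, 0, 1], cube[:, 2, 1])
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p_raw"] == pytest.approx(p, rel=1e-12)
        assert row["df"] == 8


class TestIcc:
    def test_identical_raters_give_one(self):
        col = np.linspace(10, 90, 6)[:, None]
        ratings = make_ratings(np.tile(col, (1, 4)))
        assert st.icc_c_k(ratings).icc_c_k == pytest.approx(1.0, abs=1e-12)

    def test_mean_squares_oracle_3x4(self):
        rng = np.random.default_rng(8)
        Y = rng.uniform(1, 100, size=(3, 4))
        res = st.icc_c_k(make_ratings(Y))
        n, k = Y.shape
        grand = Y.mean()
        ms_t = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ss_e = ((Y - Y.mean(axis=1, keepdims=True)
                 - Y.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        ms_e = ss_e / ((n - 1) * (k - 1))
        assert res.icc_c_k == pytest.approx((ms_t - ms_e) / ms_t, rel=1e-8)

    def test_matches_pingouin_icc3k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        Y = np.clip(np.linspace(20, 80, 10)[:, None]
                    + rng.normal(0, 12, size=(10, 6)), 1, 100)
        ratings = make_ratings(Y)
        ours = st.icc_c_k(ratings)
        theirs = pg.intraclass_corr(
            data=ratings, targets="stimulus_id", raters="rater_id",
            ratings="rating").set_index("Type").loc["ICC(C,k)", "ICC"]
        assert ours.icc_c_k == pytest.approx(theirs, rel=1e-9)

    def test_decreases_with_noise(self):
        signal = np.linspace(20, 80, 12)[:, None]
        rng = np.random.default_rng(10)
        iccs = []
        for sd in (2.0, 15.0, 60.0):
            Y = np.clip(signal + rng.normal(0, sd, size=(12, 8)), 1, 100)
            iccs.append(st.icc_c_k(make_ratings(Y)).icc_c_k)
        assert iccs[0] > iccs[1] > iccs[2]

    def test_incomplete_matrix_rejected(self):
        ratings = random_ratings(np.random.default_rng(11)).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            st.icc_c_k(ratings)


class TestPearson:
    def test_perfect_correlation_flagged(self):
        x = np.arange(5.0)
        with pytest.warns(RuntimeWarning):
            r, t, df = st.pearson_r_t(x, x)
        assert r == 1.0 and np.isinf(t) and df == 3

    def test_orthogonal_columns_zero(self):
        a = np.tile([1.0, 2.0, 3.0], 3)
        b = np.repeat([1.0, 2.0, 3.0], 3)
        r, t, df = st.pearson_r_t(a, b)
        assert abs(r) < 1e-12 and abs(t) < 1e-12 and df == 7

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 40))
        r, t, df = st.pearson_r_t(x, y)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(r_oracle, rel=1e-10)
        assert t == pytest.approx(r * np.sqrt(38 / (1 - r * r)), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.pearson_r_t(np.ones(5), np.arange(5.0))
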