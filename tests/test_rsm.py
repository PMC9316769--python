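"""Quadratic response-surface fitting, prediction and ANOVA."""

import numpy as np
import pytest

from uaeqc.doe import FactorSpec, generate_bbd
from uaeqc.rsm import (QuadraticModel, anova, fit_quadratic, model_matrix,
                       surface_grid)

# the published fitted surface, coded scale, model-matrix order
# [b0, b1, b2, b3, b12, b13, b23, b11, b22, b33]
PUBLISHED_COEF = (0.81, -0.22, 0.2, 0.084, 0.012, 0.076, -0.014,
                  -0.33, -0.031, -0.069)


def make_factors():
    return [
        FactorSpec("methanol", "%", 50, 70, 90),
        FactorSpec("ratio", "mL/g", 30, 50, 70),
        FactorSpec("time", "min", 20, 35, 50),
    ]


def model_from_coef(coef):
    c = np.asarray(coef, float)
    return QuadraticModel(beta0=c[0], beta_linear=c[1:4], beta_inter=c[4:7],
                          beta_quad=c[7:10], factors=make_factors())


class TestFitQuadratic:
    def test_exact_recovery_of_known_surface(self, rng):
        """Zero-noise responses from a known β are interpolated back to
        machine precision."""
        design = generate_bbd(make_factors(), n_center=5)
        truth = rng.normal(size=10)
        y = model_matrix(design.coded) @ truth
        model = fit_quadratic(design, y)
        assert np.allclose(model.coef, truth, atol=1e-10)

    def test_constant_response(self):
        design = generate_bbd(make_factors())
        model = fit_quadratic(design, np.full(17, 3.25))
        assert model.beta0 == pytest.approx(3.25, abs=1e-12)
        assert np.allclose(model.coef[1:], 0.0, atol=1e-12)

    def test_matches_normal_equations_on_random_instances(self, rng):
        """OLS solution equals the brute-force normal-equation solve."""
        design = generate_bbd(make_factors())
        M = model_matrix(design.coded)
        for _ in range(100):
            y = rng.normal(size=17)
            beta_ne = np.linalg.solve(M.T @ M, M.T @ y)
            model = fit_quadratic(design, y)
            assert np.allclose(model.coef, beta_ne, atol=1e-9)

    def test_statsmodels_cross_check(self, published_design):
        """Independent OLS implementation agrees on the published data."""
        sm = pytest.importorskip("statsmodels.api")
        design, od = published_design
        M = model_matrix(design.coded)
        res = sm.OLS(od, M).fit()
        model = fit_quadratic(design, od)
        assert np.allclose(model.coef, res.params, atol=1e-10)
        assert res.rsquared == pytest.approx(0.9874, abs=5e-5)

    def test_rejects_nonfinite_and_short_input(self):
        design = generate_bbd(make_factors())
        with pytest.raises(ValueError, match="non-finite"):
            fit_quadratic(design, np.r_[np.full(16, 1.0), np.nan])
        with pytest.raises(ValueError, match="17 runs|responses"):
            fit_quadratic(design, np.ones(5))


class TestPredict:
    def test_origin_returns_intercept(self):
        model = model_from_coef(PUBLISHED_COEF)
        assert model.predict([0.0, 0.0, 0.0]) == pytest.approx(0.81)

    def test_hand_evaluated_polynomial(self):
        # coded (1, −1, 0): 0.81 − 0.22 − 0.2 − 0.012 − 0.33 − 0.031
        model = model_from_coef(PUBLISHED_COEF)
        expected = 0.81 - 0.22 - 0.2 - 0.012 - 0.33 - 0.031
        assert model.predict([1.0, -1.0, 0.0]) == pytest.approx(expected, abs=1e-12)

    def test_published_coefficients_predict_od_at_rounded_optimum(self):
        """The printed coefficients evaluated at (65 %, 70 mL/g, 40 min)
        — coded (−0.25, 1, 1/3) — give the printed prediction 1.02."""
        model = model_from_coef(PUBLISHED_COEF)
        val = model.predict([65.0, 70.0, 40.0], coded=False)
        assert val == pytest.approx(1.02, abs=0.005)

    def test_actual_units_equal_coded_route(self):
        model = model_from_coef(PUBLISHED_COEF)
        assert model.predict([65.0, 70.0, 40.0], coded=False) == pytest.approx(
            model.predict([-0.25, 1.0, 1 / 3]), abs=1e-12)

    def test_extrapolation_warns(self):
        model = model_from_coef(PUBLISHED_COEF)
        with pytest.warns(UserWarning, match="outside"):
            model.predict([2.0, 0.0, 0.0])


class TestAnova:
    def test_zero_noise_gives_r2_one(self, rng):
        design = generate_bbd(make_factors())
        y = model_matrix(design.coded) @ rng.normal(size=10)
        model = fit_quadratic(design, y)
        table = anova(model, design, y)
        assert table.r2 == pytest.approx(1.0, abs=1e-9)
        assert table.table.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-18)

    def test_ss_identities(self, published_anova):
        """SST = SSmodel + SSE and SSE = SSlof + SSpe."""
        t = published_anova.table
        assert t.loc["model", "ss"] + t.loc["residual", "ss"] == pytest.approx(
            t.loc["corrected_total", "ss"], rel=1e-9)
        assert t.loc["lack_of_fit", "ss"] + t.loc["pure_error", "ss"] == \
            pytest.approx(t.loc["residual", "ss"], rel=1e-9)

    def test_degrees_of_freedom_17_run_design(self, published_anova):
        t = published_anova.table
        assert t.loc["model", "df"] == 9
        assert t.loc["residual", "df"] == 7
        assert t.loc["lack_of_fit", "df"] == 3
        assert t.loc["pure_error", "df"] == 4
        assert t.loc["corrected_total", "df"] == 16

    def test_linear_term_partial_ss_closed_form(self, rng):
        """On the orthogonal coded design each linear/interaction term's
        drop-one SS equals coefficient² × (column sum of squares 8);
        e.g. a printed term SS of 0.3758 implies |β| = √(0.3758/8)."""
        design = generate_bbd(make_factors())
        y = rng.normal(size=17)
        model = fit_quadratic(design, y)
        table = anova(model, design, y)
        labels = model.term_labels
        for idx, label in enumerate(labels[:6]):  # linear + interaction
            coef = model.coef[1 + idx]
            nsq = 8.0 if idx < 3 else 4.0  # interaction columns have SS 4
            assert table.table.loc[label, "ss"] == pytest.approx(
                coef ** 2 * nsq, rel=1e-9, abs=1e-12)

    def test_quadratic_partial_ss_not_additive(self, published_anova):
        """Quadratic-term columns are non-orthogonal to the intercept,
        so per-term partial SS need not sum to the model SS."""
        t = published_anova.table
        term_sum = t.iloc[1:10]["ss"].sum()
        assert term_sum != pytest.approx(t.loc["model", "ss"], rel=1e-4)

    def test_no_replicates_warns_and_omits_lof(self, rng):
        design = generate_bbd(make_factors(), n_center=1)
        y = rng.normal(size=13)
        model = fit_quadratic(design, y)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            table = anova(model, design, y)
        assert "lack_of_fit" not in table.table.index
        assert "pure_error" not in table.table.index


class TestSurfaceGrid:
    def test_corners_match_predict(self, fitted_model):
        xi, xj, Z = surface_grid(fitted_model, 0, 2, resolution=2)
        assert Z[0, 0] == pytest.approx(fitted_model.predict([-1, 0, -1]))
        assert Z[1, 1] == pytest.approx(fitted_model.predict([1, 0, 1]))

    def test_interior_maximum_near_stationary_point(self, fitted_model):
        """The (methanol, time) grid at centre ratio peaks in the
        interior at negative coded methanol, matching the analytic
        stationary point of the restricted quadratic."""
        xi, xj, Z = surface_grid(fitted_model, 0, 2, resolution=201)
        a, b = np.unravel_index(np.argmax(Z), Z.shape)
        assert 0 < a < 200 and 0 < b < 200
        assert xi[a] < 0
        # analytic stationary point of the 2-factor restriction
        A2 = np.array([[fitted_model.beta_quad[0],
                        0.5 * fitted_model.beta_inter[1]],
                       [0.5 * fitted_model.beta_inter[1],
                        fitted_model.beta_quad[2]]])
        b2 = np.array([fitted_model.beta_linear[0], fitted_model.beta_linear[2]])
        xs = np.linalg.solve(-2 * A2, b2)
        assert abs(xi[a] - xs[0]) < 0.02 and abs(xj[b] - xs[1]) < 0.02

    def test_pure_even_model_symmetric(self):
        model = model_from_coef([1, 0, 0, 0, 0, 0, 0, -1, -0.5, -0.2])
        _, _, Z = surface_grid(model, 0, 1, resolution=21)
        assert np.allclose(Z, Z[::-1, :], atol=1e-12)
        assert np.allclose(Z, Z[:, ::-1], atol=1e-12)

    def test_same_factor_twice_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            surface_grid(fitted_model, 1, 1)
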