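"""Quadratic model matrix, OLS fit, significance screening, prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

import extopt as e
from extopt.exceptions import InputError, ModelSpecError, SingularFitError
from extopt.reference import EQ_BRANCHES_TPC, EQ_LEAVES_DPPH


class TestModelMatrix:
    def test_center_row_is_intercept_only(self, ccrd3):
        X = e.build_model_matrix(ccrd3, e.full_quadratic_terms(3))
        center_rows = X[[p.point_type == "center" for p in ccrd3.points]]
        np.testing.assert_array_equal(center_rows[:, 0], 1.0)
        np.testing.assert_array_equal(center_rows[:, 1:], 0.0)

    def test_all_ones_factorial_row(self):
        X = e.build_model_matrix(np.array([[1.0, 1.0, 1.0]]), e.full_quadratic_terms(3))
        np.testing.assert_array_equal(X, 1.0)

    def test_axial_row(self):
        alpha = e.rotatable_alpha(3)
        X = e.build_model_matrix(np.array([[alpha, 0.0, 0.0]]), e.full_quadratic_terms(3))
        row = dict(zip([t.label() for t in e.full_quadratic_terms(3)], X[0]))
        assert row["X1"] == pytest.approx(alpha)
        assert row["X1^2"] == pytest.approx(alpha**2)
        assert row["X1^2"] == pytest.approx(2.8284, abs=5e-4)
        for lbl in ("X2", "X3", "X2^2", "X3^2", "X1*X2", "X1*X3", "X2*X3"):
            assert row[lbl] == 0.0

    def test_duplicate_terms_rejected(self, ccrd3):
        terms = e.full_quadratic_terms(3) + [e.ModelTerm("linear", (0,))]
        with pytest.raises(ModelSpecError, match="duplicate"):
            e.build_model_matrix(ccrd3, terms)

    def test_term_label_round_trip(self):
        for t in e.full_quadratic_terms(4):
            assert e.ModelTerm.from_label(t.label()).label() == t.label()


class TestFitFull:
    def test_noiseless_recovery_of_published_surface(self, ccrd3):
        truth = e.QuadraticModel.from_coefficients(EQ_LEAVES_DPPH, 3)
        y = truth.predict(ccrd3.coded_array())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = e.fit_full(ccrd3, y)
        got = fit.coefficients
        for lbl, coef in EQ_LEAVES_DPPH.items():
            assert got[lbl] == pytest.approx(coef, abs=1e-8)
        for lbl in ("X2*X3",):
            assert got[lbl] == pytest.approx(0.0, abs=1e-8)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_noiseless_recovery_any_coefficients(self, ccrd3, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 10, size=10)
        labels = [t.label() for t in e.full_quadratic_terms(3)]
        truth = e.QuadraticModel.from_coefficients(dict(zip(labels, beta)), 3)
        y = truth.predict(ccrd3.coded_array())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = e.fit_full(ccrd3, y)
        np.testing.assert_allclose(
            [fit.coefficients[l] for l in labels], beta, atol=1e-8
        )

    def test_constant_response(self, ccrd3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = e.fit_full(ccrd3, np.full(17, 42.0))
        assert fit.coefficients["1"] == pytest.approx(42.0, abs=1e-10)
        for lbl, c in fit.coefficients.items():
            if lbl != "1":
                assert c == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, ccrd3, rng):
        """OLS equals the explicit (X'X)^-1 X'y solve on random instances."""
        X = e.build_model_matrix(ccrd3, e.full_quadratic_terms(3))
        for _ in range(20):
            y = rng.normal(50, 10, size=17)
            fit = e.fit_full(ccrd3, y)
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                [t.coefficient for t in fit.terms], beta_oracle, atol=1e-8
            )

    def test_matches_statsmodels(self, ccrd3, rng):
        """Coefficients, SEs and p-values agree with an independent OLS fit."""
        sm = pytest.importorskip("statsmodels.api")
        X = e.build_model_matrix(ccrd3, e.full_quadratic_terms(3))
        y = rng.normal(60, 5, size=17)
        fit = e.fit_full(ccrd3, y)
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose([t.coefficient for t in fit.terms], res.params, rtol=1e-10)
        np.testing.assert_allclose([t.std_error for t in fit.terms], res.bse, rtol=1e-10)
        np.testing.assert_allclose([t.p_value for t in fit.terms], res.pvalues, rtol=1e-8)

    def test_residual_orthogonality_and_ss_identity(self, noisy_leaves_study):
        design, y = noisy_leaves_study
        fit = e.fit_full(design, y)
        X = e.build_model_matrix(design, fit.terms)
        resid = y - X @ np.array([t.coefficient for t in fit.terms])
        assert np.max(np.abs(X.T @ resid)) / np.max(np.abs(X.T @ y)) < 1e-8
        ss_tot = np.sum((y - y.mean()) ** 2)
        yhat = X @ np.array([t.coefficient for t in fit.terms])
        ss_reg = np.sum((yhat - y.mean()) ** 2)
        ss_res = np.sum(resid**2)
        assert ss_tot == pytest.approx(ss_reg + ss_res, rel=1e-8)

    def test_rank_deficient_matrix_names_columns(self, ccrd3):
        # duplicate a factor: X2 == X1 makes linear columns collinear
        coded = ccrd3.coded_array().copy()
        coded[:, 1] = coded[:, 0]
        with pytest.raises(SingularFitError, match="rank deficient"):
            e.fit_full(coded, np.arange(17.0))


class TestEffectTable:
    def test_p_value_symmetry_and_center(self):
        df = 8
        assert 2 * stats.t.sf(0.0, df) == pytest.approx(1.0)
        for t in (0.5, 1.3, 2.7):
            assert stats.t.sf(t, df) == pytest.approx(stats.t.cdf(-t, df), rel=1e-12)

    def test_p_against_quadrature_oracle(self, noisy_leaves_study):
        """Two-sided p equals numeric integration of the t density."""
        design, y = noisy_leaves_study
        fit = e.fit_full(design, y)
        assert fit.df_residual == 7
        for term in fit.terms:
            tail, _ = integrate.quad(
                lambda x: stats.t.pdf(x, fit.df_residual), abs(term.t_value), np.inf
            )
            assert term.p_value == pytest.approx(2 * tail, abs=1e-6)

    def test_ranked_by_abs_t_descending(self, noisy_leaves_study):
        design, y = noisy_leaves_study
        fit = e.fit_full(design, y)
        table = e.effect_table(fit)
        assert "1" not in list(table["term"])
        assert list(table["abs_t"]) == sorted(table["abs_t"], reverse=True)
        assert (table["significant"] == (table["p_value"] <= 0.1)).all()


class TestSelectAndRefit:
    def test_published_thin_branch_structure_is_representable(self, ccrd3):
        """A reduced model {1, X1, X2, X2*X3} (interaction without its
        parent X3) must be expressible and refittable."""
        truth = e.QuadraticModel.from_coefficients(EQ_BRANCHES_TPC, 3)
        y = truth.predict(ccrd3.coded_array())
        terms = [e.ModelTerm.from_label(l) for l in EQ_BRANCHES_TPC]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = e.fit_full(ccrd3, y, terms=terms)
        for lbl, coef in EQ_BRANCHES_TPC.items():
            assert fit.coefficients[lbl] == pytest.approx(coef, abs=1e-8)

    def test_true_terms_retained_under_noise(self, ccrd3):
        """3-term truth + small noise: the true terms survive the screen in
        >= 95% of seeded replicates."""
        truth = {"1": 300.0, "X1": 38.0, "X2": 14.0, "X2*X3": -20.0}
        cfg = e.SyntheticConfig(truth, ccrd3, noise_sd=2.0, seed=101)
        summary = e.recovery_experiment(cfg, 500)
        for lbl in ("X1", "X2", "X2*X3"):
            assert summary["selection_frequency"][lbl] >= 0.95

    def test_intercept_always_retained(self, ccrd3, rng):
        y = rng.normal(0, 1, size=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced = e.select_and_refit(ccrd3, y)
        assert reduced.terms[0].kind == "intercept"

    def test_reduced_center_prediction_is_intercept(self, noisy_leaves_study):
        design, y = noisy_leaves_study
        reduced = e.select_and_refit(design, y)
        assert reduced.predict(np.zeros(3)) == pytest.approx(reduced.coefficients["1"])


class TestPredict:
    def test_published_optimum_prediction(self, eq1_model):
        assert round(eq1_model.predict(np.array([0.5, -0.5, 1.5])), 2) == 63.48

    def test_intercept_at_center(self, eq1_model, eq2_model):
        assert eq1_model.predict(np.zeros(3)) == pytest.approx(65.26)
        assert eq2_model.predict(np.zeros(3)) == pytest.approx(328.61)

    def test_dimension_mismatch(self, eq1_model):
        with pytest.raises(InputError):
            eq1_model.predict(np.zeros(2))

    def test_json_round_trip(self, tmp_path, noisy_leaves_study):
        design, y = noisy_leaves_study
        model = e.select_and_refit(design, y, response_name="DPPH")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = e.QuadraticModel.from_json(path)
        assert back.response_name == model.response_name
        assert back.df_residual == model.df_residual
        np.testing.assert_allclose(
            [t.coefficient for t in back.terms], [t.coefficient for t in model.terms]
        )


class TestSurfaceGrid:
    def test_center_value_on_grid(self, eq1_model):
        grid = e.surface_grid(eq1_model, 0, 1, resolution=41)
        at_center = grid[(grid.coded_i == 0.0) & (grid.coded_j == 0.0)]
        assert len(at_center) == 1
        assert at_center.predicted.iloc[0] == pytest.approx(65.26)

    def test_row_major_order_and_shape(self, eq1_model):
        grid = e.surface_grid(eq1_model, 0, 1, resolution=5)
        assert len(grid) == 25
        assert list(grid.coded_i[:5]) == [grid.coded_i[0]] * 5  # i varies slowest

    def test_refinement_converges(self, eq1_model):
        """Coarse-grid max within 0.05 response units of a 10x finer grid."""
        coarse = e.surface_grid(eq1_model, 0, 1, resolution=68).predicted.max()
        fine = e.surface_grid(eq1_model, 0, 1, resolution=673).predicted.max()
        assert abs(coarse - fine) < 0.05

    def test_intercept_only_model_is_flat(self):
        m = e.QuadraticModel.from_coefficients({"1": 7.0}, 3)
        grid = e.surface_grid(m, 0, 2, resolution=9)
        assert (grid.predicted == 7.0).all()
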