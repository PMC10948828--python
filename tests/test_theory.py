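"""Closed-form bias/MSE theory, optimal constants and the Searls machinery."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import imputemean as im
from imputemean.theory import SingularSystemError, UndefinedConstantError


class TestTheoreticalMse:
    @pytest.mark.parametrize("mode", ["as_printed", "table_consistent"])
    def test_t0_variance_pop3(self, pop3, mode):
        p, d = pop3
        assert im.theoretical_mse("t0", p, d, mode=mode).mse == pytest.approx(97.40, abs=0.005)

    @pytest.mark.parametrize("mode", ["as_printed", "table_consistent"])
    def test_t1_minimum_pop3(self, pop3, mode):
        p, d = pop3
        assert im.theoretical_mse("t1", p, d, mode=mode).mse == pytest.approx(69.22, abs=0.005)

    def test_t2_literal_formula_negative_and_flagged(self, pop1):
        # the literal subtracted-term expression is not usable as an MSE
        p, d = pop1
        with pytest.warns(RuntimeWarning, match="negative MSE"):
            res = im.theoretical_mse("t2", p, d, mode="as_printed")
        assert res.is_negative
        assert res.mse == pytest.approx(-6965.7, rel=1e-3)

    def test_t1_equals_t0_at_zero_correlation(self):
        p = im.derive_params(N=100, Ybar=20.0, Xbar=10.0, Cy=0.5, Cx=0.6, rho=0.0)
        d = im.thetas(100, 30, 20)
        v0 = im.theoretical_mse("t0", p, d).mse
        assert im.theoretical_mse("t1", p, d).mse == pytest.approx(v0, rel=1e-14)

    def test_regression_type_estimators_pop3(self, pop3):
        p, d = pop3
        assert im.theoretical_mse("t3", p, d).mse == pytest.approx(193.13, abs=0.005)
        assert im.theoretical_mse("t4", p, d).mse == pytest.approx(163.14, abs=0.005)
        assert im.theoretical_mse("t5", p, d).mse == pytest.approx(127.39, abs=0.005)

    def test_t1_t8_t9_identical(self, table1):
        # their closed-form minima are the same algebraic expression
        for p, d in table1.values():
            m1 = im.theoretical_mse("t1", p, d).mse
            assert im.theoretical_mse("t8", p, d).mse == m1
            assert im.theoretical_mse("t9", p, d).mse == m1

    def test_two_code_paths_for_t1_agree(self, table1):
        # V(t0) - theta_rn*Ybar^2*rho^2*Cy^2 == Ybar^2*Cy^2*(theta_rN - theta_rn*rho^2)
        for p, d in table1.values():
            via_v0 = (
                im.theoretical_mse("t0", p, d).mse
                - d.theta_rn * p.Ybar**2 * p.rho**2 * p.Cy**2
            )
            assert im.theoretical_mse("t1", p, d).mse == pytest.approx(via_v0, rel=1e-12)

    def test_t10_modes_differ(self, pop3):
        p, d = pop3
        literal = im.theoretical_mse("t10", p, d, mode="as_printed").mse
        repaired = im.theoretical_mse("t10", p, d, mode="table_consistent").mse
        assert literal == pytest.approx(d.theta_rN * p.Ybar**2 * p.Cy**2 * (1 - p.rho**2))
        assert repaired == im.theoretical_mse("t1", p, d).mse

    def test_unknown_estimator_rejected(self, pop3):
        p, d = pop3
        with pytest.raises(ValueError, match="unknown estimator"):
            im.theoretical_mse("t42", p, d)


class TestOptimalConstants:
    def test_lambda_pop3(self, pop3):
        p, _ = pop3
        lam = im.optimal_constants("t1", p)["lam"]
        assert lam == pytest.approx(1 - p.Cyx / p.Cx**2, rel=1e-14)
        assert lam == pytest.approx(0.3040, abs=5e-4)

    def test_beta_exp_pop2(self, pop2):
        p, _ = pop2
        assert im.optimal_constants("t2", p)["beta_exp"] == pytest.approx(1.0495, abs=5e-4)

    def test_m_zero_when_rho_cy_equals_cx(self):
        p = im.derive_params(N=100, Ybar=10, Xbar=5, Cy=0.5, Cx=0.4, rho=0.8)
        assert im.optimal_constants("t9", p)["m"] == pytest.approx(0.0, abs=1e-15)

    def test_delta_undefined_at_zero_correlation(self):
        p = im.derive_params(N=100, Ybar=10, Xbar=5, Cy=0.5, Cx=0.4, rho=0.0)
        with pytest.raises(UndefinedConstantError):
            im.optimal_constants("t8", p)

    def test_constant_free_estimators_empty(self, pop1):
        p, _ = pop1
        for est in ("t0", "tr", "t3", "t4", "t5"):
            assert im.optimal_constants(est, p) == {}


class TestBias:
    def test_t0_unbiased(self, pop1):
        p, d = pop1
        assert im.theoretical_bias("t0", p, d) == 0.0

    def test_ratio_bias_pop1(self, pop1):
        p, d = pop1
        expected = d.theta_rn * p.Ybar * (p.Cx**2 - p.Cyx)
        b = im.theoretical_bias("tr", p, d)
        assert b == pytest.approx(expected, rel=1e-14)
        assert b == pytest.approx(30.76, abs=0.05)

    def test_t1_bias_at_optimum_symbolic(self, table1):
        # substituting lam_opt = 1 - Cyx/Cx^2 into (1-lam)*theta_rn*Ybar*(Cx^2-Cyx)
        for p, d in table1.values():
            lam = im.optimal_constants("t1", p)["lam"]
            expected = (p.Cyx / p.Cx**2) * d.theta_rn * p.Ybar * (p.Cx**2 - p.Cyx)
            got = im.theoretical_bias("t1", p, d, {"lam": lam})
            assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_constant_raises(self, pop1):
        p, d = pop1
        with pytest.raises(ValueError, match="requires constant"):
            im.theoretical_bias("t1", p, d)

    def test_t8_pole_at_delta_equal_xbar(self, pop1):
        p, d = pop1
        with pytest.raises(ZeroDivisionError):
            im.theoretical_bias("t8", p, d, {"delta": p.Xbar})


class TestSearls:
    def test_pop1_coefficients(self, pop1):
        p, d = pop1
        c = im.searls_coefficients(p, d)
        assert c.A == pytest.approx(1.01544, abs=5e-6)
        assert c.C == pytest.approx(1.00470, abs=5e-6)
        assert c.D == pytest.approx(1.00691, abs=5e-6)
        assert c.F == pytest.approx(0.99002, abs=5e-6)

    def test_census_degenerate_singular(self, pop1):
        p, _ = pop1
        d = im.thetas(p.N, p.N, p.N)  # theta_rN = 0
        c = im.searls_coefficients(p, d)
        assert c.A == c.B == c.C == c.D == c.F == 1.0
        assert c.M == 0.0 and c.kappa1 is None
        with pytest.raises(SingularSystemError):
            im.min_mse_tp(c, p.Ybar)

    def test_pop3_expansion_sign_b(self, pop3):
        p, d = pop3
        c = im.searls_coefficients(p, d, b_sign="expansion_plus")
        assert c.B == pytest.approx(1.41285, abs=5e-6)
        assert c.is_positive_definite

    def test_printed_sign_indefinite_on_fixtures(self, table1):
        # the literal minus sign makes [[A,C],[C,B]] indefinite here: the
        # solved point is a saddle of that quadratic
        for p, d in table1.values():
            c = im.searls_coefficients(p, d, b_sign="printed_minus")
            assert c.M < 0
            assert not c.is_positive_definite

    def test_quadratic_trivial_evaluations(self, pop1):
        p, d = pop1
        c = im.searls_coefficients(p, d)
        assert im.mse_tp_at(0.0, 0.0, c, p.Ybar) == pytest.approx(p.Ybar**2, rel=1e-15)
        expected = p.Ybar**2 * (1 + c.A - 2 * c.D)
        assert im.mse_tp_at(1.0, 0.0, c, p.Ybar) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("b_sign", ["printed_minus", "expansion_plus"])
    def test_stationary_value_matches_quadratic_at_optimum(self, table1, b_sign):
        for p, d in table1.values():
            c = im.searls_coefficients(p, d, b_sign=b_sign)
            at_opt = im.mse_tp_at(c.kappa1, c.kappa2, c, p.Ybar)
            assert im.min_mse_tp(c, p.Ybar) == pytest.approx(at_opt, rel=1e-9)

    def test_normal_equations_hold(self, table1):
        for p, d in table1.values():
            c = im.searls_coefficients(p, d)
            assert abs(c.A * c.kappa1 + c.C * c.kappa2 - c.D) < 1e-10
            assert abs(c.C * c.kappa1 + c.B * c.kappa2 - c.F) < 1e-10

    def test_pop3_stationary_value_frozen(self, pop3):
        # high-precision direct evaluation of Ybar^2*(1 - (Du+Fv)/M); this is
        # NOT the published tp table cell (61.49), which no variant reproduces
        p, d = pop3
        c = im.searls_coefficients(p, d)
        assert im.min_mse_tp(c, p.Ybar) == pytest.approx(93.9308, abs=5e-4)

    def test_literal_minimum_formula_differs(self, pop3):
        p, d = pop3
        c = im.searls_coefficients(p, d)
        stat = im.min_mse_tp(c, p.Ybar, formula="stationary")
        lit = im.min_mse_tp(c, p.Ybar, formula="literal")
        assert lit != pytest.approx(stat, rel=1e-3)


class TestProfilesAndOracle:
    @pytest.mark.parametrize("est", ["t1", "t2", "t6", "t7", "t9", "t10"])
    def test_numeric_minimizer_matches_closed_form(self, table1, est):
        """scipy scalar minimization over the tuning constant recovers the
        published optimal constant and minimum value."""
        for p, d in table1.values():
            res = minimize_scalar(
                lambda c: im.mse_profile(est, c, p, d), bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            key = list(im.optimal_constants(est, p).keys())[0]
            opt = im.optimal_constants(est, p)[key]
            assert res.x == pytest.approx(opt, abs=1e-6)
            assert res.fun == pytest.approx(
                im.profile_min_closed_form(est, p, d), rel=1e-8
            )


class TestEfficiencyAndTables:
    def test_pre_self_is_100(self):
        assert im.pre_percent(12.3, 12.3) == 100.0

    def test_pre_scale_invariant(self, pop3):
        p, d = pop3
        a = im.theoretical_mse("t0", p, d).mse
        b = im.theoretical_mse("t1", p, d).mse
        assert im.pre_percent(a, b) == pytest.approx(im.pre_percent(7 * a, 7 * b), rel=1e-14)

    def test_pre_t1_fixtures(self, pop1, pop3):
        for (p, d), expected in [(pop3, 140.71), (pop1, 128.66)]:
            v0 = im.theoretical_mse("t0", p, d).mse
            m1 = im.theoretical_mse("t1", p, d).mse
            assert im.pre_percent(v0, m1) == pytest.approx(expected, abs=0.005)

    def test_pre_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            im.pre_percent(1.0, 0.0)

    def test_efficiency_report_flags_match_differences(self, pop3):
        p, d = pop3
        rep = im.efficiency_report(p, d)
        assert (rep.table["tp_better"] == (rep.table["mse_diff_vs_tp"] > 0)).all()
        # recompute each difference independently
        for est in rep.table.index:
            mse = im.theoretical_mse(est, p, d).mse
            assert rep.table.loc[est, "mse_diff_vs_tp"] == pytest.approx(mse - rep.mse_tp)

    def test_efficiency_tie_reported_false_at_zero_correlation(self):
        p = im.derive_params(N=100, Ybar=20.0, Xbar=10.0, Cy=0.5, Cx=0.6, rho=0.0)
        d = im.thetas(100, 30, 20)
        rep = im.efficiency_report(p, d)
        # t1 ties t0 exactly at rho=0; strict inequality means both flags agree
        assert rep.table.loc["t1", "mse"] == rep.table.loc["t0", "mse"]

    def test_build_table_pop3_cells(self, table1):
        t = im.build_table(
            [table1[k] for k in ("POP1", "POP2", "POP3")], labels=["POP1", "POP2", "POP3"]
        )
        rounded = im.round_table(t)
        assert rounded.loc["t3", ("POP3", "mse")] == 193.13
        assert rounded.loc["t5", ("POP3", "mse")] == 127.39
        assert rounded.loc["t0", ("POP2", "mse")] == 16.44

    def test_build_table_empty_rejected(self):
        with pytest.raises(ValueError):
            im.build_table([])

    def test_round_table_half_away_from_zero(self, table1):
        t = im.build_table([table1["POP3"]], labels=["POP3"])
        r = im.round_table(t)
        assert np.all(np.abs(r.to_numpy() - t.to_numpy()) <= 0.5e-2 + 1e-12)
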