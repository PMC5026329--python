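"""Point estimator, C_hat, and the four variance methods."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.sandbox.regression.gmm import IV2SLS

from ts2sls import (Sample, c_hat, fit_ts2sls, ols_fit, sandwich_vcov,
                    ts2sls_point, variance)
from ts2sls.exceptions import SingularMatrixError, ValidationError

from conftest import random_design


class TestPoint:
    def test_scalar_ratio_of_stage_coefficients(self):
        fs = ols_fit(np.array([4.0, 8.0]), np.array([[1.0], [2.0]]))
        beta, X1h = ts2sls_point(np.array([2.0, 4.0]), np.array([[1.0], [2.0]]), fs)
        assert beta == pytest.approx(0.5)
        np.testing.assert_allclose(X1h[:, 0], [4.0, 8.0])

    def test_outcome_orthogonal_to_instruments_gives_zero(self):
        Z1 = np.array([[1.0], [-1.0]])
        y1 = np.array([3.0, 3.0])  # Z1'y1 = 0
        fs = ols_fit(np.array([1.0, 3.0]), np.array([[1.0], [2.0]]))
        beta, _ = ts2sls_point(y1, Z1, fs)
        assert beta == pytest.approx(0.0, abs=1e-14)

    def test_same_sample_reduces_to_classical_2sls(self):
        """With sample2 == sample1 the estimator is textbook 2SLS."""
        rng = np.random.default_rng(11)
        n, kz, kx = 200, 3, 2
        Z = rng.normal(size=(n, kz))
        X = Z @ (rng.normal(size=(kz, kx)) + 2 * np.eye(kz, kx)) \
            + rng.normal(size=(n, kx))
        y = X @ np.array([1.0, -0.5]) + rng.normal(size=n)
        fs = ols_fit(X, Z)
        beta, _ = ts2sls_point(y, Z, fs)
        oracle = IV2SLS(y, X, Z).fit().params
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_collinear_first_stage_raises(self):
        fs = ols_fit(np.column_stack([np.arange(4.0), 2 * np.arange(4.0)]),
                     np.arange(1.0, 5.0).reshape(4, 1) * np.ones((4, 2))
                     + np.random.default_rng(1).normal(size=(4, 2)))
        # force perfectly collinear predicted exposures
        fs.coefficients = np.array([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(SingularMatrixError):
            ts2sls_point(np.ones(5), np.random.default_rng(0).normal(size=(5, 2)), fs)


class TestCHat:
    def test_just_identified_is_pi_inverse(self):
        fs = ols_fit(np.array([4.0, 8.0]), np.array([[1.0], [2.0]]))
        _, X1h = ts2sls_point(np.array([2.0, 4.0]), np.array([[1.0], [2.0]]), fs)
        C = c_hat(X1h, np.array([[1.0], [2.0]]))
        assert C[0, 0] == pytest.approx(0.25, abs=1e-12)

    def test_identity_C_Pi(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            Z1 = rng.normal(size=(30, 3))
            Pi = rng.normal(size=(3, 2)) + np.eye(3, 2)
            X1h = Z1 @ Pi
            C = c_hat(X1h, Z1)
            np.testing.assert_allclose(C @ Pi, np.eye(2), atol=1e-10)

    def test_dual_closed_forms_agree(self):
        rng = np.random.default_rng(13)
        Z1 = rng.normal(size=(40, 3))
        Pi = rng.normal(size=(3, 2)) + np.eye(3, 2)
        X1h = Z1 @ Pi
        C1 = c_hat(X1h, Z1)
        G = Z1.T @ Z1
        C2 = np.linalg.solve(Pi.T @ G @ Pi, Pi.T @ G)
        np.testing.assert_allclose(C1, C2, atol=1e-10)


class TestVarianceToy:
    """Hand-evaluated values on the scalar toy dataset."""

    def _fits(self, flavor):
        rf = ols_fit(np.array([1.0, 2.0, 3.0]), np.array([[1.0], [1.0], [2.0]]))
        fs = ols_fit(np.array([1.0, 3.0]), np.array([[1.0], [2.0]]))
        sandwich_vcov(rf, flavor)
        sandwich_vcov(fs, flavor)
        beta, X1h = ts2sls_point(np.array([1.0, 2.0, 3.0]), rf.Z, fs)
        C = c_hat(X1h, rf.Z)
        return rf, fs, beta, X1h, C

    def test_robust_and_delta_hand_value(self):
        rf, fs, beta, X1h, C = self._fits("HC0")
        assert beta == pytest.approx(15 / 14, abs=1e-12)
        v_robust = variance("robust", beta, C, rf, fs, X1h)
        v_delta = variance("scalar_delta", beta, C, rf, fs, X1h)
        assert v_robust[0, 0] == pytest.approx(0.0145830, abs=5e-8)
        assert v_delta[0, 0] == pytest.approx(v_robust[0, 0], abs=1e-12)

    def test_homoskedastic_and_is_hand_values(self):
        rf, fs, beta, X1h, C = self._fits("homoskedastic")
        assert rf.sigma2() == pytest.approx(1 / 6, abs=1e-12)
        assert fs.sigma2() == pytest.approx(0.1, abs=1e-12)
        v_h = variance("homoskedastic", beta, C, rf, fs, X1h)
        v_is = variance("inoue_solon", beta, C, rf, fs, X1h,
                        y1=np.array([1.0, 2.0, 3.0]), alpha_hat=1.5)
        assert v_h[0, 0] == pytest.approx(0.0258862, abs=5e-8)
        assert v_is[0, 0] == pytest.approx(0.0288147, abs=5e-8)

    def test_perfect_fit_gives_zero_everywhere(self):
        rf = ols_fit(np.array([2.0, 4.0]), np.array([[1.0], [2.0]]))
        fs = ols_fit(np.array([4.0, 8.0]), np.array([[1.0], [2.0]]))
        for flavor, methods in [("HC0", ["robust", "scalar_delta"]),
                                ("homoskedastic", ["homoskedastic", "inoue_solon"])]:
            sandwich_vcov(rf, flavor)
            sandwich_vcov(fs, flavor)
            beta, X1h = ts2sls_point(np.array([2.0, 4.0]),
                                     np.array([[1.0], [2.0]]), fs)
            C = c_hat(X1h, np.array([[1.0], [2.0]]))
            for m in methods:
                v = variance(m, beta, C, rf, fs, X1h,
                             y1=np.array([2.0, 4.0]), alpha_hat=1.0)
                assert v[0, 0] == pytest.approx(0.0, abs=1e-20)

    def test_method_flavor_mismatch_raises(self):
        rf, fs, beta, X1h, C = self._fits("homoskedastic")
        with pytest.raises(ValidationError, match="robust"):
            variance("robust", beta, C, rf, fs, X1h)
        rf, fs, beta, X1h, C = self._fits("HC0")
        with pytest.raises(ValidationError, match="homoskedastic"):
            variance("inoue_solon", beta, C, rf, fs, X1h,
                     y1=np.zeros(3), alpha_hat=1.0)

    def test_scalar_delta_multivariate_raises(self):
        rng = np.random.default_rng(14)
        rf = ols_fit(rng.normal(size=20), rng.normal(size=(20, 2)))
        fs = ols_fit(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)))
        sandwich_vcov(rf, "HC0")
        sandwich_vcov(fs, "HC0")
        with pytest.raises(ValidationError, match="kx = kz = 1"):
            variance("scalar_delta", np.ones(2), np.eye(2), rf, fs,
                     rng.normal(size=(20, 2)))


class TestFitEndToEnd:
    def test_toy_composition(self, toy_sample1, toy_sample2):
        res = fit_ts2sls(toy_sample1, toy_sample2, vcov_method="robust")
        assert res.params["x"] == pytest.approx(15 / 14, abs=1e-12)
        assert res.bse["x"] == pytest.approx(np.sqrt(0.0145830), abs=1e-6)
        lo, hi = res.conf_int().loc["x"]
        assert lo == pytest.approx(15 / 14 - 1.959964 * res.bse["x"], abs=1e-6)

    def test_robust_equals_delta_just_identified(self, toy_sample1, toy_sample2):
        r1 = fit_ts2sls(toy_sample1, toy_sample2, vcov_method="robust")
        r2 = fit_ts2sls(toy_sample1, toy_sample2, vcov_method="scalar_delta")
        assert r1.vcov[0, 0] == pytest.approx(r2.vcov[0, 0], abs=1e-12)

    def test_same_sample_homoskedastic_point_matches_2sls(self):
        rng = np.random.default_rng(15)
        n = 150
        z = rng.normal(size=n)
        x = 1.5 * z + rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        s1 = Sample(df, {"y": "outcome", "z": "instrument"}, "s1")
        s2 = Sample(df, {"x": "exposure", "z": "instrument"}, "s2")
        res = fit_ts2sls(s1, s2, vcov_method="homoskedastic")
        oracle = IV2SLS(y, x[:, None], z[:, None]).fit().params
        assert res.params["x"] == pytest.approx(oracle[0], abs=1e-10)


class TestInvariances:
    def test_instrument_rescale_invariance(self):
        rng = np.random.default_rng(16)
        s1, s2, _, _ = random_design(rng)
        base = fit_ts2sls(s1, s2, vcov_method="robust")
        k = 7.5
        df1, df2 = s1.data.copy(), s2.data.copy()
        df1["z0"] *= k
        df2["z0"] *= k
        r2 = fit_ts2sls(Sample(df1, s1.roles), Sample(df2, s2.roles),
                        vcov_method="robust")
        np.testing.assert_allclose(r2.beta_hat, base.beta_hat, atol=1e-8)
        np.testing.assert_allclose(r2.vcov, base.vcov, atol=1e-8)
        for m in ("homoskedastic", "inoue_solon"):
            a = fit_ts2sls(s1, s2, vcov_method=m).vcov
            b = fit_ts2sls(Sample(df1, s1.roles), Sample(df2, s2.roles),
                           vcov_method=m).vcov
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_exposure_rescale_equivariance(self):
        rng = np.random.default_rng(17)
        s1, s2, _, _ = random_design(rng)
        base = fit_ts2sls(s1, s2, vcov_method="robust")
        k = 4.0
        df2 = s2.data.copy()
        df2["x0"] *= k
        r2 = fit_ts2sls(s1, Sample(df2, s2.roles), vcov_method="robust")
        assert r2.params["x0"] == pytest.approx(base.params["x0"] / k, abs=1e-10)
        assert r2.vcov[0, 0] == pytest.approx(base.vcov[0, 0] / k ** 2,
                                              rel=1e-8)

    def test_robust_with_homoskedastic_plugin_collapses_to_eq13(self):
        """The general sandwich with homoskedastic stage vcovs equals the
        explicit homoskedastic formula — algebraic collapse."""
        rng = np.random.default_rng(18)
        for _ in range(5):
            s1, s2, _, _ = random_design(rng)
            rf = ols_fit(s1.y, s1.Z)
            fs = ols_fit(s2.X, s2.Z)
            sandwich_vcov(rf, "homoskedastic")
            sandwich_vcov(fs, "homoskedastic")
            beta, X1h = ts2sls_point(s1.y, s1.Z, fs)
            C = c_hat(X1h, s1.Z)
            V13 = variance("homoskedastic", beta, C, rf, fs, X1h)
            bC = np.kron(np.atleast_1d(beta)[None, :], C)
            V12 = C @ rf.vcov @ C.T + bC @ fs.vcov @ bC.T
            np.testing.assert_allclose(V12, V13, atol=1e-10)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_scalar_just_identified_identities(seed):
    """beta = pi_y1/pi_x2, C = 1/Pi, robust == delta, over random draws."""
    rng = np.random.default_rng(seed)
    n1, n2 = 30, 25
    z1, z2 = rng.normal(size=(n1, 1)), rng.normal(size=(n2, 1))
    x2 = 1.5 * z2[:, 0] + rng.normal(size=n2)
    y1 = 2.0 * z1[:, 0] + rng.normal(size=n1)
    rf, fs = ols_fit(y1, z1), ols_fit(x2, z2)
    sandwich_vcov(rf, "HC0")
    sandwich_vcov(fs, "HC0")
    beta, X1h = ts2sls_point(y1, z1, fs)
    pi_y1 = rf.coefficients.item()
    pi_x2 = fs.coefficients.item()
    assert beta[0] == pytest.approx(pi_y1 / pi_x2, abs=1e-10)
    C = c_hat(X1h, z1)
    assert C[0, 0] == pytest.approx(1 / pi_x2, abs=1e-10)
    vr = variance("robust", beta, C, rf, fs, X1h)[0, 0]
    vd = variance("scalar_delta", beta, C, rf, fs, X1h)[0, 0]
    assert vr == pytest.approx(vd, abs=1e-10 * max(1.0, vd))
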