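"""Unit and property tests for the BPEEC distribution itself."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import bpeec as b
from bpeec import BPEECParams, SeriesControl
from bpeec.model import SeriesConvergenceError


valid_params = st.builds(
    BPEECParams,
    alpha1=st.floats(-3.0, -0.1),
    alpha2=st.floats(0.2, 3.0),
    alpha3=st.floats(-2.0, 0.0),
)


class TestValidation:
    @pytest.mark.parametrize(
        "triple,valid,violation",
        [
            ((-0.5, 1.0, -0.3), True, None),
            ((0.09219, 0.54266, -0.15297), False, "alpha1 < 0"),
            ((-0.5, 0.6, 0.5), False, "alpha3 <= 0"),
            ((-0.5, -1.0, 0.0), False, "alpha2 > 0"),
        ],
    )
    def test_region(self, triple, valid, violation):
        report = b.validate_params(BPEECParams(*triple))
        assert report.valid is valid
        if violation:
            assert violation in report.violations

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            b.validate_params(BPEECParams(math.nan, 1.0, 0.0))

    def test_invalid_params_refused_by_series(self):
        with pytest.raises(b.InvalidParameterError):
            b.normalizing_constant(BPEECParams(0.5, 1.0, 0.0))


class TestNormalizingConstant:
    def test_independence_closed_forms(self):
        assert b.normalizing_constant(BPEECParams(-math.log(2), 1, 0)).value == pytest.approx(1.0, abs=1e-14)
        expected = math.exp(-1) / (2 * (1 - math.exp(-1)))
        assert b.normalizing_constant(BPEECParams(-1, 2, 0)).value == pytest.approx(expected, rel=1e-13)

    def test_against_naive_partial_summation(self, dependent_params, naive_oracle):
        res = b.normalizing_constant(dependent_params)
        assert res.value == pytest.approx(naive_oracle(dependent_params, 10_000), rel=1e-12)
        assert res.value == pytest.approx(0.34179, rel=1e-4)

    def test_certified_tail_bound(self, dependent_params):
        ctl = SeriesControl(rel_tol=1e-12)
        res = b.normalizing_constant(dependent_params, ctl)
        assert 0 <= res.tail_bound <= ctl.rel_tol * res.value
        assert res.log_value == pytest.approx(math.log(res.value))

    def test_max_terms_exceeded(self):
        with pytest.raises(SeriesConvergenceError, match="not converged"):
            b.normalizing_constant(BPEECParams(-1e-6, 1.0, -0.5), SeriesControl(max_terms=100))


class TestDerivativeSeries:
    def test_zero_dependence_single_term(self):
        out = b.normalizing_constant_derivative_series(BPEECParams(-math.log(2), 1, 0))
        assert out == pytest.approx(1.0, rel=1e-12)

    def test_cross_check_small_ratio(self):
        p = BPEECParams(-1.0, 1.0, -0.01)
        direct = b.normalizing_constant(p).value
        out = b.normalizing_constant_derivative_series(p, rel_tol=1e-8)
        assert out == pytest.approx(direct, rel=1e-8)

    def test_moderate_ratio_is_asymptotic_only(self):
        # the k-expansion is asymptotic: at alpha3/alpha2 = -0.1 its optimal
        # truncation cannot certify 1e-8, and a loose target still lands
        # within ~1e-3 of the direct series
        p = BPEECParams(-1.0, 1.0, -0.1)
        direct = b.normalizing_constant(p).value
        with pytest.raises(SeriesConvergenceError, match="divergent"):
            b.normalizing_constant_derivative_series(p, rel_tol=1e-8)
        out = b.normalizing_constant_derivative_series(p, rel_tol=1e-3)
        assert out == pytest.approx(direct, rel=1e-3)

    def test_large_ratio_detected_divergent(self):
        with pytest.raises(SeriesConvergenceError, match="divergent"):
            b.normalizing_constant_derivative_series(BPEECParams(-1, 1, -5), k_max=50)


class TestDensities:
    def test_joint_density_examples(self, dependent_params, independent_params):
        N0 = b.normalizing_constant(independent_params)
        assert b.joint_density(0, 0, independent_params, N0) == pytest.approx(0.5, rel=1e-12)
        assert b.joint_density(1, 1, independent_params, N0) == pytest.approx(0.25 * math.exp(-1), rel=1e-12)
        N = b.normalizing_constant(dependent_params)
        # oracle: exp(-1 - 1.5) / N with N from the brute-force summation
        assert b.joint_density(0, 1, dependent_params, N) == pytest.approx(
            math.exp(-2.5) / 0.3417891039825499, rel=1e-12
        )

    def test_conditional_pmf_values_and_normalization(self):
        p = BPEECParams(-math.log(2), 1.0, 0.0)
        assert b.conditional_pmf_x_given_y(0, 3.7, p) == pytest.approx(0.5, rel=1e-12)
        p2 = BPEECParams(-1.0, 1.0, -1.0)
        lam = math.exp(2) - 1
        assert b.conditional_pmf_x_given_y(0, 1.0, p2) == pytest.approx(lam / (1 + lam), rel=1e-12)
        assert b.conditional_pmf_x_given_y(1, 1.0, p2) == pytest.approx(lam / (1 + lam) ** 2, rel=1e-12)
        xs = np.arange(400)
        assert b.conditional_pmf_x_given_y(xs, 1.0, p2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_conditional_pdf_y_given_x(self):
        p = BPEECParams(-1.0, 1.0, -0.5)
        assert b.conditional_pdf_y_given_x(0.0, 1, p) == pytest.approx(2.0, rel=1e-12)
        assert b.conditional_pdf_y_given_x(0.5, 1, p) == pytest.approx(2 * math.exp(-1), rel=1e-12)
        val, _ = integrate.quad(lambda y: b.conditional_pdf_y_given_x(y, 3, p), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_marginals(self, dependent_params, independent_params):
        N = b.normalizing_constant(dependent_params)
        assert b.marginal_pmf_x(0, dependent_params, N) == pytest.approx(0.71755, rel=1e-4)
        xs = np.arange(300)
        assert b.marginal_pmf_x(xs, dependent_params, N).sum() == pytest.approx(1.0, abs=1e-10)
        N0 = b.normalizing_constant(independent_params)
        assert b.marginal_pdf_y(0.0, independent_params, N0) == pytest.approx(1.0, rel=1e-12)
        assert b.marginal_pdf_y(1.0, independent_params, N0) == pytest.approx(math.exp(-1), rel=1e-12)
        val, _ = integrate.quad(lambda y: b.marginal_pdf_y(y, dependent_params, N), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(p=valid_params, x=st.integers(0, 20), y=st.floats(0.05, 5.0))
    def test_compatibility_identity(self, p, x, y):
        """joint = conditional * marginal in both factorizations."""
        N = b.normalizing_constant(p)
        joint = b.joint_density(x, y, p, N)
        via_y = b.conditional_pmf_x_given_y(x, y, p) * b.marginal_pdf_y(y, p, N)
        via_x = b.conditional_pdf_y_given_x(y, x, p) * b.marginal_pmf_x(x, p, N)
        assert via_y == pytest.approx(joint, rel=1e-12)
        assert via_x == pytest.approx(joint, rel=1e-12)


class TestRegression:
    def test_closed_forms(self):
        assert b.regression_x_given_y(2.3, BPEECParams(-math.log(2), 1, 0)) == pytest.approx(1.0, rel=1e-12)
        assert b.regression_x_given_y(1.0, BPEECParams(-1, 1, -1)) == pytest.approx(1 / (math.exp(2) - 1), rel=1e-12)
        p = BPEECParams(-1.0, 1.0, -0.5)
        assert b.regression_y_given_x(0, p) == pytest.approx(2 / 3, rel=1e-12)
        assert b.regression_y_given_x(1, p) == pytest.approx(0.5, rel=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(p=st.builds(BPEECParams, alpha1=st.floats(-3, -0.1),
                       alpha2=st.floats(0.2, 3.0), alpha3=st.floats(-2, -0.01)))
    def test_strictly_decreasing_under_negative_dependence(self, p):
        ys = np.linspace(0.0, 5.0, 40)
        ry = np.asarray(b.regression_x_given_y(ys, p))
        assert np.all(np.diff(ry) < 0)
        xs = np.arange(0, 25)
        rx = np.asarray(b.regression_y_given_x(xs, p))
        assert np.all(np.diff(rx) < 0)


class TestMoments:
    def test_independence_factorization(self, independent_params):
        N = b.normalizing_constant(independent_params)
        m = b.moments(independent_params, N)
        assert m.mean_x == pytest.approx(1.0, rel=1e-10)
        assert m.mean_y == pytest.approx(1.0, rel=1e-10)
        assert m.correlation == pytest.approx(0.0, abs=1e-10)
        assert m.var_y == pytest.approx(1.0, rel=1e-10)  # Exp(1) variance
        assert b.product_moment_xy(independent_params, N) == pytest.approx(1.0, rel=1e-10)

    def test_hypergeometric_cross_check(self, dependent_params):
        N = b.normalizing_constant(dependent_params)
        direct = b.product_moment_xy(dependent_params, N)
        hyp = b.product_moment_xy_hypergeometric(dependent_params, N)
        assert hyp == pytest.approx(direct, rel=1e-6)

    def test_correlation_sign_matches_covariance(self, dependent_params):
        N = b.normalizing_constant(dependent_params)
        m = b.moments(dependent_params, N)
        cov = b.product_moment_xy(dependent_params, N) - m.mean_x * m.mean_y
        assert math.copysign(1, m.correlation) == math.copysign(1, cov)


class TestSampler:
    def test_rejects_bad_n(self, dependent_params):
        with pytest.raises(ValueError, match="n must be positive"):
            b.sample(dependent_params, 0, 1)

    def test_seed_determinism(self, dependent_params):
        x1, y1 = b.sample(dependent_params, 500, 11)
        x2, y2 = b.sample(dependent_params, 500, 11)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_marginal_frequency(self, dependent_params):
        n = 100_000
        x, y = b.sample(dependent_params, n, 2024)
        N = b.normalizing_constant(dependent_params)
        p0 = b.marginal_pmf_x(0, dependent_params, N)
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(np.mean(x == 0) - p0) < 4 * se
        assert np.all(y > 0)
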