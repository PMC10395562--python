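"""Fractional-polynomial basis, exhaustive power search, likelihood-ratio
comparisons and reference-anchored curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gripmr import compare_fp, curve_from_fp, fit_fp, fit_fp_fixed, fit_linear, fp_basis
from gripmr.exceptions import DomainError, IncomparableFitsError, SingularFitError
from gripmr.fracpoly import FP_POWERS, fp_derivative_basis, fp_power_sets


@pytest.mark.parametrize(
    "x, powers, expected",
    [
        (np.e, (0.0,), [1.0]),
        (4.0, (0.5, 0.5), [2.0, 2.0 * np.log(4.0)]),
        (2.0, (-2.0,), [0.25]),
        (np.e, (0.0, 0.0), [1.0, 1.0]),  # repeated log power: ln x, (ln x)^2
        (3.0, (2.0,), [9.0]),
    ],
)
def test_basis_closed_forms(x, powers, expected):
    np.testing.assert_allclose(fp_basis(np.array([x]), powers)[0], expected, atol=1e-12)


def test_basis_rejects_nonpositive_x_with_count():
    with pytest.raises(DomainError, match="2 offending"):
        fp_basis(np.array([1.0, 0.0, -3.0]), (1.0,))


def test_derivative_basis_matches_numerical_gradient():
    x = np.linspace(5.0, 80.0, 40)
    h = 1e-6
    for powers in [(0.0,), (-2.0,), (0.5, 0.5), (0.0, 0.0), (1.0, 3.0)]:
        num = (fp_basis(x + h, powers) - fp_basis(x - h, powers)) / (2 * h)
        np.testing.assert_allclose(fp_derivative_basis(x, powers), num, rtol=1e-5)


def test_noiseless_recovery_selects_true_power():
    rng = np.random.default_rng(0)
    x = rng.uniform(10, 120, 2_000)
    fit_log = fit_fp(3.0 * np.log(x), x, degree=1)
    assert fit_log.powers == (0.0,)
    assert fit_log.fp_coefficients[0] == pytest.approx(3.0, abs=1e-6)
    fit_id = fit_fp(5.0 + 2.0 * x, x, degree=1)
    assert fit_id.powers == (1.0,)


def test_power_selection_under_small_noise():
    """y = 2*sqrt(x) + tiny noise: the sqrt power wins across seeds."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.uniform(10, 120, 10_000)
        y = 2.0 * np.sqrt(x) + rng.normal(0, 0.01, x.size)
        hits += fit_fp(y, x, degree=1).powers == (0.5,)
    assert hits >= 9


def test_exhaustive_search_beats_every_candidate():
    rng = np.random.default_rng(7)
    x = rng.uniform(10, 120, 3_000)
    y = 0.02 * x - 3.0 * np.log(x) + rng.normal(0, 1.0, x.size)
    for degree in (1, 2):
        best = fit_fp(y, x, degree=degree)
        for powers in fp_power_sets(degree):
            assert best.deviance <= fit_fp_fixed(y, x, powers=powers).deviance + 1e-8


def test_compare_identical_fits_gives_p_one():
    rng = np.random.default_rng(1)
    x = rng.uniform(10, 100, 500)
    y = x + rng.normal(0, 1, 500)
    fit = fit_fp(y, x, degree=1)
    res = compare_fp(fit, fit)
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_compare_mismatched_n_raises():
    rng = np.random.default_rng(2)
    x = rng.uniform(10, 100, 400)
    y = x + rng.normal(0, 1, 400)
    a = fit_linear(y, x)
    b = fit_linear(y[:300], x[:300])
    with pytest.raises(IncomparableFitsError):
        compare_fp(a, b)


def test_lr_df_convention():
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 100, 1_000)
    y = np.log(x) ** 2 + rng.normal(0, 0.5, 1_000)
    lin = fit_linear(y, x)
    fp1, fp2 = fit_fp(y, x, degree=1), fit_fp(y, x, degree=2)
    assert compare_fp(lin, fp1).df == 1
    assert compare_fp(fp1, fp2).df == 2
    assert compare_fp(lin, fp2).df == 3


def test_compare_statistic_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(4)
    n = 2_000
    x = rng.uniform(10, 100, n)
    c = rng.normal(0, 1, (n, 2))
    y = 0.05 * x + c @ [1.0, -0.5] + rng.normal(0, 1, n)
    s1 = compare_fp(fit_linear(y, x, c), fit_fp(y, x, c, degree=1)).statistic
    c2 = c * [1000.0, 0.01] + [5.0, -7.0]
    s2 = compare_fp(fit_linear(y, x, c2), fit_fp(y, x, c2, degree=1)).statistic
    assert s1 == pytest.approx(s2, rel=1e-6, abs=1e-8)


def test_ols_core_matches_statsmodels():
    """Dual-route check: the internal least-squares core agrees with
    statsmodels on coefficients, covariance and Gaussian deviance."""
    import statsmodels.api as sm

    from gripmr.fracpoly import _ols

    rng = np.random.default_rng(11)
    n = 800
    design = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = design @ [1.0, 0.5, -2.0, 0.1] + rng.normal(size=n)
    beta, cov, rss, deviance = _ols(design, y)
    ref = sm.OLS(y, design).fit()
    np.testing.assert_allclose(beta, ref.params, rtol=1e-10)
    np.testing.assert_allclose(cov, ref.cov_params(), rtol=1e-8)
    assert deviance == pytest.approx(-2.0 * ref.llf, rel=1e-10)


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(5)
    x = rng.uniform(10, 100, 200)
    dup = np.column_stack([x, x])  # duplicates the power-1 FP column
    with pytest.raises(SingularFitError):
        fit_fp_fixed(x + rng.normal(0, 1, 200), x, covariates=dup, powers=(1.0,))


class TestCurve:
    def test_zero_at_reference_with_zero_width(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(10, 100, 1_000)
        y = 3 * np.log(x) + rng.normal(0, 1, 1_000)
        fit = fit_fp(y, x, degree=1)
        curve = curve_from_fp(fit, reference=50.0, grid=np.array([25.0, 50.0, 75.0]))
        d, lo, hi = curve.at(50.0)
        assert d == 0.0 and lo == 0.0 and hi == 0.0

    def test_linear_fit_gives_exact_line(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(10, 100, 500)
        y = 4.0 + 0.2 * x
        fit = fit_linear(y, x)
        grid = np.array([20.0, 50.0, 80.0])
        curve = curve_from_fp(fit, 50.0, grid)
        np.testing.assert_allclose(curve.difference, 0.2 * (grid - 50.0), atol=1e-8)

    def test_log_truth_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(10, 150, 2_000)
        fit = fit_fp(3.0 * np.log(x), x, degree=1)
        curve = curve_from_fp(fit, 50.0, np.array([100.0]))
        assert curve.difference[0] == pytest.approx(3.0 * np.log(2.0), abs=1e-6)

    def test_ci_symmetric_and_widens_with_noise(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(10, 100, 3_000)
        grid = np.array([20.0, 35.0, 65.0, 80.0])
        widths = []
        for noise in (0.5, 2.0):
            y = 3 * np.log(x) + rng.normal(0, noise, x.size)
            curve = curve_from_fp(fit_fp_fixed(y, x, powers=(0.0,)), 50.0, grid)
            np.testing.assert_allclose(
                curve.upper95 - curve.difference,
                curve.difference - curve.lower95,
                rtol=1e-9,
            )
            widths.append(curve.upper95 - curve.lower95)
        assert (widths[1] > widths[0]).all()

    def test_grid_must_be_positive(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(10, 100, 200)
        fit = fit_linear(x + rng.normal(0, 1, 200), x)
        with pytest.raises(DomainError):
            curve_from_fp(fit, 50.0, np.array([-5.0, 50.0]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    powers=st.lists(st.sampled_from(FP_POWERS), min_size=1, max_size=2),
    seed=st.integers(0, 10_000),
)
def test_basis_always_finite_for_positive_x(powers, seed):
    x = np.random.default_rng(seed).uniform(0.1, 200.0, 50)
    b = fp_basis(x, tuple(powers))
    assert np.isfinite(b).all()
    assert b.shape == (50, len(powers))
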