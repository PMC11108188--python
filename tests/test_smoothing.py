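import numpy as np
import pytest

from pbranova.smoothing import (
    BasisError,
    RankError,
    basis_matrix,
    build_basis,
    evaluate_curves,
    fit_penalized,
    penalty_matrix,
    saturated_bspline_basis,
    select_lambda_gcv,
    smooth_series,
)


class TestBasisConstruction:
    def test_fourier_count_rounds_up_to_odd(self):
        basis = build_basis("fourier", (1, 60), 10)
        assert basis.n_basis == 11  # constant + 5 sine/cosine pairs
        assert basis.period == 59.0

    def test_bspline_no_interior_breaks_spans_cubics(self):
        basis = build_basis("bspline", (0, 1), 4)
        assert basis.n_basis == 4
        # cubic reproduction: fit t^3 exactly with 4 points
        grid = np.linspace(0, 1, 4)
        fit = fit_penalized((grid, grid[None, :] ** 3, np.array(["a"])), basis, 0.0)
        fine = np.linspace(0, 1, 50)
        vals = evaluate_curves(fit, fine).values[0]
        np.testing.assert_allclose(vals, fine**3, atol=1e-10)

    def test_transition_outside_domain_rejected(self):
        with pytest.raises(BasisError, match="outside"):
            build_basis("bspline", (0, 10), 12, transitions=[15.0])

    def test_triple_knot_breaks_first_derivative_not_value(self):
        basis = build_basis("bspline", (0, 40), 20, transitions=[20.0],
                            transition_multiplicity=3)
        grid = np.linspace(0, 40, 401)
        coef = np.sin(np.arange(basis.n_basis))  # arbitrary smooth-ish coefficients
        eps = 1e-6
        f = lambda x, d: basis_matrix(basis, np.array(x), d) @ coef
        left, right = f([20 - eps], 0)[0], f([20 + eps], 0)[0]
        dleft, dright = f([20 - eps], 1)[0], f([20 + eps], 1)[0]
        assert abs(left - right) < 1e-4          # value continuous
        assert abs(dleft - dright) > 1e-3        # slope jumps


class TestBasisMatrix:
    def test_constant_derivative_is_zero(self):
        basis = build_basis("fourier", (0, 10), 5)
        M = basis_matrix(basis, np.linspace(0, 10, 7), 1)
        np.testing.assert_array_equal(M[:, 0], 0.0)

    def test_fourier_sine_derivative_closed_form(self):
        basis = build_basis("fourier", (0, 10), 3, period=10.0)
        M = basis_matrix(basis, np.array([0.0]), 1)
        # d/dt sin(2 pi t / P) at t=0 is 2 pi / P
        assert M[0, 1] == pytest.approx(2 * np.pi / 10.0)

    def test_bspline_partition_of_unity(self):
        basis = build_basis("bspline", (0, 50), 20)
        M = basis_matrix(basis, np.linspace(0, 50, 101), 0)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)

    def test_deriv_order_at_spline_order_rejected(self):
        basis = build_basis("bspline", (0, 1), 6)
        with pytest.raises(BasisError):
            basis_matrix(basis, np.array([0.5]), 4)


class TestPenaltyMatrix:
    def test_symmetric(self):
        basis = build_basis("bspline", (0, 10), 12)
        R = penalty_matrix(basis)
        np.testing.assert_allclose(R, R.T, atol=1e-10)

    def test_straight_line_has_zero_roughness(self):
        basis = build_basis("bspline", (0, 1), 8)
        R = penalty_matrix(basis, 2)
        grid = np.linspace(0, 1, 8)
        fit = fit_penalized((grid, (2 * grid + 1)[None, :], np.array(["a"])), basis, 0.0)
        c = fit.coefficients[0]
        assert c @ R @ c == pytest.approx(0.0, abs=1e-8)

    def test_quadratic_roughness_matches_closed_form(self):
        # for f(t) = t^2 on [0,1], integral of (f'')^2 is 4
        basis = build_basis("bspline", (0, 1), 8)
        R = penalty_matrix(basis, 2)
        grid = np.linspace(0, 1, 8)
        fit = fit_penalized((grid, (grid**2)[None, :], np.array(["a"])), basis, 0.0)
        c = fit.coefficients[0]
        assert c @ R @ c == pytest.approx(4.0, rel=1e-6)


class TestPenalizedFit:
    def test_interpolation_when_saturated_and_unpenalized(self):
        grid = np.linspace(0, 10, 9)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, 9))
        basis = build_basis("bspline", (0, 10), 9)
        fit = fit_penalized((grid, y, np.array(["a", "a", "b"])), basis, 0.0)
        vals = evaluate_curves(fit, grid).values
        np.testing.assert_allclose(vals, y, atol=1e-8)

    def test_constant_data_fit_exactly_at_any_lambda(self):
        grid = np.linspace(1, 60, 60)
        y = np.full((2, 60), 5.0)
        basis = build_basis("bspline", (1, 60), 20)
        for lam in (0.0, 1.0, 1e6):
            fit = fit_penalized((grid, y, np.array(["a", "a"])), basis, lam)
            np.testing.assert_allclose(
                evaluate_curves(fit, grid).values, 5.0, atol=1e-6
            )

    def test_huge_lambda_approaches_least_squares_line(self):
        grid = np.linspace(0, 10, 21)
        rng = np.random.default_rng(1)
        y = (1.5 * grid + rng.normal(0, 0.5, 21))[None, :]
        basis = build_basis("bspline", (0, 10), 15)
        fit = fit_penalized((grid, y, np.array(["a"])), basis, 1e10)
        smoothed = evaluate_curves(fit, grid).values[0]
        slope, icept = np.polyfit(grid, y[0], 1)
        np.testing.assert_allclose(smoothed, slope * grid + icept, atol=1e-3)

    def test_oversaturated_unpenalized_raises_rank_error(self):
        grid = np.linspace(0, 1, 5)
        basis = build_basis("bspline", (0, 1), 10)
        with pytest.raises(RankError, match="lambda"):
            fit_penalized((grid, np.zeros((1, 5)), np.array(["a"])), basis, 0.0)

    def test_smoothing_operator_is_linear(self):
        grid = np.linspace(0, 10, 15)
        rng = np.random.default_rng(3)
        y1, y2 = rng.normal(size=15), rng.normal(size=15)
        basis = build_basis("bspline", (0, 10), 10)
        lab = np.array(["a"])
        f = lambda y: fit_penalized((grid, y[None, :], lab), basis, 2.5).coefficients[0]
        np.testing.assert_allclose(
            f(2 * y1 - 3 * y2), 2 * f(y1) - 3 * f(y2), atol=1e-8
        )


class TestGCV:
    def test_line_plus_tiny_noise_prefers_heaviest_smoothing(self):
        grid = np.linspace(0, 10, 30)
        rng = np.random.default_rng(5)
        y = (2 * grid + 1 + rng.normal(0, 1e-4, 30))[None, :]
        basis = build_basis("bspline", (0, 10), 20)
        lam_grid = np.logspace(-2, 6, 9)
        lam, _ = select_lambda_gcv((grid, y, np.array(["a"])), basis, lam_grid)
        assert lam == pytest.approx(lam_grid[-1])

    def test_df_nonincreasing_in_lambda(self):
        grid = np.linspace(0, 10, 25)
        rng = np.random.default_rng(6)
        y = rng.normal(size=(1, 25))
        basis = build_basis("bspline", (0, 10), 20)
        _, trace = select_lambda_gcv(
            (grid, y, np.array(["a"])), basis, np.logspace(-3, 3, 13)
        )
        assert np.all(np.diff(trace["df"]) <= 1e-9)

    def test_single_candidate_returned(self):
        grid = np.linspace(0, 10, 12)
        y = np.sin(grid)[None, :]
        basis = build_basis("bspline", (0, 10), 8)
        lam, _ = select_lambda_gcv((grid, y, np.array(["a"])), basis, [0.7])
        assert lam == 0.7


class TestEvaluation:
    def test_first_derivative_matches_finite_differences(self):
        grid = np.linspace(1, 60, 60)
        y = (70 + 40 * np.sin(np.pi * grid / 15))[None, :]
        basis = build_basis("fourier", (1, 60), 21)
        fit = smooth_series((grid, y, np.array(["a"])), basis)
        fine = np.linspace(2, 59, 500)
        deriv = evaluate_curves(fit, fine, deriv_order=1).values[0]
        h = 1e-4
        fd = (
            evaluate_curves(fit, fine + h).values[0]
            - evaluate_curves(fit, fine - h).values[0]
        ) / (2 * h)
        np.testing.assert_allclose(deriv, fd, atol=1e-4)

    def test_sine_derivative_peak_magnitude(self):
        grid = np.linspace(1, 60, 60)
        y = (40 * np.sin(np.pi * grid / 15))[None, :]
        basis = build_basis("fourier", (1, 60), 41)
        fit = smooth_series((grid, y, np.array(["a"])), basis)
        fine = np.linspace(5, 55, 2000)
        deriv = evaluate_curves(fit, fine, deriv_order=1).values[0]
        assert deriv.max() == pytest.approx(40 * np.pi / 15, rel=0.02)

    def test_negative_clipping_sets_flag_only_at_order_zero(self):
        grid = np.linspace(0, 10, 11)
        y = (np.linspace(-2, 2, 11))[None, :]
        basis = build_basis("bspline", (0, 10), 6)
        fit = fit_penalized((grid, y, np.array(["a"])), basis, 1e-6)
        clipped = evaluate_curves(fit, grid, clip_negative=True)
        assert clipped.clipped and clipped.values.min() == 0.0
        deriv = evaluate_curves(fit, grid, deriv_order=1, clip_negative=True)
        assert not deriv.clipped

    def test_grid_outside_domain_rejected(self):
        basis = build_basis("bspline", (0, 10), 6)
        grid = np.linspace(0, 10, 11)
        fit = fit_penalized((grid, np.zeros((1, 11)), np.array(["a"])), basis, 1.0)
        with pytest.raises(BasisError, match="domain"):
            evaluate_curves(fit, np.array([11.0]))

    def test_saturated_basis_from_grid_counts_knots(self):
        grid = np.arange(11.0, 51.0)
        basis = saturated_bspline_basis(grid, transitions=[20.0, 30.0, 40.0])
        # 38 interior points, 3 of them at multiplicity 3 -> 38 + 6 + order
        assert basis.n_basis == 38 + 6 + 4
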