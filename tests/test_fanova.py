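from itertools import combinations

import numpy as np
import pytest

from pbranova.baselines import univariate_anova
from pbranova.fanova import (
    BalanceError,
    estimate_effects,
    fft_statistic,
    permutation_test,
    pointwise_f,
)
from pbranova.simulator import SimDesign, simulate_pbr
from pbranova.smoothing import CurveSet, build_basis, evaluate_curves, smooth_series


def exhaustive_fft(values, grid, group_size):
    """Oracle: F_FT over every equal-size relabeling, by direct enumeration."""
    n_subj = values.shape[0]
    stats = []
    for combo in combinations(range(n_subj), group_size):
        labels = np.array(["B"] * n_subj)
        labels[list(combo)] = "A"
        cs = CurveSet(grid=grid, values=values, groups=labels)
        fit = estimate_effects(cs)
        stats.append(fft_statistic(fit.ssa, fit.sse, fit.q_a, fit.q_e, grid))
    return np.array(stats)


class TestEffects:
    def test_toy_effects_by_hand(self, toy_constant_curves):
        fit = estimate_effects(toy_constant_curves)
        np.testing.assert_allclose(fit.mu_hat, 1.5)
        np.testing.assert_allclose(fit.alpha_hat["A"], -0.5)
        np.testing.assert_allclose(fit.alpha_hat["B"], 0.5)
        np.testing.assert_allclose(fit.ssa, 1.0)
        np.testing.assert_allclose(fit.sse, 4.0)
        np.testing.assert_allclose(fit.f_curve, 0.5)
        assert (fit.q_a, fit.q_e) == (1, 2)

    def test_identical_curves_give_zero_effects(self):
        values = np.tile(np.sin(np.linspace(0, 3, 20)), (4, 1))
        cs = CurveSet(grid=np.linspace(0, 3, 20), values=values,
                      groups=np.array(["a", "a", "b", "b"]))
        fit = estimate_effects(cs)
        for a in fit.alpha_hat.values():
            np.testing.assert_allclose(a, 0.0, atol=1e-12)

    def test_effects_sum_to_zero_on_simulated_data(self):
        table = simulate_pbr(SimDesign(seed=11, n_per_group=4))
        values, labels, _ = table.to_matrix()
        fit = estimate_effects(CurveSet(grid=table.grid, values=values, groups=labels))
        total = sum(fit.alpha_hat.values())
        np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_ss_decomposition(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 5, 30)
        values = rng.normal(size=(6, 30))
        cs = CurveSet(grid=grid, values=values,
                      groups=np.array(["a", "a", "b", "b", "c", "c"]))
        fit = estimate_effects(cs)
        sst = np.sum((values - values.mean(axis=0)) ** 2, axis=0)
        np.testing.assert_allclose(fit.ssa + fit.sse, sst, rtol=1e-10)

    def test_unbalanced_groups_rejected(self):
        cs = CurveSet(grid=np.array([0.0, 1.0]), values=np.zeros((3, 2)),
                      groups=np.array(["a", "a", "b"]))
        with pytest.raises(BalanceError):
            estimate_effects(cs)


class TestPointwiseF:
    def test_pointwise_f_equals_univariate_anova_at_every_grid_point(self):
        table = simulate_pbr(SimDesign(seed=3, n_per_group=5))
        values, labels, _ = table.to_matrix()
        cs = CurveSet(grid=table.grid, values=values, groups=labels)
        fit = estimate_effects(cs)
        for k in range(0, len(cs.grid), 7):
            oracle = univariate_anova(values[:, k], labels)["factor"].f
            assert fit.f_curve[k] == pytest.approx(oracle, rel=1e-10)

    def test_zero_ssa_gives_zero_f(self):
        f = pointwise_f(np.zeros(5), np.ones(5), 2, 10)
        np.testing.assert_array_equal(f, 0.0)

    def test_zero_sse_with_signal_gives_infinity(self):
        f = pointwise_f(np.array([1.0]), np.array([0.0]), 1, 2)
        assert np.isinf(f[0])


class TestFftStatistic:
    def test_constant_f_toy_gives_half_on_any_region(self, toy_constant_curves):
        fit = estimate_effects(toy_constant_curves)
        for region in (None, (0.0, 1.0), (0.0, 2.0), (1.0, 2.0)):
            assert fft_statistic(
                fit.ssa, fit.sse, fit.q_a, fit.q_e, fit.grid, region
            ) == pytest.approx(0.5)

    def test_region_integrals_are_additive(self):
        rng = np.random.default_rng(9)
        grid = np.linspace(0, 10, 101)
        values = rng.normal(size=(6, 101)) + np.sin(grid)
        cs = CurveSet(grid=grid, values=values,
                      groups=np.array(["a"] * 3 + ["b"] * 3))
        fit = estimate_effects(cs)

        def integrals(region):
            mask = (grid >= region[0] - 1e-9) & (grid < region[1] - 1e-9)
            mask |= np.isclose(grid, region[1])
            return (np.trapezoid(fit.ssa[mask], grid[mask]),
                    np.trapezoid(fit.sse[mask], grid[mask]))

        na, da = integrals((0, 5))
        nb, db = integrals((5, 10))
        nf, df_ = integrals((0, 10))
        assert na + nb == pytest.approx(nf)
        assert da + db == pytest.approx(df_)

    def test_two_point_grid_reduces_to_pointwise_anova(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=6)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        values = np.tile(vals[:, None], (1, 2))  # constant over a 2-point grid
        cs = CurveSet(grid=np.array([0.0, 1.0]), values=values, groups=labels)
        fit = estimate_effects(cs)
        fft = fft_statistic(fit.ssa, fit.sse, fit.q_a, fit.q_e, fit.grid)
        oracle = univariate_anova(vals, labels)["factor"].f
        assert fft == pytest.approx(oracle, rel=1e-12)

    def test_empty_region_rejected(self, toy_constant_curves):
        fit = estimate_effects(toy_constant_curves)
        with pytest.raises(ValueError, match="region"):
            fft_statistic(fit.ssa, fit.sse, fit.q_a, fit.q_e, fit.grid, (5.0, 6.0))


class TestPermutationTest:
    def test_toy_permutation_multiset_matches_exhaustive_enumeration(
        self, toy_constant_curves
    ):
        stats = exhaustive_fft(toy_constant_curves.values, toy_constant_curves.grid, 2)
        np.testing.assert_allclose(np.sort(stats), [0, 0, 0.5, 0.5, 8, 8], atol=1e-12)
        # strict exceedance of the observed 0.5 over the 6 relabelings
        assert np.mean(stats > 0.5) == pytest.approx(2 / 6)

    def test_random_permutation_p_converges_to_exhaustive(self, toy_constant_curves):
        r = 30_000
        res = permutation_test(toy_constant_curves, r=r, seed=12, pointwise=False)
        p_exact = 2 / 6
        se = np.sqrt(p_exact * (1 - p_exact) / r)
        assert abs(res.p_value - p_exact) < 3 * se

    def test_identical_curves_flagged_degenerate(self):
        values = np.tile(np.linspace(0, 1, 10), (4, 1))
        cs = CurveSet(grid=np.linspace(0, 1, 10), values=values,
                      groups=np.array(["a", "a", "b", "b"]))
        res = permutation_test(cs, r=50, seed=0, pointwise=False)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_group_renaming_leaves_statistics_unchanged(self, toy_constant_curves):
        res1 = permutation_test(toy_constant_curves, r=200, seed=5, pointwise=False)
        renamed = CurveSet(
            grid=toy_constant_curves.grid,
            values=toy_constant_curves.values,
            groups=np.array(["ctrl", "ctrl", "dosed", "dosed"]),
        )
        res2 = permutation_test(renamed, r=200, seed=5, pointwise=False)
        assert res1.f_ft_obs == pytest.approx(res2.f_ft_obs)
        np.testing.assert_allclose(res1.f_ft_perm, res2.f_ft_perm)

    def test_scale_equivariance(self, toy_constant_curves):
        scaled = CurveSet(
            grid=toy_constant_curves.grid,
            values=7.3 * toy_constant_curves.values,
            groups=toy_constant_curves.groups,
        )
        f1 = estimate_effects(toy_constant_curves)
        f2 = estimate_effects(scaled)
        np.testing.assert_allclose(f1.f_curve, f2.f_curve)

    def test_seed_reproducibility(self, toy_constant_curves):
        a = permutation_test(toy_constant_curves, r=100, seed=42)
        b = permutation_test(toy_constant_curves, r=100, seed=42)
        np.testing.assert_array_equal(a.f_ft_perm, b.f_ft_perm)
        np.testing.assert_array_equal(a.pointwise_envelope, b.pointwise_envelope)

    def test_envelope_has_region_grid_length(self, toy_constant_curves):
        res = permutation_test(toy_constant_curves, region=(0.0, 1.0), r=50, seed=1)
        assert len(res.pointwise_envelope) == 2

    def test_rejects_strong_group_separation_on_smoothed_simulation(self):
        table = simulate_pbr(SimDesign(seed=21, n_per_group=10))
        basis = build_basis("fourier", (1, 60), 10)
        curves = evaluate_curves(smooth_series(table, basis))
        res = permutation_test(curves, r=300, seed=2, pointwise=False)
        assert res.p_value == 0.0
        assert res.f_ft_obs > res.critical
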