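"""One-way functional ANOVA: effects, F(t), the integrated F_FT statistic and
its permutation null distribution.

The model is y_ij(t) = mu(t) + alpha_i(t) + eps_ij(t) on a balanced design
with a groups of n curves each.  At every grid point the usual one-way
decomposition applies:

    SSA(t) = n * sum_i alpha_i(t)^2          (df q_A = a - 1)
    SSE(t) = sum_ij (y_ij(t) - ybar_i(t))^2  (df q_E = a (n - 1))
    F(t)   = [SSA(t)/q_A] / [SSE(t)/q_E]

The scalar test statistic integrates numerator and denominator before taking
the ratio:

    F_FT = [∫ SSA(t) dt / q_A] / [∫ SSE(t) dt / q_E]

Its null distribution is approximated by permuting whole-curve group labels
(preserving group sizes) and recomputing F_FT; the critical value is the
100(1-tau)th percentile of the permuted values and the p-value is the
proportion of permuted statistics strictly exceeding the observed one (so a
p-value of exactly 0 is possible and is how an extreme observed statistic is
reported).  The only assumption is that subjects are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .smoothing import CurveSet

__all__ = [
    "FanovaFit",
    "PermutationResult",
    "estimate_effects",
    "pointwise_ss",
    "pointwise_f",
    "fft_statistic",
    "permutation_test",
    "BalanceError",
]


class BalanceError(ValueError):
    """Groups are not balanced (equal size) as the decomposition requires."""


@dataclass
class FanovaFit:
    """Estimated functional effects and pointwise sums of squares."""

    grid: np.ndarray
    mu_hat: np.ndarray            # grand-mean curve
    alpha_hat: dict               # group label -> effect curve
    ssa: np.ndarray
    sse: np.ndarray
    f_curve: np.ndarray
    q_a: int
    q_e: int
    groups: np.ndarray            # unique labels, first-appearance order
    n_per_group: int


@dataclass
class PermutationResult:
    """Observed F_FT, its permutation distribution and derived quantities."""

    f_ft_obs: float
    f_ft_perm: np.ndarray
    r: int
    tau: float
    critical: float
    p_value: float
    seed: int | None
    pointwise_envelope: np.ndarray | None = None
    degenerate: bool = False


def _group_index(curves: CurveSet) -> tuple[np.ndarray, np.ndarray, int]:
    labels = curves.group_labels
    sizes = np.array([(curves.groups == g).sum() for g in labels])
    if len(labels) < 2:
        raise BalanceError("at least 2 groups are required")
    if not np.all(sizes == sizes[0]):
        raise BalanceError(
            f"unbalanced groups: sizes {dict(zip(labels.tolist(), sizes.tolist()))}"
        )
    return labels, sizes, int(sizes[0])


def estimate_effects(curves: CurveSet) -> FanovaFit:
    """Estimate mu(t) and alpha_i(t) and fill in SS, F(t) and the dfs."""
    labels, _, n = _group_index(curves)
    a = len(labels)
    if n < 2:
        raise BalanceError("at least 2 subjects per group are required")
    mu = curves.values.mean(axis=0)
    alpha = {g: curves.values[curves.groups == g].mean(axis=0) - mu for g in labels}
    fit = FanovaFit(
        grid=curves.grid,
        mu_hat=mu,
        alpha_hat=alpha,
        ssa=np.zeros_like(mu),
        sse=np.zeros_like(mu),
        f_curve=np.zeros_like(mu),
        q_a=a - 1,
        q_e=a * (n - 1),
        groups=labels,
        n_per_group=n,
    )
    fit.ssa, fit.sse = pointwise_ss(curves, fit)
    fit.f_curve = pointwise_f(fit.ssa, fit.sse, fit.q_a, fit.q_e)
    return fit


def pointwise_ss(curves: CurveSet, fit: FanovaFit) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise hypothesis and error sums of squares."""
    n = fit.n_per_group
    ssa = n * sum(a**2 for a in fit.alpha_hat.values())
    sse = np.zeros_like(fit.mu_hat)
    for g in fit.groups:
        block = curves.values[curves.groups == g]
        sse += np.sum((block - block.mean(axis=0)) ** 2, axis=0)
    return ssa, sse


def pointwise_f(
    ssa: np.ndarray, sse: np.ndarray, q_a: int, q_e: int
) -> np.ndarray:
    """F(t) = [SSA/q_a] / [SSE/q_e]; +inf where SSE=0 < SSA, 0 where both 0."""
    if q_a < 1 or q_e < 1:
        raise ValueError("degrees of freedom must be >= 1")
    ssa = np.asarray(ssa, float)
    sse = np.asarray(sse, float)
    f = np.empty_like(ssa)
    zero_e = sse == 0
    both = zero_e & (ssa == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssa / q_a) / (sse / q_e)
    f[zero_e] = np.inf
    if both.any():
        warnings.warn("SSA and SSE both zero at some grid points; F set to 0 there")
        f[both] = 0.0
    return f


def _region_mask(grid: np.ndarray, region: tuple[float, float] | None) -> np.ndarray:
    if region is None:
        return np.ones_like(grid, bool)
    start, end = float(region[0]), float(region[1])
    mask = (grid >= start - 1e-9) & (grid < end - 1e-9)
    mask |= np.isclose(grid, end)  # share the boundary ordinate with the neighbor
    return mask


def fft_statistic(
    ssa: np.ndarray,
    sse: np.ndarray,
    q_a: int,
    q_e: int,
    grid: np.ndarray,
    region: tuple[float, float] | None = None,
) -> float:
    """Integrated F statistic over a region via the trapezoid rule.

    Grid points where SSE is exactly zero (possible only through clipping
    artifacts) are excluded from both integrals with a warning.
    """
    mask = _region_mask(np.asarray(grid, float), region)
    if mask.sum() < 2:
        raise ValueError(f"region {region} covers fewer than 2 grid points")
    t = np.asarray(grid, float)[mask]
    sa = np.asarray(ssa, float)[mask]
    se = np.asarray(sse, float)[mask]
    finite = se > 0
    if not finite.all():
        if finite.sum() < 2:
            raise ValueError("SSE is zero across the region; F_FT undefined")
        warnings.warn("excluding grid points with SSE = 0 from the F_FT integrals")
        t, sa, se = t[finite], sa[finite], se[finite]
    num = np.trapezoid(sa, t) / q_a
    den = np.trapezoid(se, t) / q_e
    return float(num / den)


def _fft_from_values(
    values: np.ndarray,
    group_codes: np.ndarray,
    a: int,
    n: int,
    t: np.ndarray,
    q_a: int,
    q_e: int,
    return_f_curve: bool = False,
):
    """F_FT (and optionally F(t)) from a subjects-by-grid value matrix.

    Vectorized over groups via an indicator matrix; used by the permutation
    loop where effects are re-estimated thousands of times.
    """
    P = np.zeros((a, values.shape[0]))
    P[group_codes, np.arange(values.shape[0])] = 1.0
    gmeans = (P @ values) / n
    mu = values.mean(axis=0)
    ssa = n * np.sum((gmeans - mu) ** 2, axis=0)
    sst = np.sum((values - mu) ** 2, axis=0)
    sse = sst - ssa
    num = np.trapezoid(ssa, t) / q_a
    den = np.trapezoid(sse, t) / q_e
    fft = float(num / den) if den > 0 else np.inf
    if not return_f_curve:
        return fft, None
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sse > 0, (ssa / q_a) / (sse / q_e), np.inf)
        f[(sse <= 0) & (ssa == 0)] = 0.0
    return fft, f


def permutation_test(
    curves: CurveSet,
    region: tuple[float, float] | None = None,
    r: int = 10_000,
    tau: float = 0.05,
    seed: int | None = None,
    *,
    pointwise: bool = True,
) -> PermutationResult:
    """Permutation calibration of the F_FT statistic.

    Whole curves are reassigned to groups uniformly at random (group sizes
    preserved) ``r`` times.  Returns the observed statistic, the permutation
    distribution, the 100(1-tau)th-percentile critical value (linear
    interpolation between order statistics), the strict-exceedance p-value
    and, if ``pointwise``, the pointwise 100(1-tau)th percentile envelope of
    the permuted F(t) curves.
    """
    if r < 1:
        raise ValueError("permutation count r must be >= 1")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    labels, _, n = _group_index(curves)
    a = len(labels)
    if a * n < 3:
        raise BalanceError("too few curves to permute meaningfully")
    code_of = {g: i for i, g in enumerate(labels)}
    codes = np.array([code_of[g] for g in curves.groups])

    mask = _region_mask(curves.grid, region)
    if mask.sum() < 2:
        raise ValueError(f"region {region} covers fewer than 2 grid points")
    t = curves.grid[mask]
    values = curves.values[:, mask]
    q_a, q_e = a - 1, a * (n - 1)

    obs, _ = _fft_from_values(values, codes, a, n, t, q_a, q_e)

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(r)
    envelope = None
    f_perm = np.empty((r, len(t))) if pointwise else None
    for i in range(r):
        shuffled = rng.permutation(codes)
        fft, f = _fft_from_values(
            values, shuffled, a, n, t, q_a, q_e, return_f_curve=pointwise
        )
        perm_stats[i] = fft
        if pointwise:
            f_perm[i] = f
    critical = float(np.quantile(perm_stats, 1.0 - tau))
    p_value = float(np.mean(perm_stats > obs))
    if pointwise:
        envelope = np.quantile(f_perm, 1.0 - tau, axis=0)
    degenerate = bool(np.allclose(perm_stats, perm_stats[0]) or obs == 0.0)
    return PermutationResult(
        f_ft_obs=obs,
        f_ft_perm=perm_stats,
        r=r,
        tau=tau,
        critical=critical,
        p_value=p_value,
        seed=seed,
        pointwise_envelope=envelope,
        degenerate=degenerate,
    )
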