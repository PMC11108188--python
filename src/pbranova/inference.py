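"""Residual-bootstrap confidence bands and Bonferroni post hoc testing.

Bands
-----
After fitting the functional ANOVA, each subject leaves a residual curve
nu_ij(t) = y_ij(t) - mu(t) - alpha_i(t).  Bootstrap datasets are built by
resampling these residual curves with replacement from the pooled set of all
a*n of them and reattaching them to the fitted effects,
y*_ij(t) = nu*(t) + mu(t) + alpha_i(t).  Effects are re-estimated per
replicate, the difference curves (bootstrap minus observed) are collected,
and the pointwise percentiles of those differences added to the observed
estimate form the band.  Bands are pointwise only: they are interpretable at
each t, not simultaneously over the domain.

Post hoc tests
--------------
After an omnibus rejection, pairwise contrasts alpha_i(t) - alpha_i'(t) are
tested by restricting the curve set to the two groups involved and rerunning
the F_FT permutation test, either over the full analysis window or within
each lighting period.  Bonferroni correction divides the nominal level tau by
the number of tests in each family; contrasts that fail the full-domain test
are dropped before subregion testing (hierarchical flow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .fanova import FanovaFit, PermutationResult, estimate_effects, permutation_test
from .io_design import Region
from .smoothing import CurveSet

__all__ = [
    "BootstrapBand",
    "PosthocTest",
    "PosthocReport",
    "subject_effects",
    "bootstrap_bands",
    "contrast_curves",
    "posthoc_fft",
]


@dataclass
class BootstrapBand:
    """Pointwise confidence envelope around an effect or contrast curve."""

    target: str
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    b: int
    seed: int | None


@dataclass
class PosthocTest:
    contrast: str
    region: str
    f_ft_crit: float
    f_ft_obs: float
    p_value: float
    adjusted_level: float
    decision: str  # "Reject" or "FTR"


@dataclass
class PosthocReport:
    family: list
    nominal_tau: float
    n_tests: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "region": t.region,
                    "H0": t.contrast,
                    "FFTcrit": t.f_ft_crit,
                    "FFTobs": t.f_ft_obs,
                    "p_value": t.p_value,
                    "sig_level": t.adjusted_level,
                    "decision": t.decision,
                }
                for t in self.family
            ]
        )


def subject_effects(curves: CurveSet, fit: FanovaFit) -> np.ndarray:
    """Residual curves nu_ij(t) = y_ij(t) - mu(t) - alpha_i(t), one per row.

    Their group-wise pointwise mean is identically zero by construction.
    """
    resid = np.empty_like(curves.values)
    for g in fit.groups:
        mask = curves.groups == g
        resid[mask] = curves.values[mask] - fit.mu_hat - fit.alpha_hat[g]
    return resid


def _targets_from(mu: np.ndarray, alpha: dict, targets: Sequence[str]) -> dict:
    """Map target names to their curves.

    Names: ``overall_mean``, ``effect:<group>``, ``contrast:<g1>-<g2>``.
    """
    by_str = {str(g): g for g in alpha}
    out = {}
    for name in targets:
        if name == "overall_mean":
            out[name] = mu
        elif name.startswith("effect:"):
            key = name.split(":", 1)[1]
            if key not in by_str:
                raise ValueError(f"unknown group {key!r}; have {sorted(by_str)}")
            out[name] = alpha[by_str[key]]
        elif name.startswith("contrast:"):
            g1, g2 = name.split(":", 1)[1].split("-")
            if g1 == g2:
                raise ValueError(f"self-contrast {name!r}")
            for key in (g1, g2):
                if key not in by_str:
                    raise ValueError(f"unknown group {key!r}; have {sorted(by_str)}")
            out[name] = alpha[by_str[g1]] - alpha[by_str[g2]]
        else:
            raise ValueError(f"unknown band target {name!r}")
    return out


def _targets_for(fit: FanovaFit, targets: Sequence[str]) -> dict:
    return _targets_from(fit.mu_hat, fit.alpha_hat, targets)


def _find_group(fit: FanovaFit, label: str):
    for g in fit.groups:
        if str(g) == label:
            return g
    raise ValueError(f"unknown group {label!r}; have {[str(g) for g in fit.groups]}")


def bootstrap_bands(
    curves: CurveSet,
    fit: FanovaFit,
    targets: Sequence[str],
    b: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    *,
    pool: str = "all",
    orientation: str = "percentile",
) -> list[BootstrapBand]:
    """Pointwise bootstrap bands for effects and contrasts.

    Residual curves are resampled with replacement from the pooled set of all
    subjects (``pool="all"``; ``pool="group"`` restricts resampling within
    each group) and reattached to the fitted effects; effects are then
    re-estimated.  With ``orientation="percentile"`` the band is the observed
    estimate plus the (1±level)/2 pointwise percentiles of the
    bootstrap-minus-observed difference curves; ``orientation="basic"``
    reflects the percentiles about the estimate.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if b < 20:
        warnings.warn(f"b={b} bootstrap replicates give unstable percentile bands")
    if pool not in ("all", "group"):
        raise ValueError("pool must be 'all' or 'group'")
    if orientation not in ("percentile", "basic"):
        raise ValueError("orientation must be 'percentile' or 'basic'")

    resid = subject_effects(curves, fit)
    observed = _targets_for(fit, targets)
    fitted = curves.values - resid  # mu + alpha_i per row

    rng = np.random.default_rng(seed)
    n_subj = resid.shape[0]
    diffs = {name: np.empty((b, len(curves.grid))) for name in targets}
    group_rows = {g: np.where(curves.groups == g)[0] for g in fit.groups}
    for rep in range(b):
        if pool == "all":
            pick = rng.integers(0, n_subj, size=n_subj)
        else:
            pick = np.empty(n_subj, int)
            for rows in group_rows.values():
                pick[rows] = rng.choice(rows, size=len(rows), replace=True)
        boot_values = fitted + resid[pick]
        mu_b = boot_values.mean(axis=0)
        alpha_b = {
            g: boot_values[rows].mean(axis=0) - mu_b for g, rows in group_rows.items()
        }
        bcurves = _targets_from(mu_b, alpha_b, targets)
        for name in targets:
            diffs[name][rep] = bcurves[name] - observed[name]

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    bands = []
    for name in targets:
        d_lo = np.quantile(diffs[name], lo_q, axis=0)
        d_hi = np.quantile(diffs[name], hi_q, axis=0)
        est = observed[name]
        if orientation == "percentile":
            lower, upper = est + d_lo, est + d_hi
        else:  # basic bootstrap: reflect the percentiles
            lower, upper = est - d_hi, est - d_lo
        bands.append(
            BootstrapBand(
                target=name, grid=curves.grid, estimate=est,
                lower=lower, upper=upper, level=level, b=b, seed=seed,
            )
        )
    return bands


def contrast_curves(
    fit: FanovaFit, mode: str = "all_pairs", control: str | None = None
) -> dict[str, np.ndarray]:
    """Pairwise effect differences alpha_i(t) - alpha_i'(t).

    ``all_pairs`` yields a(a-1)/2 contrasts; ``vs_control`` yields a-1
    contrasts of each group against the named control.
    """
    groups = list(fit.groups)
    if mode == "all_pairs":
        pairs = list(combinations(groups, 2))
    elif mode == "vs_control":
        if control is None:
            raise ValueError("vs_control mode requires a control label")
        c = _find_group(fit, str(control))
        pairs = [(g, c) for g in groups if g != c]
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    return {
        f"{g1}-{g2}": fit.alpha_hat[g1] - fit.alpha_hat[g2] for g1, g2 in pairs
    }


def _contrast_pairs(
    fit: FanovaFit, mode: str, control: str | None
) -> list[tuple]:
    groups = list(fit.groups)
    if mode == "all_pairs":
        return list(combinations(groups, 2))
    c = _find_group(fit, str(control))
    return [(g, c) for g in groups if g != c]


def posthoc_fft(
    curves: CurveSet,
    full_region: Region | tuple[float, float],
    subregions: Sequence[Region] = (),
    *,
    mode: str = "all_pairs",
    control: str | None = None,
    r: int = 10_000,
    tau: float = 0.05,
    seed: int | None = None,
    include_omnibus: bool = True,
    hierarchical: bool = True,
) -> PosthocReport:
    """Bonferroni-corrected pairwise F_FT tests over the analysis regions.

    The full-domain family tests every contrast at ``tau / n_contrasts``.
    When ``hierarchical`` (the default), contrasts failing their full-domain
    test are dropped, and the survivors are then tested within each subregion
    at ``tau / (n_survivors * n_subregions)``.  Each test restricts the curve
    set to the two groups involved and runs its own permutation calibration.
    """
    fit = estimate_effects(curves)
    pairs = _contrast_pairs(fit, mode, control)
    rng = np.random.default_rng(seed)
    full = _as_region(full_region, "full")
    tests: list[PosthocTest] = []

    if include_omnibus:
        res = permutation_test(
            curves, (full.start, full.end), r=r, tau=tau,
            seed=int(rng.integers(2**31)), pointwise=False,
        )
        tests.append(_row(res, _omnibus_label(fit), full.name, tau))

    level_full = tau / len(pairs)
    survivors = []
    for g1, g2 in pairs:
        sub = curves.subset_groups([g1, g2])
        res = permutation_test(
            sub, (full.start, full.end), r=r, tau=level_full,
            seed=int(rng.integers(2**31)), pointwise=False,
        )
        row = _row(res, f"{g1}-{g2}", full.name, level_full)
        tests.append(row)
        if row.decision == "Reject" or not hierarchical:
            survivors.append((g1, g2))

    if subregions and survivors:
        m = len(survivors) * len(subregions)
        level_sub = tau / m
        for region in subregions:
            reg = _as_region(region, "region")
            for g1, g2 in survivors:
                sub = curves.subset_groups([g1, g2])
                res = permutation_test(
                    sub, (reg.start, reg.end), r=r, tau=level_sub,
                    seed=int(rng.integers(2**31)), pointwise=False,
                )
                tests.append(_row(res, f"{g1}-{g2}", reg.name, level_sub))

    return PosthocReport(family=tests, nominal_tau=tau, n_tests=len(tests))


def _as_region(region, fallback_name: str) -> Region:
    if isinstance(region, Region):
        return region
    start, end = region
    return Region(fallback_name, float(start), float(end))


def _omnibus_label(fit: FanovaFit) -> str:
    return " = ".join(f"alpha[{g}]" for g in fit.groups)


def _row(res: PermutationResult, contrast: str, region: str, level: float) -> PosthocTest:
    # quantile for the critical value is taken at the test's adjusted level
    crit = float(np.quantile(res.f_ft_perm, 1.0 - level))
    return PosthocTest(
        contrast=contrast,
        region=region,
        f_ft_crit=crit,
        f_ft_obs=res.f_ft_obs,
        p_value=res.p_value,
        adjusted_level=level,
        decision="Reject" if res.p_value < level else "FTR",
    )
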