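"""Basis smoothing of locomotor curves.

Discrete minute-by-minute speed records are converted to smooth functions by
penalized least squares on a basis expansion.  Two basis systems are offered:

* a Fourier basis (constant plus sine/cosine pairs) for periodic data, fit by
  ordinary least squares with a modest number of basis functions;
* a cubic B-spline basis, typically saturated (one knot per observation) and
  regularized by a roughness penalty on the integrated squared second
  derivative, with the penalty weight chosen by generalized cross validation
  (GCV).

B-spline bases can carry extra knot multiplicity at the light/dark transition
times so that the fitted speed stays continuous while its first derivative is
allowed to jump — the feature the startle-response analysis relies on.

Curves and their derivatives are evaluated analytically from the basis
coefficients (never by finite differences) on a fine, evenly spaced grid;
negative speeds may optionally be clipped to zero at evaluation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline

from .io_design import RawSeriesTable

__all__ = [
    "BasisSystem",
    "SmoothCurves",
    "CurveSet",
    "build_basis",
    "saturated_bspline_basis",
    "basis_matrix",
    "penalty_matrix",
    "fit_penalized",
    "select_lambda_gcv",
    "smooth_series",
    "evaluate_curves",
    "BasisError",
    "RankError",
    "DEFAULT_GRID_STEP",
    "DEFAULT_LAMBDA_GRID",
]

#: Evaluation grid spacing in minutes (resolves 3-minute startle windows
#: with 30 points).
DEFAULT_GRID_STEP = 0.1

#: Default grid searched by GCV: 25 log-spaced penalty weights.
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 25)


class BasisError(ValueError):
    """Invalid basis construction request."""


class RankError(np.linalg.LinAlgError):
    """The smoothing normal equations are singular."""


@dataclass(frozen=True)
class BasisSystem:
    """A Fourier or B-spline basis over a closed interval.

    For Fourier bases ``n_basis`` is odd (constant + sine/cosine pairs) and
    ``period`` defaults to the domain width (the convention of the R ``fda``
    package).  For B-splines the full knot vector carries the domain endpoints
    with multiplicity ``order`` plus the interior breakpoints with their
    multiplicities; ``n_basis = len(knots) - order``.
    """

    kind: Literal["fourier", "bspline"]
    domain: tuple[float, float]
    n_basis: int
    period: float | None = None
    order: int = 4
    knots: tuple[float, ...] = ()  # full knot vector (bspline only)

    @property
    def n_harmonics(self) -> int:
        return (self.n_basis - 1) // 2


def build_basis(
    kind: Literal["fourier", "bspline"],
    domain: tuple[float, float],
    n_basis: int,
    *,
    period: float | None = None,
    order: int = 4,
    transitions: Sequence[float] = (),
    transition_multiplicity: int | None = None,
) -> BasisSystem:
    """Construct a basis system.

    Parameters
    ----------
    n_basis
        Requested size.  Fourier sizes are rounded up to the next odd count
        (constant term + whole sine/cosine pairs).  For B-splines the
        ``n_basis - order`` interior knots are placed uniformly, after
        reserving multiplicity at any ``transitions``.
    transitions
        Interior times where a B-spline basis should lose smoothness (the
        light/dark switches).  Each receives multiplicity
        ``transition_multiplicity`` (default ``order - 1``: continuous value,
        discontinuous first derivative).
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise BasisError(f"empty domain [{lo}, {hi}]")
    if n_basis < 1:
        raise BasisError("n_basis must be >= 1")

    if kind == "fourier":
        if transitions:
            raise BasisError("a Fourier basis cannot carry transition knots")
        if n_basis % 2 == 0:
            n_basis += 1  # round up to constant + whole harmonic pairs
        return BasisSystem(
            kind="fourier",
            domain=(lo, hi),
            n_basis=n_basis,
            period=float(period) if period is not None else hi - lo,
        )

    if kind == "bspline":
        mult = transition_multiplicity if transition_multiplicity is not None else order - 1
        if not 1 <= mult <= order:
            raise BasisError(f"transition multiplicity must be in [1, {order}]")
        for t in transitions:
            if not lo < t < hi:
                raise BasisError(f"transition time {t} outside open domain ({lo}, {hi})")
        n_interior = n_basis - order
        n_extra = len(transitions) * mult
        n_uniform = n_interior - n_extra
        if n_uniform < 0:
            raise BasisError(
                f"n_basis={n_basis} too small for {len(transitions)} transitions "
                f"of multiplicity {mult} at order {order}"
            )
        # spread plain knots inside the segments between transitions so they
        # never collide with (and inflate the multiplicity of) a transition
        bounds = [lo, *sorted(float(t) for t in transitions), hi]
        lengths = np.diff(bounds)
        shares = n_uniform * lengths / lengths.sum()
        counts = np.floor(shares).astype(int)
        for _ in range(n_uniform - counts.sum()):
            counts[np.argmax(shares - counts)] += 1
        uniform = np.concatenate(
            [
                a + (b - a) * np.arange(1, c + 1) / (c + 1)
                for a, b, c in zip(bounds[:-1], bounds[1:], counts)
            ]
            or [np.empty(0)]
        )
        interior = np.sort(
            np.concatenate([uniform, np.repeat(np.asarray(transitions, float), mult)])
        )
        knots = np.concatenate([[lo] * order, interior, [hi] * order])
        return BasisSystem(
            kind="bspline",
            domain=(lo, hi),
            n_basis=len(knots) - order,
            order=order,
            knots=tuple(knots),
        )

    raise BasisError(f"unknown basis kind {kind!r}")


def saturated_bspline_basis(
    grid: np.ndarray,
    *,
    order: int = 4,
    transitions: Sequence[float] = (),
    transition_multiplicity: int | None = None,
) -> BasisSystem:
    """B-spline basis with one knot per observation time ("saturated").

    Interior knots sit at the interior observation times; transition times
    that coincide with observation times have their multiplicity raised to
    ``transition_multiplicity`` (default ``order - 1``).
    """
    grid = np.asarray(grid, float)
    lo, hi = grid[0], grid[-1]
    mult = transition_multiplicity if transition_multiplicity is not None else order - 1
    trans = set(float(t) for t in transitions)
    interior: list[float] = []
    for t in grid[1:-1]:
        m = mult if float(t) in trans else 1
        interior.extend([float(t)] * m)
    missing = [t for t in trans if not np.isclose(grid, t).any()]
    if missing:
        raise BasisError(f"transitions {missing} are not observation times")
    knots = np.concatenate([[lo] * order, interior, [hi] * order])
    return BasisSystem(
        kind="bspline", domain=(lo, hi), n_basis=len(knots) - order,
        order=order, knots=tuple(knots),
    )


def basis_matrix(basis: BasisSystem, grid: np.ndarray, deriv_order: int = 0) -> np.ndarray:
    """Evaluate all basis functions (or a derivative) on a grid.

    Returns an array of shape ``(len(grid), n_basis)``.  At a knot of reduced
    continuity the right-hand limit is returned (B-spline convention).
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    lo, hi = basis.domain
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise BasisError(f"grid extends outside basis domain [{lo}, {hi}]")

    if basis.kind == "fourier":
        omega = 2.0 * np.pi / basis.period
        cols = []
        # constant term: derivative of any positive order is zero
        cols.append(np.ones_like(grid) if deriv_order == 0 else np.zeros_like(grid))
        shift = deriv_order * np.pi / 2.0
        for k in range(1, basis.n_harmonics + 1):
            w = k * omega
            amp = w**deriv_order
            cols.append(amp * np.sin(w * grid + shift))
            cols.append(amp * np.cos(w * grid + shift))
        return np.column_stack(cols)

    if deriv_order >= basis.order:
        raise BasisError(
            f"derivative order {deriv_order} >= spline order {basis.order}"
        )
    return _bspline_design(np.asarray(basis.knots), basis.order, grid, deriv_order)


def _bspline_design(
    knots: np.ndarray, order: int, grid: np.ndarray, deriv: int
) -> np.ndarray:
    """B-spline design matrix for an arbitrary derivative order.

    Differentiation uses the de Boor coefficient-differencing recurrence
    (spline order drops by one per pass, knot vector is trimmed by one at
    each end) so that interior knots of high multiplicity — where the
    derivative may genuinely jump — are handled exactly; zero-width knot
    spans contribute nothing.  Evaluation at a discontinuity returns the
    right-hand limit.
    """
    degree = order - 1
    n = len(knots) - order
    D = np.eye(n)
    for m in range(1, deriv + 1):
        tc = knots[m - 1 : len(knots) - (m - 1)] if m > 1 else knots
        dc = degree - (m - 1)
        n_c = n - (m - 1)
        Dm = np.zeros((n_c - 1, n_c))
        for j in range(n_c - 1):
            span = tc[j + 1 + dc] - tc[j + 1]
            if span > 0:
                Dm[j, j] = -dc / span
                Dm[j, j + 1] = dc / span
        D = Dm @ D
    t_eval = knots[deriv : len(knots) - deriv] if deriv else knots
    B = BSpline.design_matrix(grid, t_eval, degree - deriv).toarray()
    return B @ D


def penalty_matrix(
    basis: BasisSystem, penalty_order: int = 2, *, n_quad: int = 2001
) -> np.ndarray:
    """Roughness penalty matrix R with R[i, j] = ∫ D^m b_i(t) D^m b_j(t) dt.

    Computed by composite trapezoid quadrature on a fine uniform grid over the
    basis domain; symmetric positive semidefinite by construction.
    """
    if basis.kind == "bspline" and penalty_order >= basis.order:
        raise BasisError("penalty order must be below the spline order")
    lo, hi = basis.domain
    tq = np.linspace(lo, hi, n_quad)
    M = basis_matrix(basis, tq, penalty_order)
    w = np.full(n_quad, (hi - lo) / (n_quad - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    R = (M * w[:, None]).T @ M
    return 0.5 * (R + R.T)


@dataclass
class SmoothCurves:
    """Per-subject basis coefficients from a shared penalized fit."""

    basis: BasisSystem
    coefficients: np.ndarray  # (n_subjects, n_basis)
    lam: float
    penalty_order: int
    fit_grid: np.ndarray
    groups: np.ndarray
    subjects: list
    gcv: float | None = None


@dataclass
class CurveSet:
    """Functional observations evaluated on a common grid.

    ``values`` has one row per subject; ``groups`` carries the treatment
    label of each row.  ``derivative_order`` records which derivative of the
    smooth these values are (0 = the curve itself, 1 = acceleration of a
    speed curve, ...).  ``clipped`` marks whether negative values were zeroed.
    """

    grid: np.ndarray
    values: np.ndarray
    groups: np.ndarray
    derivative_order: int = 0
    clipped: bool = False
    subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != (len(self.groups), len(self.grid)):
            raise ValueError("values must be (n_subjects, n_grid)")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def group_labels(self) -> np.ndarray:
        """Unique labels in first-appearance order."""
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    def subset_groups(self, labels: Sequence) -> "CurveSet":
        mask = np.isin(self.groups, np.asarray(labels))
        return CurveSet(
            grid=self.grid,
            values=self.values[mask],
            groups=self.groups[mask],
            derivative_order=self.derivative_order,
            clipped=self.clipped,
            subjects=[s for s, m in zip(self.subjects, mask) if m] if self.subjects else [],
        )

    def restrict(self, start: float, end: float) -> "CurveSet":
        """Keep grid points with start <= t < end, plus t == end if on-grid."""
        mask = (self.grid >= start - 1e-9) & (self.grid < end - 1e-9)
        mask |= np.isclose(self.grid, end)
        if mask.sum() < 2:
            raise ValueError(f"region [{start}, {end}) covers fewer than 2 grid points")
        return CurveSet(
            grid=self.grid[mask],
            values=self.values[:, mask],
            groups=self.groups,
            derivative_order=self.derivative_order,
            clipped=self.clipped,
            subjects=self.subjects,
        )


def _design(table: RawSeriesTable | tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    if isinstance(table, RawSeriesTable):
        Y, labels, subjects = table.to_matrix()
        return table.grid, Y, labels, subjects
    grid, Y, labels = table
    return (
        np.asarray(grid, float),
        np.asarray(Y, float),
        np.asarray(labels),
        list(range(len(labels))),
    )


def fit_penalized(
    table: RawSeriesTable | tuple,
    basis: BasisSystem,
    lam: float = 0.0,
    *,
    penalty_order: int = 2,
) -> SmoothCurves:
    """Fit all subjects by penalized least squares with a shared basis.

    Minimizes, per subject, ``Σ_k (y(t_k) - fit(t_k))² + lam · c'Rc`` where R
    is the roughness penalty of order ``penalty_order``.  A single symmetric
    factorization is shared across subjects.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    grid, Y, labels, subjects = _design(table)
    B = basis_matrix(basis, grid, 0)
    T = len(grid)
    if lam == 0 and basis.n_basis > T:
        raise RankError(
            f"n_basis={basis.n_basis} exceeds {T} observation times with lambda=0; "
            "use a positive lambda"
        )
    A = B.T @ B
    if lam > 0:
        A = A + lam * penalty_matrix(basis, penalty_order)
    try:
        from scipy.linalg import cho_factor, cho_solve

        fac = cho_factor(A)
        C = cho_solve(fac, B.T @ Y.T)
    except np.linalg.LinAlgError as exc:
        raise RankError(
            "singular smoothing system; increase lambda or reduce n_basis"
        ) from exc
    return SmoothCurves(
        basis=basis,
        coefficients=C.T,
        lam=float(lam),
        penalty_order=penalty_order,
        fit_grid=grid,
        groups=labels,
        subjects=subjects,
    )


def _hat_quantities(B: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve for the smoother and return (B @ A^{-1} B', its trace)."""
    from scipy.linalg import cho_factor, cho_solve

    fac = cho_factor(A)
    X = cho_solve(fac, B.T)  # (n_basis, T)
    df = float(np.sum(B * X.T))
    return X, df


def select_lambda_gcv(
    table: RawSeriesTable | tuple,
    basis: BasisSystem,
    lambda_grid: np.ndarray | None = None,
    *,
    penalty_order: int = 2,
) -> tuple[float, dict]:
    """Choose the penalty weight by generalized cross validation.

    For each candidate lambda the GCV score is summed over subjects:
    ``Σ_j T · SSE_j(λ) / (T - df(λ))²`` with ``df`` the trace of the smoothing
    hat operator.  Returns the argmin and a trace dict
    ``{"lambda": [...], "gcv": [...], "df": [...]}``.
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, float)
    if np.any(~np.isfinite(lambda_grid)) or np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be positive and finite")
    grid, Y, _, _ = _design(table)
    T = len(grid)
    B = basis_matrix(basis, grid, 0)
    R = penalty_matrix(basis, penalty_order)
    BtB = B.T @ B
    BtY = B.T @ Y.T
    scores, dfs, lams = [], [], []
    for lam in lambda_grid:
        from scipy.linalg import cho_factor, cho_solve

        try:
            fac = cho_factor(BtB + lam * R)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular system at lambda={lam:g}; skipped")
            continue
        C = cho_solve(fac, BtY)
        X = cho_solve(fac, B.T)
        df = float(np.sum(B * X.T))
        if df >= T:
            warnings.warn(f"effective df {df:.1f} >= {T} at lambda={lam:g}; skipped")
            continue
        resid = Y.T - B @ C
        sse = np.sum(resid**2, axis=0)
        scores.append(float(np.sum(T * sse / (T - df) ** 2)))
        dfs.append(df)
        lams.append(float(lam))
    if not scores:
        raise RankError("GCV failed at every candidate lambda")
    best = int(np.argmin(scores))
    trace = {"lambda": lams, "gcv": scores, "df": dfs}
    return lams[best], trace


def smooth_series(
    table: RawSeriesTable | tuple,
    basis: BasisSystem,
    lam: float | Literal["gcv"] = 0.0,
    *,
    penalty_order: int = 2,
    lambda_grid: np.ndarray | None = None,
) -> SmoothCurves:
    """Fit curves, optionally selecting the penalty weight by GCV."""
    if lam == "gcv":
        lam_star, trace = select_lambda_gcv(
            table, basis, lambda_grid, penalty_order=penalty_order
        )
        fit = fit_penalized(table, basis, lam_star, penalty_order=penalty_order)
        fit.gcv = trace["gcv"][trace["lambda"].index(lam_star)]
        return fit
    return fit_penalized(table, basis, float(lam), penalty_order=penalty_order)


def evaluate_curves(
    smooth: SmoothCurves,
    grid: np.ndarray | None = None,
    deriv_order: int = 0,
    *,
    clip_negative: bool = False,
    grid_step: float = DEFAULT_GRID_STEP,
) -> CurveSet:
    """Evaluate the fitted curves (or a derivative) on a grid.

    Derivatives come from the basis coefficients analytically.  Negative
    values are clipped to zero only for the curve itself (``deriv_order=0``);
    signed derivatives are never clipped.
    """
    if grid is None:
        lo, hi = smooth.basis.domain
        n = int(round((hi - lo) / grid_step)) + 1
        grid = np.linspace(lo, hi, n)
    grid = np.asarray(grid, float)
    M = basis_matrix(smooth.basis, grid, deriv_order)
    values = smooth.coefficients @ M.T
    clipped = False
    if clip_negative and deriv_order == 0:
        clipped = bool(np.any(values < 0))
        values = np.clip(values, 0.0, None)
    return CurveSet(
        grid=grid,
        values=values,
        groups=smooth.groups,
        derivative_order=deriv_order,
        clipped=clipped,
        subjects=list(smooth.subjects),
    )
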