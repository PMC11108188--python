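"""Synthetic photolocomotor curve generator.

Each simulated fish swims with a sine-wave speed profile around a common
baseline of 70 distance/min, with subject-level random variation in the
amplitude, period and phase plus an iid Gaussian vertical offset:

    f_ij(t) = 70 + A_ij * sin(pi * t / R_ij + pi * P_ij) + W_ij(t),
    W ~ N(0, sigma^2 = 36)

where W is iid measurement noise drawn independently at every recorded
minute.  (That W is per-measurement, not a per-subject constant offset, is
pinned down by the scalar-ANOVA behavior of the design: collapsing each
curve to its 60-minute mean leaves a residual variance of roughly
36/60 ≈ 0.6, and the repeated-measures residual mean square is the sum of
the noise variance and the within-group sine-mode variance.  A constant
offset is available via ``noise_scope``.)

The default three-group design draws, per subject,

    group 1:  A ~ Unif(37, 43),  R ~ N(15, 0.025),  P ~ N(0, 0.0225)
    group 2:  A ~ Unif(17, 23),  R ~ N(15, 0.025),  P ~ N(1, 0.0225)
    group 3:  A ~ Unif(57, 63),  R ~ N(10, 0.025),  P ~ N(1, 0.0225)

(normal parameters are variances), evaluated at t = 1, ..., 60 minutes with
20 subjects per group.  The three group-mean profiles all average to the
same 70 over full sine periods, so collapsing each curve to its mean hides
the group structure entirely — the scenario in which scalar ANOVA fails and
the functional analysis does not.

The construction deliberately omits features of real assay data: no
light/dark structure, no startle transients, no negative-speed clipping and
no temporal measurement noise beyond the smooth sine (so smoothing is nearly
lossless here).

``simulate_null`` draws every group from one group's distributions, giving
an exact null for size calibration of the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_design import RawSeriesTable

__all__ = [
    "GroupSpec",
    "SimDesign",
    "simulate_pbr",
    "simulate_null",
    "mean_function",
    "population_mean_function",
]

BASELINE = 70.0


@dataclass(frozen=True)
class GroupSpec:
    """Subject-level variation of one treatment group.

    ``period_var`` and ``phase_var`` are variances, not standard deviations.
    """

    amplitude_lo: float
    amplitude_hi: float
    period_mean: float
    period_var: float
    phase_mean: float
    phase_var: float

    def __post_init__(self) -> None:
        if not self.amplitude_hi > self.amplitude_lo:
            raise ValueError("amplitude support must satisfy lo < hi")
        if self.period_mean <= 0:
            raise ValueError("mean period must be positive")


DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec(37, 43, 15, 0.025, 0, 0.0225),
    GroupSpec(17, 23, 15, 0.025, 1, 0.0225),
    GroupSpec(57, 63, 10, 0.025, 1, 0.0225),
)


@dataclass
class SimDesign:
    """Simulation design; the defaults reproduce the three-group sine study."""

    n_per_group: int = 20
    grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 61.0))
    baseline: float = BASELINE
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    noise_var: float = 36.0
    seed: int | None = None
    #: Where the Gaussian term W applies: fresh draw per measurement
    #: ("measurement", the default), one constant offset per subject
    #: ("subject"), or one per group ("group").
    noise_scope: str = "measurement"

    def __post_init__(self) -> None:
        if self.noise_var < 0:
            raise ValueError("noise variance must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_scope not in ("measurement", "subject", "group"):
            raise ValueError("noise_scope must be 'measurement', 'subject' or 'group'")
        self.grid = np.asarray(self.grid, float)


def _draw_curves(
    design: SimDesign, specs: tuple[GroupSpec, ...], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    t = design.grid
    sigma = float(np.sqrt(design.noise_var))
    for gi, spec in enumerate(specs, start=1):
        w_group = rng.normal(0.0, sigma) if design.noise_scope == "group" else None
        for j in range(1, design.n_per_group + 1):
            amp = rng.uniform(spec.amplitude_lo, spec.amplitude_hi)
            per = rng.normal(spec.period_mean, np.sqrt(spec.period_var))
            pha = rng.normal(spec.phase_mean, np.sqrt(spec.phase_var))
            if design.noise_scope == "measurement":
                w = rng.normal(0.0, sigma, size=len(t))
            elif design.noise_scope == "group":
                w = w_group
            else:
                w = rng.normal(0.0, sigma)
            values = design.baseline + amp * np.sin(np.pi * t / per + np.pi * pha) + w
            rows.append(
                pd.DataFrame(
                    {
                        "subject": f"g{gi}s{j:03d}",
                        "group": f"level{gi}",
                        "time": t,
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_pbr(design: SimDesign | None = None) -> RawSeriesTable:
    """Simulate a balanced multi-group photolocomotor curve dataset."""
    design = design or SimDesign()
    rng = np.random.default_rng(design.seed)
    return RawSeriesTable(_draw_curves(design, design.groups, rng))


def simulate_null(
    design: SimDesign | None = None, group_index_for_all: int = 1
) -> RawSeriesTable:
    """Simulate under the null: every group drawn from one group's law.

    Group labels are still assigned (arbitrarily), so the rejection rate of
    any test run on this output estimates its size.
    """
    design = design or SimDesign()
    spec = design.groups[group_index_for_all - 1]
    rng = np.random.default_rng(design.seed)
    return RawSeriesTable(_draw_curves(design, (spec,) * len(design.groups), rng))


def mean_function(group_index: int, t, design: SimDesign | None = None) -> np.ndarray:
    """The group's mean swim profile: baseline + A sin(pi t / R + pi P)
    at the distributions' mean amplitude/period/phase."""
    design = design or SimDesign()
    spec = design.groups[group_index - 1]
    t = np.asarray(t, float)
    amp = 0.5 * (spec.amplitude_lo + spec.amplitude_hi)
    return design.baseline + amp * np.sin(
        np.pi * t / spec.period_mean + np.pi * spec.phase_mean
    )


def population_mean_function(
    group_index: int, t, design: SimDesign | None = None, *, n_nodes: int = 41
) -> np.ndarray:
    """E[f_ij(t)]: the exact mean curve of the generator, by quadrature.

    Differs from :func:`mean_function` (the plug-in sine at the mean
    amplitude/period/phase) because sin is nonlinear in the random period and
    phase: their scatter attenuates the expected curve toward the baseline
    (for phase alone the factor is exp(-pi^2 Var(P)/2)).  Amplitude enters
    linearly, so only the period/phase expectation needs Gauss-Hermite
    quadrature.  This is the correct truth when checking coverage of
    estimated group-mean curves.
    """
    design = design or SimDesign()
    spec = design.groups[group_index - 1]
    t = np.asarray(t, float)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    r_vals = spec.period_mean + np.sqrt(spec.period_var) * nodes
    p_vals = spec.phase_mean + np.sqrt(spec.phase_var) * nodes
    amp = 0.5 * (spec.amplitude_lo + spec.amplitude_hi)
    acc = np.zeros_like(t)
    for wr, rv in zip(weights, r_vals):
        acc += wr * (
            weights
            @ np.sin(np.pi * t[None, :] / rv + np.pi * p_vals[:, None])
        )
    return design.baseline + amp * acc
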