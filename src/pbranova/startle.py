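"""Startle-response analysis via acceleration curves.

Fish change speed sharply for roughly three minutes after a lighting switch.
Because the speed curves are smooth basis expansions, their first derivative
— the acceleration — is available analytically, and the functional ANOVA
machinery applies to it unchanged.  This module derives the per-transition
startle windows from the experiment design and runs omnibus and vs-control
F_FT permutation tests of the acceleration curves inside them.

Acceleration is computed from the *unclipped* smooth: zeroing negative
speeds before differentiating would create artificial derivative spikes at
the clipping boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import PosthocReport, posthoc_fft
from .io_design import DesignError, ExperimentDesign, Region
from .smoothing import CurveSet, SmoothCurves, evaluate_curves

__all__ = ["StartleWindows", "acceleration_curves", "derive_windows", "startle_fanova"]

DEFAULT_WINDOW_MINUTES = 3.0


@dataclass
class StartleWindows:
    """Post-transition analysis windows, one per non-acclimation period."""

    transitions: list  # (time, direction) with direction in {to_light, to_dark}
    window_minutes: float
    regions: list  # Region per transition, [t, t + window)


def acceleration_curves(
    smooth: SmoothCurves, grid: np.ndarray | None = None
) -> CurveSet:
    """First-derivative (acceleration) curves of the fitted smooths.

    The result is signed; no negativity clipping is applied.
    """
    return evaluate_curves(smooth, grid=grid, deriv_order=1, clip_negative=False)


def derive_windows(
    design: ExperimentDesign, window_minutes: float = DEFAULT_WINDOW_MINUTES
) -> StartleWindows:
    """One startle window at the start of each analysis period.

    The window direction is the condition of the period being entered; the
    window may not extend past the end of its period.
    """
    if window_minutes <= 0:
        raise DesignError("window_minutes must be positive")
    shortest = min(p.end - p.start for p in design.periods)
    if window_minutes > shortest:
        raise DesignError(
            f"window of {window_minutes} min exceeds the shortest period ({shortest} min)"
        )
    transitions, regions = [], []
    counts = {"light": 0, "dark": 0}
    for p in design.periods:
        counts[p.condition] += 1
        direction = "to_light" if p.condition == "light" else "to_dark"
        name = f"{'L' if p.condition == 'light' else 'D'}{counts[p.condition]}"
        transitions.append((p.start, direction))
        regions.append(Region(name, p.start, p.start + window_minutes))
    return StartleWindows(
        transitions=transitions, window_minutes=window_minutes, regions=regions
    )


def startle_fanova(
    acceleration: CurveSet,
    windows: StartleWindows,
    *,
    full_region: Region | tuple[float, float] | None = None,
    mode: str = "vs_control",
    control: str | None = None,
    r: int = 10_000,
    tau: float = 0.05,
    seed: int | None = None,
    hierarchical: bool = True,
) -> PosthocReport:
    """Omnibus and per-window post hoc F_FT tests of the acceleration curves.

    The omnibus and full-domain contrast tests integrate over ``full_region``
    (default: from the first transition to the end of the last period's
    window coverage on the grid); the subregion family tests each surviving
    contrast inside every startle window at tau / (n_survivors * n_windows).
    """
    if acceleration.derivative_order != 1:
        raise ValueError("startle_fanova expects first-derivative curves")
    if full_region is None:
        start = windows.transitions[0][0]
        full_region = Region("full", start, float(acceleration.grid[-1]))
    return posthoc_fft(
        acceleration,
        full_region,
        subregions=windows.regions,
        mode=mode,
        control=control,
        r=r,
        tau=tau,
        seed=seed,
        hierarchical=hierarchical,
    )
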