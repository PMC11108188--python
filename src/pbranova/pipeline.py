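"""End-to-end workflow: simulate/load -> smooth -> FANOVA -> post hoc/startle.

One global seed is split deterministically into per-stage seeds (simulation,
omnibus permutation, post hoc permutations, bootstrap, startle) so any stage
can be re-run independently while the whole pipeline stays reproducible.
All outputs are CSV, accompanied by the resolved configuration as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_design, simulator, smoothing, startle as startle_mod
from .fanova import estimate_effects, permutation_test
from .inference import posthoc_fft
from .io_design import ExperimentDesign, RawSeriesTable, Region

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    input_path: str | None = None          # long CSV; None -> simulate
    design_path: str | None = None         # YAML design; None -> full data span
    simulate: bool = False
    null_simulation: bool = False
    n_per_group: int = 20
    basis: str = "fourier"                 # "fourier" or "bspline"
    n_basis: int = 11
    lam: str | float = 0.0                 # "gcv" or a number
    grid_step: float = smoothing.DEFAULT_GRID_STEP
    clip_negative: bool = False
    transitions: list = field(default_factory=list)
    permutations: int = 10_000
    bootstrap: int = 1000
    tau: float = 0.05
    seed: int = 0
    posthoc_mode: str | None = None        # None, "all_pairs", "vs_control"
    control: str | None = None
    run_startle: bool = False
    startle_window: float = 3.0
    out_dir: str = "pbranova_out"


def stage_seeds(seed: int) -> dict[str, int]:
    """Split one seed into independent per-stage seeds."""
    rng = np.random.default_rng(seed)
    names = ("simulate", "omnibus", "posthoc", "bootstrap", "startle")
    return {name: int(s) for name, s in zip(names, rng.integers(2**31, size=len(names)))}


def _load_or_simulate(cfg: RunConfig, seeds: dict) -> RawSeriesTable:
    if cfg.simulate or cfg.input_path is None:
        design = simulator.SimDesign(n_per_group=cfg.n_per_group, seed=seeds["simulate"])
        if cfg.null_simulation:
            return simulator.simulate_null(design)
        return simulator.simulate_pbr(design)
    return io_design.read_series(cfg.input_path)


def _smooth(cfg: RunConfig, table: RawSeriesTable) -> smoothing.SmoothCurves:
    grid = table.grid
    domain = (float(grid[0]), float(grid[-1]))
    if cfg.basis == "fourier":
        basis = smoothing.build_basis("fourier", domain, cfg.n_basis)
        return smoothing.smooth_series(table, basis, 0.0)
    basis = smoothing.saturated_bspline_basis(grid, transitions=cfg.transitions)
    lam = "gcv" if cfg.lam == "gcv" else float(cfg.lam)
    return smoothing.smooth_series(table, basis, lam)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured workflow and write result CSVs to ``cfg.out_dir``.

    Returns a dict of in-memory results: the omnibus permutation result,
    the effect fit, and any post hoc / startle reports.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)

    table = _load_or_simulate(cfg, seeds)
    design: ExperimentDesign | None = None
    if cfg.design_path:
        design = io_design.load_design(cfg.design_path)
        lo, hi = design.full_region.start, design.full_region.end
        mask = (table.data["time"] >= lo - 1e-9) & (table.data["time"] <= hi + 1e-9)
        table = RawSeriesTable(table.data[mask].reset_index(drop=True))
        if cfg.basis == "bspline" and not cfg.transitions:
            cfg.transitions = [p.start for p in design.periods[1:]]

    smooth = _smooth(cfg, table)
    curves = smoothing.evaluate_curves(
        smooth, grid_step=cfg.grid_step, clip_negative=cfg.clip_negative
    )
    fit = estimate_effects(curves)
    region = (
        (design.full_region.start, design.full_region.end)
        if design
        else (float(curves.grid[0]), float(curves.grid[-1]))
    )
    if cfg.permutations == 1:
        import warnings

        warnings.warn("r=1 permutation: the critical value is degenerate")
    omnibus = permutation_test(
        curves, region, r=cfg.permutations, tau=cfg.tau, seed=seeds["omnibus"],
        pointwise=False,
    )

    results: dict = {"table": table, "smooth": smooth, "curves": curves,
                     "fit": fit, "omnibus": omnibus, "seeds": seeds}

    pd.DataFrame(
        [{
            "statistic": omnibus.f_ft_obs,
            "critical": omnibus.critical,
            "p_value": omnibus.p_value,
            "r": omnibus.r,
            "tau": omnibus.tau,
            "decision": "Reject" if omnibus.p_value < cfg.tau else "FTR",
        }]
    ).to_csv(out / "omnibus.csv", index=False)
    eff = pd.DataFrame({"time": curves.grid, "mu_hat": fit.mu_hat, "f_obs": fit.f_curve})
    for g in fit.groups:
        eff[f"alpha_{g}"] = fit.alpha_hat[g]
    eff.to_csv(out / "effects.csv", index=False)

    if cfg.posthoc_mode:
        subregions = list(design.regions.values()) if design else []
        subregions = [reg for reg in subregions if reg is not (design.full_region if design else None)]
        full = design.full_region if design else Region("full", *region)
        report = posthoc_fft(
            curves, full,
            subregions=[reg for reg in subregions if reg.name != full.name],
            mode=cfg.posthoc_mode, control=cfg.control,
            r=cfg.permutations, tau=cfg.tau, seed=seeds["posthoc"],
        )
        report.to_frame().to_csv(out / "posthoc.csv", index=False)
        results["posthoc"] = report

    if cfg.run_startle:
        if design is None:
            raise ValueError("startle analysis requires a design file with periods")
        accel = startle_mod.acceleration_curves(smooth)
        accel = accel.restrict(design.full_region.start, design.full_region.end)
        windows = startle_mod.derive_windows(design, cfg.startle_window)
        report = startle_mod.startle_fanova(
            accel, windows,
            full_region=design.full_region,
            mode=cfg.posthoc_mode or "vs_control", control=cfg.control,
            r=cfg.permutations, tau=cfg.tau, seed=seeds["startle"],
        )
        report.to_frame().to_csv(out / "startle.csv", index=False)
        results["startle"] = report

    with open(out / "config.json", "w") as fh:
        json.dump({**asdict(cfg), "stage_seeds": seeds}, fh, indent=2)
    return results
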