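"""Startle-response analysis on a synthetic light/dark transition assay.

Real assays record speed under alternating lighting: fish slow abruptly when
the light turns on and burst when it turns off.  No public generative model
exists for that data, so this example builds a synthetic stand-in: square-
wave speed profiles (fast in dark, slow in light) with exponential startle
transients at each switch, dose-dependent attenuation, and Gaussian noise.

Curves are smoothed with a saturated cubic B-spline basis carrying triple
knots at the lighting transitions (value continuous, slope free to jump),
with the roughness penalty weight chosen by generalized cross validation.
The first derivative of the smooths — the acceleration — is then compared
across dose groups inside the three minutes after each transition.
"""

import numpy as np
import pandas as pd

from pbranova import (
    ExperimentDesign,
    Period,
    RawSeriesTable,
    acceleration_curves,
    derive_windows,
    saturated_bspline_basis,
    smooth_series,
    startle_fanova,
)

design = ExperimentDesign(
    domain=(0, 50),
    acclimation=(0, 10),
    periods=[Period(10, 20, "light"), Period(20, 30, "dark"),
             Period(30, 40, "light"), Period(40, 50, "dark")],
)
transitions = [p.start for p in design.periods]

rng = np.random.default_rng(11)
grid = np.arange(10.0, 51.0)  # minute stamps, acclimation excluded
doses = {"control": 1.0, "mid": 0.6, "high": 0.25}  # startle attenuation
rows = []
for group, strength in doses.items():
    for j in range(12):
        dark = np.isin(np.floor((grid - 10) / 10) % 2, [1])  # D1, D2 minutes
        base = np.where(dark, 45.0, 15.0)
        speed = base.astype(float)
        for t0 in transitions[1:]:  # transient at each switch
            dt = grid - t0
            mask = dt >= 0
            sign = 1.0 if (t0 - 10) // 10 % 2 == 0 else -1.0
            speed[mask] += sign * strength * 25 * np.exp(-dt[mask] / 1.2)
        speed += rng.normal(0, 3.0, len(grid))
        for t, v in zip(grid, speed):
            rows.append({"subject": f"{group}{j}", "group": group,
                         "time": t, "value": v})
table = RawSeriesTable(pd.DataFrame(rows))

basis = saturated_bspline_basis(table.grid, transitions=transitions[1:])
smooth = smooth_series(table, basis, "gcv")
print(f"GCV chose lambda = {smooth.lam:g}")

accel = acceleration_curves(smooth).restrict(10.0, 50.0)
windows = derive_windows(design, 3.0)
report = startle_fanova(
    accel, windows, full_region=design.full_region,
    mode="vs_control", control="control", r=1000, tau=0.05, seed=9,
)
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("The omnibus row tests all groups over the full window; subsequent")
print("rows compare each dose with the control over the whole domain and")
print("then within each 3-minute post-transition startle window, at")
print("Bonferroni-adjusted levels.  The high dose's blunted startle is")
print("detected in the windows; where 'FTR' appears the data cannot")
print("distinguish that dose's startle from the control's.")
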