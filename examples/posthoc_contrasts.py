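"""Post hoc contrasts and bootstrap confidence bands after an omnibus rejection.

After the omnibus functional ANOVA rejects, pairwise effect-difference
curves alpha_i(t) - alpha_j(t) are tested with Bonferroni-adjusted F_FT
permutation tests, and pointwise residual-bootstrap bands visualize each
effect's uncertainty.
"""

import numpy as np

from pbranova import (
    SimDesign,
    bootstrap_bands,
    build_basis,
    estimate_effects,
    evaluate_curves,
    posthoc_fft,
    simulate_pbr,
    smooth_series,
)

table = simulate_pbr(SimDesign(seed=42))
basis = build_basis("fourier", (1.0, 60.0), 10)
curves = evaluate_curves(smooth_series(table, basis))
fit = estimate_effects(curves)

# all three pairwise contrasts, each tested at tau/3 = 0.0167
report = posthoc_fft(curves, (1.0, 60.0), mode="all_pairs", r=1000, seed=3)
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()

bands = bootstrap_bands(
    curves, fit, [f"effect:level{g}" for g in (1, 2, 3)], b=1000, level=0.95, seed=5
)
for band in bands:
    width = np.mean(band.upper - band.lower)
    peak = np.max(np.abs(band.estimate))
    print(f"{band.target}: peak |effect| = {peak:6.2f}, "
          f"mean 95% band width = {width:5.2f}")
print()
print("Every pairwise contrast is rejected at the Bonferroni-adjusted level:")
print("each group's swim pattern differs from both others somewhere in the")
print("hour.  The ~10-unit band widths show the effect curves are estimated")
print("much more precisely than the ~40-unit peak effect sizes.")
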