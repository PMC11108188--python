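# Methods

## Model and test

Each subject's locomotor record is treated as a function over a closed time
interval T (minutes). The balanced one-way functional ANOVA model is

    y_ij(t) = μ(t) + α_i(t) + ε_ij(t),  i = 1..a groups, j = 1..n subjects,

with Σ_i α_i(t) = 0. Effects are estimated by the group and grand mean
curves; the pointwise hypothesis and error sums of squares SSA(t) and
SSE(t) carry q_A = a−1 and q_E = a(n−1) degrees of freedom, and the scalar
statistic integrates numerator and denominator separately before taking
the ratio:

    F_FT = [∫_T SSA dt / q_A] / [∫_T SSE dt / q_E].

Integration is composite trapezoid on the evaluation grid. A region
restriction keeps grid points with start ≤ t < end plus the right endpoint
when it lies on the grid, so adjacent regions share their boundary
ordinate and subregion integrals add exactly to the full-window integral.

The null distribution of F_FT is approximated by permuting whole-curve
group labels uniformly at random with group sizes preserved (default
r = 10,000 draws from a seeded generator; exhaustive enumeration is used
only as a test oracle on tiny inputs). The critical value is the
100(1−τ)th percentile of the permuted statistics using the
linear-interpolation quantile convention, and the p-value is the strict
exceedance proportion #{F_FT^r > F_FT^obs}/r with no add-one correction —
so a p-value of exactly 0 is possible and simply means no permutation
reached the observed value. When all permuted statistics coincide (e.g.
identical curves) the result is flagged degenerate. The only modeling
assumption is independence across subjects; in a calibration run under the
null generator (400 repetitions, 200 permutations each) the rejection rate
at τ = 0.05 stays inside the exact binomial 99% interval around 0.05.

Grid points where SSE(t) = 0 exactly (possible only through zero-clipping
artifacts) are excluded from the integrals with a warning; they are
measure-zero and would otherwise contribute infinities.

## Smoothing

Two basis systems are supported, behind one fitting interface:

* **Fourier** (constant + sine/cosine pairs) for periodic data without
  sharp local features. A requested even size is rounded up to the next
  odd count so the basis always holds whole harmonic pairs; the period
  defaults to the domain width. Fourier fits are unpenalized ordinary
  least squares.
* **Cubic B-splines** (order 4) for data with no global structure,
  typically *saturated* — one knot per observation time — and regularized
  by a roughness penalty λ·∫(D²f)² dt with λ chosen by generalized cross
  validation. Lighting-transition times can carry extra knot multiplicity;
  the default multiplicity is order − 1, which keeps the fitted speed
  continuous while letting its first derivative jump, the behavior a
  startle transient demands. Uniformly placed interior knots are spread
  within the segments between transitions so they can never silently
  inflate a transition's multiplicity.

The GCV score at each candidate λ is Σ_j T·SSE_j(λ)/(T − df(λ))², with
df(λ) the trace of the smoothing hat operator shared by all subjects;
candidates where df ≥ T are skipped with a warning. The default search
grid is 25 log-spaced values in [1e−4, 1e4]. The penalty matrix is
computed by composite trapezoid quadrature of the basis derivatives on a
2001-point grid — deterministic and consistent with the integration rule
used everywhere else.

Fitted curves and their derivatives are evaluated analytically from the
basis coefficients (B-spline derivatives via the de Boor
coefficient-differencing recurrence, which is exact across repeated
knots), never by finite differences. The default evaluation grid is
evenly spaced at 0.1 min, fine enough to resolve a 3-minute startle
window with 30 points. Negative fitted speeds can be clipped to zero at
evaluation time; clipping applies only to the curve itself, is recorded
in a flag, and acceleration is always computed from the unclipped smooth
because clipping would create artificial derivative spikes at the
clipping boundary.

## Bootstrap bands

Residual curves ν̂_ij(t) = y_ij(t) − μ̂(t) − α̂_i(t) are resampled with
replacement from the pooled set of all a·n of them (a within-group option
exists but pooling is the default) and reattached to the fitted effects,
y*_ij = ν̂* + μ̂ + α̂_i. Effects are re-estimated per replicate (default
b = 1000) and the pointwise (1±level)/2 percentiles of the
bootstrap-minus-observed difference curves, added to the observed
estimate, form the band. The reflected ("basic bootstrap") orientation is
available behind a flag; with the near-symmetric difference distributions
produced by pooled resampling the two orientations differ negligibly.
Bands are pointwise, not simultaneous: they are interpretable at each t
separately. On simulated data the 95% effect bands achieve ~0.90 average
pointwise coverage of the true (population) effect curves.

## Post hoc testing

After an omnibus rejection, pairwise contrasts α̂_i − α̂_i′ (all pairs, or
each group against a named control) are tested by restricting the curve
set to the two groups involved and rerunning the permutation test, first
over the full analysis window at the Bonferroni level τ/(number of
contrasts). Contrasts failing the full-window test are dropped
(hierarchical flow, the default), and survivors are retested inside each
lighting-period subregion at τ/(survivors × subregions). Each test's
critical value comes from its own permutation distribution at its own
adjusted level. A contrast is rejected when its p-value falls below its
adjusted level, which by construction agrees with the
observed-versus-critical comparison.

## Startle analysis

The startle response — the rapid speed change after a lighting switch —
is quantified by the first derivative (acceleration) of the smoothed
speed curves. One analysis window of configurable length (default 3 min,
reflecting how long fish visibly accelerate after a switch) opens at the
start of every non-acclimation period; windows may not extend past their
period. The full post hoc machinery then runs on the acceleration curves:
an omnibus test over the whole analysis window and vs-control tests
inside each startle window at τ/(contrasts × windows).

## Synthetic data generator

The simulator emulates a three-group design in which scalar ANOVA is
maximally misleading: every group's mean curve averages exactly the same
baseline speed (70 distance/min) over full sine periods while the shapes
differ strongly. Each subject's curve is

    f_ij(t) = 70 + A_ij sin(π t / R_ij + π P_ij) + W_ij(t),  t = 1..60,

with per-subject amplitude A ~ Unif(37,43)/Unif(17,23)/Unif(57,63),
period R ~ N(15, 0.025)/N(15, 0.025)/N(10, 0.025) and phase
P ~ N(0, 0.0225)/N(1, 0.0225)/N(1, 0.0225) for groups 1/2/3 (normal
parameters are variances), 20 subjects per group. W is iid N(0, σ² = 36)
measurement noise drawn at every recorded minute: this scope is what
makes the design's scalar reduction blind — collapsing a curve to its
60-minute mean averages the noise down to variance ≈ 36/60 ≈ 0.6 while
the sine structure cancels, so group means are indistinguishable — and
simultaneously leaves a repeated-measures residual mean square of
σ²_noise plus the within-group sine-mode variance (~250), the regime in
which the repeated-measures F tests are dominated by unmodeled temporal
structure. Constant per-subject and per-group offset variants are
available via `noise_scope`.

Two mean-curve helpers are provided: the plug-in sine at the mean
amplitude/period/phase, and the exact population mean E[f_ij(t)] computed
by Gauss–Hermite quadrature over the random period and phase. They differ
because sin is nonlinear in those draws — phase scatter alone shrinks the
expected amplitude by exp(−π²·Var(P)/2) ≈ 0.895 — and the population
curve is the correct truth when checking coverage of estimated group
means. The plug-in curves average exactly 70 over [0, 60] (whole sine
periods); the sampled grid t = 1..60 leaves a negligible partial-period
remainder.

A null variant draws every group from one group's distributions,
providing an exact null for size calibration. All generation is
deterministic under a seed.

What the generator does *not* emulate: light/dark square-wave structure,
startle transients, non-negativity of speeds, heavy-tailed bursts, or
temporal autocorrelation in the noise. Passing tests on this generator
therefore validate the inferential machinery (size, power, coverage,
reproducibility), not robustness to those real-data features; the startle
example builds a separate synthetic square-wave-with-transients stand-in
for that pathway.

## Classical baselines

One-way ANOVA on per-subject scalars and balanced split-plot
repeated-measures ANOVA (time as the within-subject factor) are
implemented directly from their sums-of-squares decompositions, with F_A
tested against the between-subject mean square and F_T, F_AT against the
residual. p-values use the F reference distribution; no sphericity
correction is applied — the comparison's point is precisely that these
tests' assumptions fail on curve data. The univariate baseline doubles as
the per-grid-point oracle for F(t) in the test suite, and the
repeated-measures implementation is cross-checked against a frozen
R `aov` split-plot fit.

## Numerical conventions and edge cases

* Intervals are half-open [start, end); minute stamps are treated as
  interval-start times.
* Balanced designs are enforced at load; unbalanced input is rejected
  rather than reweighted.
* λ = 0 with more basis functions than observations raises a rank error
  directing the user to a positive λ.
* Quantiles (critical values, band percentiles) use linear interpolation
  between order statistics throughout.
* Seeds: every stochastic stage takes an explicit seed; the pipeline
  splits one global seed into independent per-stage seeds so stages can
  be re-run in isolation.

## Problem sizes used by the test suite

The simulation-study checks run 10 replicate studies at r = 10,000
permutations; size calibration uses 400 null repetitions at r = 200;
bootstrap coverage uses 200 repetitions at b = 200 on the minute grid.
These sizes keep Monte Carlo error well below the tolerances asserted
while the full suite completes in a few minutes on one CPU.

## Known limitations

* One-way balanced designs only; no two-way or mixed-effects extension.
* Bands are pointwise; no simultaneous band or functional outlier
  handling.
* The global statistic is the integrated-F form only (no L²-norm, F-max,
  or globalizing-F alternatives).
* Permutation and bootstrap loops are plain NumPy; very large designs
  (thousands of curves) would benefit from batching not implemented here.
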