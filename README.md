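# pbranova

Nonparametric functional ANOVA for photolocomotor behavioral response (PBR)
assays — the zebrafish "light/dark transition test" used throughout
toxicology and pharmacology to compare swim behavior across treatment
groups.

## The problem

A PBR assay records each fish's swim speed once a minute while the lighting
alternates between light and dark periods. The common practice of averaging
each fish's curve to a single number and running one-way ANOVA discards the
temporal structure: curves with wildly different shapes can share the same
mean, and the within-fish dependence invalidates the error model.
Repeated-measures ANOVA keeps the time structure but leans on normality and
sphericity assumptions that speed data violate, and localizing a significant
group × time interaction requires one post hoc test per minute.

`pbranova` instead treats each fish's record as a smooth function
y<sub>ij</sub>(t) and fits the one-way functional ANOVA model

    y_ij(t) = μ(t) + α_i(t) + ε_ij(t),    i = 1..a groups, j = 1..n fish

The pointwise sums of squares give a functional F statistic,

    SSA(t) = n Σ_i α̂_i(t)²,   SSE(t) = Σ_ij (y_ij(t) − ȳ_i(t))²,
    F(t)   = [SSA(t)/q_A] / [SSE(t)/q_E],     q_A = a−1,  q_E = a(n−1)

and integrating numerator and denominator over the domain (or any
subregion) yields the scalar test statistic

    F_FT = [∫ SSA(t) dt / q_A] / [∫ SSE(t) dt / q_E].

Its null distribution is calibrated by permuting whole-curve group labels,
so the only assumption is that fish are independent. Pointwise confidence
bands for effects and contrasts come from a residual bootstrap, post hoc
contrast and subregion tests use Bonferroni correction, and — because the
curves are smooth — the first derivative gives acceleration curves that
quantify the startle response after each lighting switch.

## Worked example

`examples/simulation_study.py` simulates three groups of 20 fish whose
sine-wave speed profiles all average 70 distance/min over the hour but
differ in amplitude, period and phase, smooths them with an 11-function
Fourier basis, and runs the permutation test:

```
simulated 60 fish x 60 minutes
F_FT observed  =   81.483
F_FT critical  =    2.218   (95th pct of 2000 permutations)
p-value        =   0.0000
```

The observed statistic dwarfs the permutation critical value: the groups'
mean curves differ decisively, even though scalar ANOVA on the same data
(`examples/scalar_anova_comparison.py`) returns p = 0.43. The other
examples show post hoc contrasts with bootstrap bands
(`posthoc_contrasts.py`) and the acceleration-based startle analysis with
transition-knot B-spline smoothing (`startle_analysis.py`).

A thin CLI wraps the same stages:

```
pbranova simulate --n 20 --seed 1 --out curves.csv
pbranova run --simulate --basis fourier --permutations 10000 --seed 1 --out-dir out/
pbranova startle --input speed.csv --design design.yaml --control 0 --out startle.csv
```

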