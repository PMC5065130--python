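# enzevo

Quantitative analysis of functional trade-offs in enzyme evolution.

When an enzyme is evolved toward a new (initially promiscuous) activity, how
much of its original, native activity does it lose along the way? Directed
evolution campaigns usually select *only* for the new activity, and the
trajectories they produce typically show **weak trade-offs**: large early
gains in the new function at little initial cost to the old one. `enzevo`
provides the statistical machinery to measure this from replicate activity
assays, and a generative simulator to test *why* weak trade-offs arise —
in particular, whether selection asymmetry alone (strong selection for the
new function, none on the old) is sufficient, without any intrinsic
mutational robustness of the native activity.

The package is aimed at analysts of directed-evolution and mutational-scan
datasets: tidy per-replicate activity tables go in, per-mutation effect
estimates, epistasis categories, DFE summaries, and trade-off curves come
out.

## The statistics at the core

**Relative effects.** A mutation's effect on one activity in background *b*
is the fold-change `f = A(variant) / A(parent)` of OD600-normalized initial
rates, aggregated across paired measurement batches as the geometric mean of
per-batch ratios, with uncertainty from the batch-to-batch dispersion of
`log10 f`. A variant below the assay's detection limit yields an upper bound
(`f <= limit / A(parent)`) rather than a point estimate, and bounds propagate
through all downstream products.

**Classification.** With neutrality band `c = 1.3` and `alpha = 0.05`:
deleterious iff `f < 1/c` **and** `p < alpha`; favorable iff `f > c` **and**
`p < alpha`; otherwise neutral (untested when no p-value exists). The
p-value is a two-sided Student t-test on `log10` activities.

**Additive null model.** If mutational effects combine additively on the log
scale, a set of mutations with fold-changes `f_1 … f_n` changes activity by

```
E = prod(f_i) = 10^(sum log10 f_i) = geomean(f)^n
```

Comparing `E` with the observed end-to-start change of a trajectory
quantifies aggregate epistasis: observed ≫ expected means antagonistic
epistasis buffered the losses.

**Epistasis categories.** The same mutation measured in two backgrounds is
classified as no epistasis / magnitude (antagonistic or synergistic) / sign
epistasis / neutral shift, gated by a between-background t-test on per-batch
log-ratios.

**DFE.** Random-library fold-changes are binned into strongly deleterious
(`f < 1/2`), weakly deleterious, neutral, and positive (`f > 1.3`), with
Wilson 95% CIs on frequencies; paired per-variant differences between the
two activities are tested by an exact Wilcoxon signed-rank test and a
two-sample Kolmogorov–Smirnov test on the log-fold distributions.

**Trade-off curve.** A trajectory maps to the unit square: x = cumulative
fraction of the total `log10` gain in the new activity, y = fraction of the
old activity's total `log10` loss not yet incurred. The **weakness index**
is the area under this curve: > 0.5 concave/weak, < 0.5 convex/strong.

**Simulator.** Per-mutation true effects on the two activities are bivariate
normal on the log10 scale with correlation `rho`; phenotypes are
log-additive plus optional sparse pairwise interaction terms; measurements
are log-normal with configurable CV. An adaptive walk screens 50 candidates
per round from a finite pool of 59 and accepts the best *measured* new
activity (greedy) or a uniform choice (random control).

## Worked example

Simulate a directed-evolution campaign in which effects on the two
activities are strongly anticorrelated (`rho = -0.9`, so every gain in the
new activity costs native activity), then analyze it:

```
$ enzevo simulate --out sim --seed 42 --rho -0.9
wrote simulated walk (10 rounds) to sim

$ enzevo effects --activity sim/activity.tsv --background occurrence \
    --trajectory sim/trajectory.tsv --out effects
wrote 20 effects to effects

$ enzevo trajectory --activity sim/activity.tsv \
    --trajectory sim/trajectory.tsv --out traj
weakness index 0.503 (weak); wrote curve to traj
```

`effects/summary.tsv` (abridged):

| background | substrate | del | neu | fav | geometric_mean | expected_total |
|------------|-----------|----:|----:|----:|---------------:|---------------:|
| occurrence | native    |  10 |   0 |   0 | 0.162          | 1.24e-08       |
| occurrence | new       |   0 |   0 |  10 | 2.94           | 4.76e+04       |

Reading it: each of the 10 accepted mutations was individually deleterious
for the native activity (geometric-mean fold 0.162 per mutation) and
favorable for the new one (2.94-fold per mutation). Under the additive null
model the 10 mutations combine to a 1.2×10⁻⁸-fold collapse of the native
activity and a 4.8×10⁴-fold gain of the new one — and because this simulated
landscape *is* additive, the chained trajectory
(`traj/trajectory_activities.tsv`) ends at exactly those relative
activities. The weakness index of 0.503 says the losses tracked the gains
almost proportionally, as expected when effects are tightly anticorrelated;
re-running with the default `rho = 0` gives concave trajectories
(weakness ≈ 0.56 on average) — weak trade-offs from selection asymmetry
alone.

The same `effects`, `epistasis`, `dfe`, and `trajectory` subcommands run on
measured data: a UTF-8 TSV with columns `dataset, variant_id, parent_id,
genotype, substrate, batch, replicate, rate, od600, detection_limit, censor`
(one row per replicate; `NA` for absent numerics; genotypes as
semicolon-joined tokens like `A80V;K185R`), plus a `round, variant_id,
parent_id` TSV for trajectories. `enzevo report --dir OUT` collates stage
outputs into one markdown report.

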