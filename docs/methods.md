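# Methods

This note documents the statistical model behind `enzevo`, the choices made
where the design was genuinely open, and what the simulator does and does not
emulate.

## Measurement model

One observation is an initial rate for (variant, substrate, batch,
replicate), optionally with an OD600 cell-density reading and a detection
limit. Normalized activity is `rate / od600`; a missing OD600 means the rate
is treated as already normalized (logged once per table). Replicate noise is
treated as multiplicative, so all inference happens on `log10` activities.

Censoring is a flag plus bound, never a sentinel value. A below-censored
record contributes an *upper bound* on activity; any variant with censored
replicates yields an `at_most` bound on its fold-change rather than a point
estimate, and such bounds turn downstream products into bounds. Censored
effects never enter means, medians, or confidence intervals; they are counted
separately (`n_in_product` records how many values actually entered each
product).

## Relative effects

The batch key pairs a variant's replicates with its parent's replicates from
the same growth/expression/assay set. Per shared batch we take the ratio of
mean normalized activities; the fold-change is the geometric mean of batch
ratios (an arithmetic-mean alternative is exposed via `batch_agg`), and
`se_log10` is the standard error of the batch `log10` ratios. Whether
variant and parent assays are actually paired within batches varies between
laboratories; when no batch key is shared the comparison falls back to the
unpaired ratio of grand means and is flagged (`paired = False`).

Significance is a two-sided **Student** (equal-variance) two-sample t-test on
`log10` normalized activities. The log scale matches the multiplicative
error model; equal variance is the conventional reading of "Student t-test"
in this assay literature. Welch and raw-scale variants are configuration
switches (`t_test`, `log_scale`), as is Benjamini–Hochberg correction
(`multiple_testing`), which is off by default — per-mutation calls in this
field are conventionally reported uncorrected, and the AND-rule below already
makes the call conservative.

A parent with no measurable activity admits no finite ratio; the effect is
flagged untested rather than guessed.

## Effect classes and summaries

With neutrality band `neutral_fold = 1.3` and `alpha = 0.05`, a call of
deleterious/favorable requires the mean fold beyond the band *and*
`p < alpha`; a beyond-band fold without a p-value (fewer than two replicates
per side) is untested. The band is symmetric on the log scale
(`> 1.3` and `< 1/1.3`). The joint requirement means the realized
false-call rate for true neutrals sits well below alpha — the acceptance
suite measures it directly.

Per background × substrate summaries report class counts, the geometric mean
with a t-interval on the mean `log10` effect back-transformed to folds, the
median fold, and the additive null model's expected total
`E = 10^(Σ log10 f) = geomean^n`. The identity with `geomean^n` is exact by
construction and asserted to 1e-9 relative in tests. The expected total in a
summary is computed over uncensored effects only, so the identity holds; the
standalone `expected_total_change` additionally folds censored bounds into a
bounded product for trajectory-level statements ("at most X when combined").

A useful deterministic self-check, used in the acceptance suite: when a
geometric mean is printed rounded to two decimals alongside its n = 26
null-model total, the printed total must lie inside
`[(g − 0.005)^26, (g + 0.005)^26]`. Three of the four unambiguous published
summary pairs we encode pass with wide margin, the fourth narrowly; a fifth
pair from the same table is inconsistent with any rounding at n ∈ {25, 26}
(it implies additional, unenumerated exclusions) and is therefore not
asserted — `n_in_product` exists precisely so users can see what entered a
product.

## Epistasis

Epistasis here means background dependence of a *single* mutation's effect —
the quantity measurable from trajectory data — not the simulator's pairwise
interaction coefficients (those are the generative counterpart). Categories
are assigned by a decision table on the two effect classes and
`delta = log10 f_b − log10 f_a`: same direction and milder in B →
magnitude-antagonistic; stronger → magnitude-synergistic; direction flip →
sign epistasis; one side neutral → neutral shift. When both effects retain
at least two per-batch log-ratios, a two-sample t-test on them gates every
call (`p_diff ≥ alpha` → no epistasis); without a p-value, magnitude calls
require `|delta| > log10(1.3)`, reusing the neutrality band. Censored-vs-
point comparisons resolve only when the bound itself orders the effects
(e.g. "at most 1e-4" vs a measured 0.125 is antagonistic in B); anything the
bound cannot order is indeterminate. The classifier is antisymmetric under
background swap, and transition-table marginals conserve the per-background
class counts exactly — both property-tested against a brute-force decision
table.

## DFE of a random library

Library variants are compared to the single common reference (not chained
parents). Bins: strongly deleterious `f < 1/strong_fold` (default 2),
weakly deleterious up to `1/neutral_fold`, neutral within the band
(boundaries inclusive), positive above. Binomial CIs use the Wilson score
interval (good coverage at the frequencies these libraries produce;
Clopper–Pearson via `binomial_ci="clopper-pearson"`). Below-censored
variants whose bound proves `f < 1/strong_fold` are counted strongly
deleterious; others are reported separately as indeterminate rather than
forced into a bin.

The paired comparison of the two activities is a Wilcoxon signed-rank test on
per-variant `log10` differences: zeros dropped, average ranks for ties, exact
p-values for n ≤ 25 via a dynamic program over the signed-rank distribution
(so ties are handled exactly under the average-rank convention), normal
approximation with continuity correction above. The distribution-level
comparison is a two-sample Kolmogorov–Smirnov test on `log10` folds with
exact small-sample p-values. A one-sample KS variant against a symmetric
null was considered and rejected: it requires a reference distribution the
data do not define, and the paired design is already covered by the
signed-rank test. Reports name the exact variant run. The conditional DFE
(native-activity bins within one promiscuous-activity bin) partitions the
unconditional DFE exactly.

## Trade-off curve and weakness index

For a trajectory with per-round activities relative to round 0, let `G_i` be
the cumulative `log10` gain of the new activity and `L_i` the cumulative
`log10` loss of the old. The curve is `x_i = G_i / G_n`,
`y_i = 1 − L_i / L_n`, and the weakness index is the trapezoid area under
it: 0.5 is proportional, above is weak/concave, below strong/convex. Log
base 10 throughout, matching order-of-magnitude narration of trajectories.

Real and simulated walks transiently *gain* old activity or dip in new
activity; the normalized curve uses each axis's running envelope
(`max.accumulate`) so x and 1−y are nondecreasing and the area stays in
[0, 1]; raw normalized values are retained alongside. The index is an
artifact-defined scalar — published trajectory figures describe weak/strong
only qualitatively — chosen as the simplest bounded monotone summary that
maps concavity to > 0.5. `trajectory_weakness` assigns the limits to
degenerate walks (1.0 when the old activity never net-declines, 0.0 when
nothing was gained while the old function decayed), so replicate studies do
not silently drop exactly the weakest trade-offs.

The generalist window (rounds where both activities are within
`retention_fold` = 10 of their maxima) is a descriptive plumbing threshold,
not a measured constant.

## Simulator

`simgen` generates the full study: per-mutation true `log10` effects on the
two activities from a bivariate normal (means `mu_old = mu_new = −0.2`,
spreads `sigma = 0.5`, correlation `rho`, default 0), log-additive genotypes
with optional sparse pairwise interaction terms (`epistasis_density`,
`epistasis_sigma`, default off), log-normal measurement noise with
`noise_cv = 0.15` in 3 batches × 2 replicates, and optional below-detection
censoring. The bivariate normal is the minimal family exposing the
correlation knob the selection-bias argument hinges on; no distributional
form is implied by data.

The adaptive walk screens `m_per_round = 50` candidates per round for 10
rounds from a **finite pool** of `n_candidate_pool = 59` mutations —
`m + rounds − 1`, i.e. the pool is sized to the campaign, every accessible
mutation is screened at least once over its course, and rejected candidates
return to the pool. This finiteness is the mechanism, not a convenience: the
greedy regime consumes the best available mutations first, so per-round gains
in the new activity decline over rounds (as real campaigns saturate), which
front-loads x and makes trajectories concave. With an effectively unlimited
pool, per-round gains are i.i.d., trajectories hover around the diagonal, and
no systematic weak trade-off emerges — we verified this numerically while
fixing the default. Greedy selection acts on *measured* new activity (one
noisy screening assay per candidate; ties break to the lowest mutation index
for determinism); the random-accept control picks uniformly. All randomness
derives from one integer seed through independent sub-streams (effect draws,
candidate draws, screening noise, random-regime acceptance, measurement), so
greedy and random regimes see identical candidate sequences for the same
seed, and `m_per_round = 1` makes the two regimes' trajectories coincide
exactly.

The simulation study behind the selection-bias claim uses 600 replicate
walks per condition: with `rho = 0`, greedy walks have mean weakness index
≈ 0.57 (> 0.5, concave), strictly above the ≈ 0.55 obtained at
`rho = −0.9`; greedy and random regimes are statistically indistinguishable
in mean per-round `log10` change of the old activity (the old function is a
selection-blind random walk) while greedy gains ≈ 7 more logs of the new
activity. Study sizes (500-variant libraries, 600 walks) were chosen so the
Monte-Carlo error is small relative to the effects being asserted.

What the generator does **not** emulate: codon-level mutation structure and
mutational biases, expression/stability as a latent variable (OD
normalization is assumed sufficient, and expression fluctuations are assumed
to affect both activities equally), population genetics (drift, clonal
interference), higher-order epistasis, and batch effects beyond independent
log-normal noise. Passing tests therefore show the *statistical pipeline* is
correct and calibrated under a realistic noise model — not that any
particular laboratory dataset satisfies additivity or log-normality.

## Numerical choices and degenerate inputs

- Exact zero-variance replicate sets short-circuit the t-test (p = 1 for
  identical means, 0 otherwise) to avoid catastrophic cancellation in
  noise-free simulations.
- Uncensored zero-activity batches give fold 0 and an untested class rather
  than −inf propagation.
- Geometric means and products are computed in log space; the
  `geomean^n = product` identity holds to ~1e-14 relative.
- Below-censored replicates mixed with measured ones conservatively enter at
  their detection limit, making the result an upper bound.
- The trajectory assembler validates the parent chain (strictly increasing
  rounds, each parent is the previous round's variant, no revisits) and
  refuses censored or zero folds rather than inventing activities.
- Exact Wilcoxon p-values use doubled average ranks (always integral) in a
  subset-sum dynamic program, so tied |differences| need no approximation.

## Limitations

- The t-interval on three batches (2 degrees of freedom) is wide; coverage is
  calibrated (measured ≈ 0.94–0.96) but power per mutation is limited, which
  is faithful to triplicate assay designs.
- The weakness index summarizes curve shape only; two very different
  trajectories can share an index.
- Epistasis categories depend on the classification of each side; mutations
  near the neutrality band can flip category under resampling. The
  significance gate exists to damp exactly this.
- The CLI emits TSV/JSON/markdown only; no plotting is bundled, since every
  figure is regenerable from the curve and effect tables.
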