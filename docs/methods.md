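# Methods

`flockgrowth` analyzes weekly performance records of commercial broiler
flocks: it partitions flocks into feed-efficiency groups, fits non-linear
growth curves to body-weight series, derives inflection-point traits, and
compares groups statistically. Because commercial integration data are
proprietary, the package ships a synthetic generator that reproduces the
statistical structure such records exhibit; every analysis stage is
exercised against it.

## Growth models and derived traits

Body weight `y` (g) at age `t` (d) is described by three three-parameter
sigmoids:

| model | equation | parameters |
|---|---|---|
| logistic | `y = W_A / (1 + exp(-K (t - t_i)))` | asymptote `W_A` (g), growth rate `K` (1/d), inflection age `t_i` (d) |
| Gompertz–Laird | `y = W_0 exp((L/K)(1 - exp(-K t)))` | hatch weight `W_0` (g), initial growth rate `L` (1/d), decay rate `K` (1/d) |
| von Bertalanffy | `y = W_A (1 - B exp(-K t))^3` | asymptote `W_A` (g), integration constant `B`, rate `K` (1/d) |

Closed-form inflection traits: logistic `W_i = W_A/2` and maximum daily
increment `MI = K W_i / 2`; von Bertalanffy `t_i = ln(3B)/K` (defined only
for `3B > 1`) and `W_i = W_A · 8/27`; Gompertz–Laird `t_i = ln(L/K)/K`
(natural log; defined only for `L > K`), `W_A = W_0 exp(L/K)` and
`W_i = W_A/e`. The natural-log reading of the Gompertz–Laird inflection
age is forced by consistency: with typical commercial estimates
(`K ≈ 0.038`, `L ≈ 0.188`) it places `t_i` in the low 40s of days, where
the fitted curves actually peak in daily gain, whereas a base-10 reading
would put it near 18 d, far from the gain maximum.

`MI` is reported for the logistic model only, following the convention of
broiler growth studies; the peak gain of the other two models is available
through the analytic derivative (`predict_gain`) instead. Reported
gram/day values round half away from zero (so `3655/2` prints as 1828 and
`2657/2` as 1329).

Crossover ages between two parameter sets (where predicted BW or daily
gain of one group overtakes the other) are located by a coarse scan plus
bisection to 0.01 d over a window defaulting to the data's support,
[0, 35] d. The smallest crossing age in the window is returned; note that
group-mean curves can also intersect trivially near hatch, so comparisons
of late-cycle overtaking should open the window after the early crossing.

## Non-linear least squares

The fitter is a damped Gauss–Newton (Levenberg-style) iteration with
analytic Jacobians, written in-package rather than delegated, because the
iteration count is itself one of the model-comparison metrics and must be
well-defined and countable: steps solve
`(JᵀJ + λ diag(JᵀJ)) δ = Jᵀr`, λ is divided by 10 on acceptance and
multiplied by 10 on rejection, and only non-increasing-RSS steps are
accepted, so the RSS trace is monotone. Convergence: relative RSS drop
below 1e-10 or relative parameter step below 1e-8, capped at 500
iterations; non-convergence returns the best-so-far parameters flagged
`converged = False`. No bounds or transformations are applied during
optimization; inadmissible optima (e.g. `L ≤ K`) are flagged, never
clamped. On six-point weekly data the von Bertalanffy RSS surface has a
long flat valley (the asymptote lies far beyond 35 d), so its fit
characteristically consumes an order of magnitude more iterations than the
logistic or Gompertz–Laird fits — a pattern the test suite asserts.

Starting values are data-driven, since six-point series are unforgiving:
logistic `W_A⁰ = 2·max(bw)` with `K⁰, t_i⁰` from a logit linearization;
Gompertz–Laird from a regression of log growth increments; von Bertalanffy
from a cube-root linearization profiled over a 24-point grid of rate
constants.

Goodness of fit: `R² = 1 − RSS/TSS`, `RMSE = sqrt(RSS/n)`, and
Gaussian-likelihood information criteria with the residual variance
counted as a parameter, `AIC = n ln(RSS/n) + 2(p+1)`,
`BIC = n ln(RSS/n) + (p+1) ln n`, `AICc = AIC + 2(p+1)(p+2)/(n−p−2)`.
Absolute AIC/BIC values are convention-dependent (additive constants and
parameter counting differ between implementations); only differences
between models fitted to the same data are meaningful, and the package
never compares them across datasets. Model ranking uses highest R² and
lowest AIC, BIC, RMSE and iteration count, combined as a mean rank with
ties broken by fewer iterations then lower RMSE.

Pooled "all data by group" fits stack every flock-week observation as one
unweighted point, mirroring the dual per-flock/pooled design of commercial
growth analyses.

## Efficiency partitioning

Flocks are split into high- (HE) and low- (LE) efficiency groups by
recursive binary partitioning of 35-d cumulative FCR. With one unique
flock per response value, a partition tree on a flock identifier is
equivalent to optimal 1-D threshold splits on the response itself, which
is what the implementation does — identical leaf structure without
thousand-level categorical machinery.

Candidate thresholds are midpoints between consecutive distinct sorted
values; the chosen split maximizes the between-group sum-of-squares gain
(ties toward the lower threshold). Because raw split p-values at
commercial sample sizes are vanishingly small, significance is scored as
LogWorth: a pooled-variance two-sample test p-value, Bonferroni-adjusted
by the number of distinct candidate thresholds at the node, transformed to
`−log10(p_adj)`. A split is admissible above a LogWorth threshold of 1.3
(adjusted p < 0.05). Defaults: at most 8 splits, at least 15 flocks per
leaf; both configurable.

Condensing 7–8 leaves into exactly two groups is under-determined, so the
package uses an explicit, reproducible rule: order leaves by mean FCR and
cut at the largest gap between adjacent leaf means — the low block is HE,
the high block LE, and every flock is labeled. A stricter variant
(`n_boundaries=2`) cuts at the two largest gaps and leaves middle leaves
unassigned, for datasets where the efficiency extremes are genuine subsets.
Tree quality is summarized by `R² = 1 − SS_within/SS_total` and
`RASE = sqrt(SS_within/n)` of the leaf-mean predictor.

## Group statistics

Weekly BW, FI, FCR and the fitted parameters are compared between
efficiency groups by one-way ANOVA with efficiency as the main effect.
Mortality percentages are arcsine-square-root transformed
(`asin(sqrt(p/100))`) before testing, while displayed means stay on the
raw percent scale. Mean separation uses pooled-variance Student's t (not
Welch), displayed as letters in descending-mean order (`a` = highest);
every maximal contiguous run of groups with no significant internal pair
shares a letter, so two groups share a letter iff they do not differ.
Printed summaries report pooled `SEM = sqrt(MSE/n_harmonic)` and
`CV = 100·sqrt(MSE)/grand mean` — the pooled convention was chosen because
per-group SEs are not separable in typical printed tables. Default alpha
is 0.05 for letter display with 0.01 available where a stricter
growth-model alpha is wanted; both are exposed in configuration.
Parameter correlations are Pearson's r with the t-transform p-value and no
multiplicity correction.

## Synthetic flock generator

The generator emulates the between-flock structure of a commercial
integration's weekly table. Per `(sex, efficiency)` cell it draws:

- **BW**: the cell's growth curve (logistic by default, with published
  group-mean parameters as defaults; Gompertz–Laird and von Bertalanffy
  generators available for cross-model recovery work) times independent
  mean-one lognormal noise per age, CVs defaulting to the 6.1–3.4%
  age profile of commercial records. Zero-CV draws therefore lie exactly
  on the generating curve, and sample means converge to it.
- **35-d FCR**: normal around the cell mean (defaults 1.371–1.527, SD
  0.02, truncated above 1), with earlier ages filled by rescaling the
  cell's cumulative-FCR trajectory template to the drawn terminal value
  plus 2% lognormal noise.
- **FI**: `FI = FCR × BW` identically, so the triad the pipeline consumes
  is internally consistent by construction.
- **Mortality**: weekly percentages from a gamma distribution (shape 9,
  mean 0.55%), accumulated, hence positive, right-skewed and
  non-decreasing.

All draws flow from a single seeded `numpy` generator, so datasets replay
bit-identically. What the generator does **not** emulate: bird-level
sampling within flocks (weekly BW in industry is a ~1% sample average;
flock-level noise absorbs it), farm/altitude/season covariates, feed
allocation-plan mechanics, and any correlation between BW noise and FCR.
Passing tests on synthetic data therefore demonstrate that the pipeline
recovers structure *of this kind* — latent efficiency mixtures and smooth
sigmoid growth with multiplicative noise — not that it is robust to every
pathology of field data.

## Numerical choices and degenerate inputs

- Table storage at 3 decimals (grams and percent), exceeding the precision
  of printed industry reports; round-trip equality is asserted at that
  precision.
- Fits require ≥ 4 distinct ages and positive BW; all-equal responses are
  a degenerate-data error; `TSS = 0` makes R² undefined (error), and a
  perfect fit sends AIC/BIC to −∞ rather than a fake finite value.
- All-equal FCR values grow a zero-split tree (R² = 0, no error); labeling
  a single-leaf tree is an error ("no partition"), as is an all-equal-leaf
  tree.
- Crossover search returns the earliest sign change at 0.01-d resolution;
  coincident curves return none.

## Analysis problem sizes

The shipped analysis scripts and test suite run at 50 flocks per
sex × efficiency cell (200 flocks), which already reproduces the
qualitative published patterns — R² > 0.99 for all pooled fits, the von
Bertalanffy iteration excess, strongly negative K–t_i correlations
(≈ −0.9), and near-perfect partition recovery — while keeping any single
run in seconds. Law-of-large-numbers checks use 2000 flocks; Monte-Carlo
recovery checks use 200 replicates per condition.

## Known limitations

- With only six weekly points ending before the growth plateau, the NLS
  asymptote is weakly identified. The *distribution* of per-flock `W_A`
  estimates is consequently right-skewed at realistic noise (CV ≈ 3.4%):
  medians are essentially unbiased, but means of per-flock estimates are
  pulled upward by occasional near-ridge fits. Group-level summaries of
  per-flock nonlinear functions (e.g. `MI`) likewise differ from the same
  functions evaluated at group-mean parameters; the package reports both
  routes rather than conflating them.
- The HE/LE condensation rule (largest leaf-mean gap) is a documented,
  reproducible stand-in for proprietary tree-software behavior, not a
  reconstruction of it.
- The von Bertalanffy fit may legitimately exhaust the 500-iteration cap
  on pooled data (flagged, best-so-far parameters returned); raising the
  cap trades runtime for a formally converged flag without materially
  changing the parameters.
- Absolute AIC/BIC values are not comparable across software conventions;
  the package documents its convention and uses within-data differences
  only.
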