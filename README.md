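# flockgrowth

Growth-curve analytics for commercial broiler flock performance records.

Broiler integrations log weekly flock body weight (BW), cumulative feed
intake (FI), cumulative feed conversion ratio (FCR) and mortality, but
rarely use those records to ask *which growth dynamics make a flock feed-
efficient*. `flockgrowth` implements that analysis end to end:

1. **Partition** flocks into high- (HE) and low- (LE) feed-efficiency
   groups by recursive binary splitting of 35-d FCR, with split
   significance scored as LogWorth (−log10 of a Bonferroni-adjusted
   p-value) and leaves condensed to two groups at the largest leaf-mean
   gap.
2. **Fit** three non-linear growth models to each flock's BW-vs-age series
   and to the pooled group data, by a damped Gauss–Newton least-squares
   iteration with analytic Jacobians and a countable iteration loop:

   - logistic `y = W_A / (1 + e^{-K(t - t_i)})`
   - Gompertz–Laird `y = W_0 e^{(L/K)(1 - e^{-Kt})}`
   - von Bertalanffy `y = W_A (1 - B e^{-Kt})^3`

3. **Derive** inflection-point traits: `W_i = W_A/2` and maximum increment
   `MI = K·W_i/2` (logistic); `t_i = ln(3B)/K`, `W_i = 8W_A/27`
   (von Bertalanffy); `t_i = ln(L/K)/K`, `W_A = W_0 e^{L/K}`
   (Gompertz–Laird) — plus analytic BW-gain curves and group crossover
   ages.
4. **Compare** groups: one-way ANOVA with efficiency as the main effect,
   pooled-t letter separation, arcsine-square-root transform for mortality
   percentages, pooled SEM/CV summaries, parameter correlations, and model
   ranking by R², AIC, BIC, RMSE and iteration count.

Because integration data are proprietary, the package includes a seeded
synthetic generator reproducing their statistical structure (two sexes, a
latent two-group efficiency mixture with 35-d FCR means near 1.37/1.53,
logistic BW trajectories with 3–7% multiplicative noise, gamma-distributed
mortality). It is first-class, tested code: every downstream stage is
validated against its known ground truth. See `docs/methods.md` for the
full model and design notes.

## Worked example

```sh
python analysis/01_simulate_flocks.py
python analysis/02_partition_efficiency.py
python analysis/03_fit_growth_models.py
python analysis/04_compare_groups.py
python analysis/05_model_selection.py
```

The second script prints, for the default 200-flock dataset:

```
male: 3 splits, R2=0.982, RASE=0.0109; HE mean FCR 1.368 < LE 1.528; agreement with latent truth 100.0%
female: 3 splits, R2=0.949, RASE=0.0118; HE mean FCR 1.429 < LE 1.525; agreement with latent truth 100.0%
```

i.e. the FCR tree recovers the latent efficiency groups perfectly and the
leaf-mean predictor explains ≈95–98% of FCR variance. The third script
fits the pooled group curves:

```
                   w_a      k     t_i       w_i       mi     r2  n_iter
sex    group
female HE     2992.304  0.117  31.949  1496.152   87.546  0.996       5
       LE     2610.427  0.120  29.640  1305.214   78.212  0.996       6
male   HE     3505.686  0.116  33.248  1752.843  101.701  0.997       5
       LE     3003.699  0.120  30.478  1501.850   89.755  0.997       6
```

HE flocks have higher asymptotic weight `w_a`, a *lower* growth-rate
constant `k`, and a later, heavier inflection point (`t_i`, `w_i`) — the
slower-decaying growth that ends heavier at slaughter age. The fifth
script confirms the model-selection pattern: every pooled fit reaches
R² > 0.99, and the von Bertalanffy fit needs the most iterations in every
cell (its asymptote lies far beyond the 35-d window), e.g.

```
male/HE: best composite rank = logistic (R2 0.9967, RMSE 37.7 g); von Bertalanffy needed 500 iterations, the most of the three: True
```

The fourth script reports the efficiency contrast (HE FCR lower at every
age, p ≈ 0) and the parameter correlation `r(K, t_i) ≈ −0.9`: flocks that
grow faster reach their inflection weight younger.

The same pipeline is scriptable via the `flockgrowth` CLI
(`simulate`, `clean`, `partition`, `fit`, `compare`, `run`) on any flock
table in the documented wide CSV dialect.

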