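# Methods

## Model

Let `C_gait` and `n_gait` be deaths and person-years in gender `g`,
area `a`, age group `i` (youngest first) and period `t`. Conditional on
the rate the counts are independent Poisson,
`C_gait ~ Poisson(n_gait r_gait)`, and the log rate is additive:

```
log r_gait = beta_g + alpha_tg + gamma_ig + kappa_kg + phi_a + delta_at .
```

The birth-cohort index is `k = M(I − i) + t`, where `M` is the ratio of
the age-interval width to the period-interval width; cohorts therefore
live on a grid of `K = M(I − 1) + T` indices, and the unequal interval
widths enter only through this index map. With the default full-size
dimensions (I = 13 five-year groups, T = 24 annual periods, M = 5) there
are K = 84 cohorts.

Priors: `beta_g ~ N(0, 1000)`. The period, age and cohort effects are
intrinsic random walks per gender — precision `tau · D'D` with `D` the
first- or second-difference operator. The spatial effect `phi` has the
intrinsic CAR (Besag) structure `Q = D − W` on the area adjacency graph;
`phi` and the interaction `delta` carry no gender subscript and are
shared across genders. The space-time interaction follows the Knorr-Held
taxonomy: its structure matrix is a Kronecker product of a spatial
factor (identity or the ICAR structure) and a temporal factor (identity
or a first-order walk), giving types I (both unstructured) through IV
(both structured); its rank is the product of the factor ranks.

### Identifiability

Sum-to-zero constraints are applied: one per gender for each of
`alpha`, `gamma`, `kappa`; one overall for `phi`; and for `delta` the
family matching its type (overall sum for I, per-area sums for II,
per-period sums for III, both families — `A + T − 1` independent
constraints — for IV). These remove the level aliasing against the
intercepts. The classical APC linear-trend aliasing is deliberately
*not* removed by additional drift constraints: with the default
random-walk orders (RW1 period, RW2 age and cohort) the period walk's
first-difference penalty breaks the likelihood-flat direction, so the
joint posterior is proper, but individual linear trends in `gamma` and
`kappa` are only weakly identified — the reported summaries (rate
profiles, region effects, ratios) are functions of identified
combinations. RW2 for age and cohort is the standard smooth-curve choice
in multivariate APC modelling; all orders are switchable in `ModelSpec`.

### Hyperpriors

Each random-effect precision `tau = sigma^-2` gets either

* a penalised-complexity prior, induced by an exponential prior on
  `sigma` calibrated by `P(sigma > u) = alpha`; on the precision scale
  `pi(tau) = (lambda/2) tau^{-3/2} exp(−lambda tau^{-1/2})` with
  `lambda = −ln(alpha)/u`. Defaults `u = 1`, `alpha = 0.01` — weakly
  informative on the log-rate scale, where effects of SD 1 are already
  implausibly large for cause-specific mortality; or
* a bounded uniform prior on the SD, `pi(sigma) ∝ 1` on `(0, 100]`. The
  bound replaces the fully improper uniform reference prior so the
  posterior is guaranteed proper regardless of the data; at these data
  sizes the bound is never active.

By default the gender copies of each temporal effect share one
precision (fewer hyperparameters); per-gender precisions are available
by flag.

## Sampler

Metropolis-within-Gibbs over latent blocks (`beta`; `alpha`, `gamma`,
`kappa` per gender; `phi`; `delta`) and the precisions:

* **Block updates.** For each block the Poisson log-likelihood Hessian is
  diagonal in the block's coordinates (every cell loads on exactly one
  coordinate), so the full conditional is well approximated by a
  Gaussian with precision `tau Q + diag(h)`. The block's conditional
  mode is found by damped Newton iteration (backtracking line search);
  the proposal is a draw from the Gaussian approximation at that mode,
  conditioned on the block's sum-to-zero constraints by
  conditioning-by-kriging. Because the mode depends only on the other
  blocks, this is an independence proposal, accepted by a
  Metropolis-Hastings step with the exact degenerate-Gaussian proposal
  density (the constrained density is the unconstrained one divided by
  the marginal of the constraint functional). Every retained draw
  satisfies its constraints to machine precision. Observed acceptance
  rates are 0.9–1.0 throughout, reflecting how close the Poisson
  conditionals are to Gaussian at these counts.
* **Precisions.** Adaptive random-walk Metropolis on `log tau`
  (Robbins-Monro step adaptation toward 44% acceptance during warmup),
  targeting the exact conditional with the generalized log-determinant
  `rank(Z'QZ)/2 · log tau` computed once per block from the structure
  restricted to the constraint space.

Defaults: 4 chains, 5,000 iterations, first half warmup. Runs are
bit-reproducible given (seed, chains, iterations); chain seeds are
spawned from one `SeedSequence`. A block that accepts no proposal during
warmup raises an adaptation-failure error rather than returning a frozen
chain. Diagnostics (ESS, split-chain R-hat) come from `arviz`.

### Numerical choices

* Kernel/rank decisions use an eigenvalue threshold of `1e-8` times the
  largest eigenvalue.
* Likelihood curvature for coordinates with no data (possible for
  cohorts when `T < M`) is floored at `1e-12`, leaving the prior to
  govern them.
* `log tau` is clamped to `[-18, 27]` so `tau Q` stays representable.
* For the type-I interaction the proposal precision is diagonal and the
  update is `O(AT)`; other types use dense Cholesky factorizations,
  which at the full Spanish dimensions (`AT = 1200`) cost ~0.05 s per
  update.
* Redundant constraint rows (the type-IV system has rank `A + T − 1`,
  one less than its `A + T` rows) are dropped before kriging.

## Model comparison

`DIC = D̄ + p_D` with `p_D = D̄ − D(θ̄)`, the plug-in deviance evaluated
at the posterior means of the latent effects — the focus level at which
the hierarchical model is specified. `WAIC = −2(lppd − p_waic)` with the
variance form of `p_waic`, using the cell `(g,a,i,t)` as the pointwise
unit. Rankings are ascending with ties broken by fewer effective
parameters, then name.

## Descriptive rates

Crude rates are `deaths/person-years × 100,000`. Directly standardized
rates use the European Standard Population 2013 weights for ages 25+,
with the open-ended `[85,+)` group carrying the sum of the 85–89 and 90+
weights. Because the study models ages 25+ only, the weights are
renormalized over the 13 modelled groups: standardized rates are *per
100,000 aged-25+ standard population* and sit above all-ages ASRs by
construction. Any other `StandardPopulation` can be substituted.

## Posterior summaries

All summaries are deterministic functions of the stored draws.
Cell-level point rates are posterior medians (the median commutes with
`exp`, so exp-scale and log-scale medians agree; draws are processed
area-by-area to bound memory). "Average rates" over a margin (age,
cohort, period) are population-weighted with weights `n_gait`, so the
national profile at a level equals total expected deaths over total
person-years there; an unweighted variant is available by flag. Region
effects report the median of `exp(phi_a)` and the exceedance probability
`P(exp(phi_a) > 1)`; space-time surfaces take the median of
`exp(phi_a + delta_at)` draw-wise before summarizing; cohort ratios
divide each region's average cohort profile by the national one,
skipping cohorts where the national profile is unavailable. Axis levels
with zero person-years are excluded.

## Synthetic data

The generator emulates a national cause-of-death registry: smooth truth
curves on the log scale (age rising ~4 log units from the youngest group
to a plateau over the two oldest; period drifting +0.005 per year; a
smooth cohort hump of amplitude 0.15), a spatial field drawn from the
ICAR prior on a rook lattice and rescaled to SD 0.2, a weak unstructured
space-time interaction of SD 0.05, a male baseline 0.3 log units above
the female, and a baseline level of 8 per 100,000. Person-years are
drawn once per (area, age) around a scale of 25,000 — the magnitude of a
province × five-year-age-group × single-year population in a
mid-size European country — and reused across periods and genders with
±5% jitter, echoing demographic stability. Truth effects are centered
onto the constraint space before counts are drawn.

Two presets: `spain_like` (G=2, A=50 on a 5×10 lattice, I=13, T=24,
K=84) matches the full study's dimensional structure; `reduced` (A=15,
I=6, T=10) keeps the same qualitative structure at desk scale and is the
preset used by the packaged studies so that the recovery (20 replicates),
selection (20 replicates × 2 fits) and sensitivity suites all run on a
single CPU in minutes; the selection study uses a still smaller grid
(A=10, I=4, T=8) since it fits two models per replicate. The selection
benchmark's exposure is sized by a power computation: the Fisher
information for one interaction cell `delta_at` is the expected death
count of its (area, period) pair, so an interaction of SD `s` only
becomes detectable once expected deaths per pair reach roughly `1/s²`
(400 for the default `s = 0.05`); the benchmark therefore uses 250,000
person-years per cell, while the recovery and sensitivity suites keep
the default 25,000. What passing
these studies shows is that the estimation machinery recovers the
generative structure at realistic magnitudes; what they cannot show is
robustness to features of real registry data the generator omits —
ICD coding-era changes mid-series, age-misstatement at the oldest ages,
population denominators with census error, or true adjacency structure
with islands and enclaves.

## Known limitations

* Inference is sampling-based; no nested-Laplace approximation is
  provided, and large type-IV interactions are the slowest component.
* No gender-correlated (multivariate) smoothing across genders: genders
  share precisions, not innovations.
* Linear trends of age and cohort effects are reported only through
  identified combinations (see Identifiability).
* The precision "truth" recorded by the generator for the spatial field
  refers to the rescaled realized draw, so recovery of `tau_phi` is
  reported but not sharply interpretable; intercept and cell-rate
  recovery are the calibrated checks.
* Choropleth rendering of real administrative boundaries is out of
  scope; spatial summaries are tables keyed by area label.
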