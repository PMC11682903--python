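# Methods

This note records the models implemented in `d2tpsa`, their assumptions, the
defaults and why they were chosen, and what the synthetic testbed does and
does not establish.

## 1. Rule-based D2T classification

A patient is difficult-to-treat when **all three** criteria hold:

1. **Multi-failure** — at least `min_failed_btsdmards` (default 2) previous
   b/tsDMARDs; the count excludes the ongoing therapy.  A
   distinct-mechanism-of-action requirement can be switched on but is
   honoured only when per-drug mechanism data exist; the cohort schema
   carries none, so the criterion is count-only in practice.
2. **Active disease** — DAPSA above the moderate-activity floor
   (default > 14; the DAPSA bands used throughout are remission ≤ 4,
   low ≤ 14, moderate ≤ 28, high > 28, with boundaries belonging to the
   lower band).
3. **Problematic management** — a clinician-perceived flag carried in the
   cohort table.

Missing inputs make the status *indeterminate*: the patient is never
silently counted on either side, and the per-criterion breakdown records
which rule could not be evaluated.  The rule engine is deliberately a
configuration object rather than hard-coded logic because published
adaptations of the RA definition differ in their exact thresholds.

### Firth-penalized univariate associations

With single-digit numbers of D2T patients, ordinary logistic ML estimates
diverge under separation and are badly biased.  Associations are therefore
estimated by maximizing the Jeffreys-penalized likelihood
`ℓ(β) + ½ log det I(β)` via Newton steps with the bias-corrected score
`U*(β) = Σ xᵢ(yᵢ − πᵢ + hᵢ(½ − πᵢ))` (hᵢ = hat diagonal) and step-halving.
Reported intervals are 95 % Wald intervals from the penalized information;
profile-penalized-likelihood intervals would be a refinement but are not
implemented.  For a 2×2 table this estimator has a closed form — the log
odds ratio after adding 0.5 to every cell — which the tests exploit as an
exact oracle, cross-checked by direct numerical maximization of the
penalized likelihood.  A multivariable Firth model is intentionally not
offered: with so few events it would not be estimable meaningfully.

## 2. Observed/expected difficulty index

Definitions as in the README.  Numerical conventions that matter:

- **Quantile estimator.**  The 75th-percentile cut-off defaults to linear
  interpolation of order statistics (the common statistical-software
  default) but is selectable among the standard estimator family, because
  the flags are threshold-dependent.  The cut-off is recomputed per cohort;
  a frozen reference value can be supplied to apply one cohort's
  calibration to another.
- **Rounding.**  The expected count is a strict ceiling, `ceil(k) = k` at
  exact integers, and never below 1.
- **Ties.**  Ratio exactly 1 is classified *respondent*; only a strict
  excess of observed over expected flags a patient.
- **Follow-up time.**  Months since PsA diagnosis — the only duration in
  the cohort schema.  The time column is configurable (e.g. time since
  first b/tsDMARD) if such a field is available.

A structural consequence worth knowing: `E ≥ rate75 × T` implies that a
flagged patient's failure rate strictly exceeds the cohort's 75th
percentile, so the flagged fraction is bounded by 25 % (plus at most one
tie's worth, 1/n).  The tests assert this bound on random cohorts.

## 3. Poisson-offset relative-difficulty regression

`A ~ Poisson`, log link, offset `log E`.  The model assumes (a) counts are
conditionally Poisson — no overdispersion correction is applied, matching
the analysis being reproduced; a negative-binomial extension would be
straightforward but is out of scope — and (b) log-linearity of covariate
effects, relaxed for continuous scores by restricted cubic splines.

- **Fitting** is IRLS (via statsmodels), deviance-change convergence at
  1e-8, at most 100 iterations; covariance is the inverse Fisher
  information; `AIC = −2ℓ + 2p`.  Rank-deficient designs abort with the
  aliased columns named.
- **Splines.**  Harrell-convention restricted cubic basis: k knots give
  k−1 columns (the first is x itself), the curve is linear beyond the
  boundary knots and the nonlinear columns vanish below the first knot.
  Default 3 knots at the 10th/50th/90th percentiles (4 and more knots use
  the standard quantile tables).  Knots are frozen on the full analysis
  data before any resampling so coefficients stay comparable.  Heavily
  zero-inflated scores (PhGA's median is 0) can produce coincident quantile
  knots; such covariates are automatically downgraded to linear coding,
  with a log record, instead of aborting.
- **Dummy coding.**  Reference levels: male sex, peripheral PsA subset,
  absence for every binary flag.  Psoriasis subtypes are *not* mutually
  exclusive (patients may have several), so each subtype is its own
  presence/absence dummy next to a `has_psoriasis` main effect, rather than
  one multi-level factor.
- **Reporting.**  Exponentiated effects with 95 % Wald intervals
  (z = 1.959964).  For a splined covariate a single exp(β) is undefined, so
  the effect is reported as the 75th-vs-25th-percentile contrast of the
  fitted curve with a delta-method interval; nonlinearity is tested by the
  joint Wald statistic of the nonlinear columns.
- **Global-assessment choice.**  The physician global assessment (PhGA) is
  the default model covariate; the patient global assessment (PGA) is
  generated and accepted as an alternative.  RDCI is generated and
  summarized but not a default model covariate.

## 4. Bagged backward-AIC selection and model averaging

On the complete cases (rows with no missing model covariate):

1. **Backward elimination on blocks.**  All design columns of one covariate
   (dummy levels, spline terms) enter and leave together.  Each step drops
   the block whose removal lowers AIC the most; ties break toward the block
   earliest in the specification order; elimination stops when no removal
   improves AIC.  The accepted AIC path is strictly decreasing by
   construction and is asserted as such.
2. **Bagging.**  B = 1 000 resamples by default (tests and the acceptance
   script use B = 200; selection frequencies scale linearly in cost and the
   Monte-Carlo error of a frequency at B = 200 is ≤ 0.035).  Resampling is
   seeded and fully reproducible.  A resample in which the full model
   cannot be fitted — typically a rare dummy level absent from the draw —
   is recorded as degenerate and re-drawn so that coefficient vectors stay
   conformable; more than 20 % degenerate draws aborts with advice to prune
   the covariate set.
3. **Sparse-covariate pruning.**  Before bagging, the pipeline drops
   covariates with fewer than 4 patients in any class or level.  Such
   levels would be absent from a large fraction of resamples (a level with
   c carriers is lost with probability ≈ e^(−c)), making the procedure
   mostly degenerate redraws; pruning is deterministic and recorded in the
   run manifest.
4. **Averaging.**  Per design column, the mean over all B resamples with
   zeros imputed when the covariate was eliminated.  Algebraically this is
   selection frequency × conditional mean, so never-selected covariates get
   exactly 0 and weakly supported effects shrink toward 0.  Every covariate
   stays in the final model; selection only zeroes per-resample
   coefficients.  No bootstrap confidence intervals are attached to the
   averaged coefficients; the per-resample draws are exported as binned
   histograms instead.
5. **Prediction.**  Because the linear predictor is offset by `log E`,
   `exp(x'β̄)` *is* the predicted observed/expected ratio; patients are
   stratified at ≤ 1, (1, 1.5], > 1.5, and per-stratum covariate
   distributions are tabulated.  Averaging-induced shrinkage means the
   model typically flags fewer patients than the raw index does.
6. **Nomogram.**  Per covariate, the contribution range of `x_block'β̄`
   over the observed data (exactly |β̄| for a binary flag), rescaled so the
   widest covariate spans 100 points.  The scale rows emitted with the
   table make the mapping invertible: total points → linear predictor →
   predicted ratio, exact to floating-point round-off (asserted to 1e-8).
   The nomogram is emitted as a table; its information content is the
   contribution mapping, not the graphic.

## 5. Synthetic cohort generator

The generator emulates the marginal structure of a single-centre cohort of
267 b/tsDMARD-treated PsA patients: binary/categorical prevalences are taken
from the published descriptive table (male 52.4 %, peripheral subset 72.3 %
of the subset distribution, psoriasis 78.5 % with subtype rates conditional
on skin involvement, fibromyalgia 15.7 %, corticosteroid use 11.6 %, …).

- **Continuous scores** are gamma-distributed with parameters solved
  numerically (log-least-squares on the three quartiles).  Scores whose
  published lower quartiles sit at zero (PhGA, PGA, HAQ, RDCI, BSA) use a
  point-mass-at-zero + gamma mixture: the zero mass is fixed (0.55 when the
  median is 0, 0.30 when only Q1 is 0) and the gamma is matched to the
  conditional quantiles of the positive part.  A pure gamma cannot place
  its median at 0, and zero-inflation is exactly how such clinimetric
  scores behave in low-activity cohorts.
- **Follow-up** is log-normal matched to median 154.5 and IQR
  [89.0, 249.25] months, floored at 3 (the treatment-duration inclusion
  criterion); the floor is numerically irrelevant (P < 1e-6).
- **Drug counts** come from the planted model
  `A = 1 + Poisson(T·λ₀·exp(x'β))`, so every patient carries at least the
  current therapy.  Defaults: λ₀ = 0.003 drugs/month — chosen so simulated
  previous-drug counts have median 0 and Q3 ≈ 1, the published regime —
  with planted rate ratios 2.0 (fibromyalgia), 1.5 (steroid use), 1.4 (nail
  psoriasis) and 0 elsewhere.  Downstream recovery tests fit
  `n_prev ~ Poisson` with offset `log T`, the exactly-specified generative
  model; the pipeline's index-offset model targets the same effects through
  the A = counts + 1 construction, accepting the small mean shift from the
  added unit.
- **Missingness** is MCAR per field, default 0.128 on the six clinimetric
  scores, making the complete-case fraction over the three modelled scores
  (1 − 0.128)³ = 0.663 ≈ the published 177/267.  Drug counts, follow-up and
  identifiers are never missing, so the index is always computable.
- **Independence.**  Covariates are drawn independently — only marginals
  are published.  An important consequence: the rule-based D2T prevalence
  under independence is the product of three small probabilities (≈ 0.5 %),
  well below the ≈ 3 % seen in real data where failures, activity and
  problematic management are strongly correlated.  Passing tests therefore
  demonstrate the correctness of the machinery on marginally faithful data,
  not the joint structure of any real cohort; effect estimates on real
  registries may behave differently under confounding, informative
  missingness or overdispersion, none of which the generator produces.

## 6. Problem sizes used by the test suite and acceptance script

Simulation-based checks use: n = 5 000 for point recovery of the planted
coefficients (each within 3 SEs), 200 replicates at n = 1 000 for 95 % Wald
CI coverage, 500 simulations at n = 500 for the 2-df nonlinearity Wald
calibration (rejection in 3–7 % under a linear truth), 100 random cohorts
for the flagged-fraction bound, and B = 200 bootstrap resamples at n = 500
for selection-frequency properties (planted rate ratio 2.0 selected in
≥ 95 % of resamples; frequencies ordered strong > weak > null for ratios
2.0/1.3/1.0).  These sizes give Monte-Carlo error comfortably inside each
asserted band while keeping the default suite fast.

## Known limitations

- Plain Poisson error: overdispersion inflates neither the index nor the
  point estimates but would narrow reported intervals on real data.
- The index uses only counts and total time; it ignores drug-survival
  timing, discontinuation reasons and mechanism coverage.
- MCAR is the only missingness mechanism generated or assumed; the
  complete-case step is biased under MNAR.
- The index threshold (75th percentile) is a calibration choice; flags are
  threshold-dependent even though regression coefficients are not.
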