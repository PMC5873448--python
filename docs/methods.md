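# Methods

## Models and estimation

All methods target the probability of a binary clinical outcome given a
covariate vector, on the logistic scale. A published CPM is treated as a
frozen intercept plus sparse named coefficient vector; a covariate a model
does not mention has coefficient exactly zero, so every model is defined
over the covariate union. Every fitted object is *collapsed* onto the raw
covariates (intercept plus per-covariate coefficient), with the
structural parameters (calibration slope, stacking weights, penalised
adjustments, λ) retained alongside; collapsed and structural evaluation
agree to numerical precision by construction, and tests enforce 1e-10.

**Recalibration / revision / extension.** Recalibration is a two-parameter
maximum-likelihood logistic fit of the outcome on one model's linear
predictor. Revision adds free adjustments δ̂_p for covariates in the
model's support; extension over all IPD covariates. Note a structural
fact: with *every* adjustment present the design `[1, LP, x_S]` is
overcomplete, because the linear predictor is an affine combination of
its own covariates — the fit has one flat direction, while the collapsed
prediction model stays identified. The internal fits therefore use the
package's coordinate-descent solver at zero penalty, which reaches the
identified optimum to ~1e-15 (pinv-based IRLS implementations stall
~1e-5 short on this flat likelihood). Adjustment selection is by
likelihood-ratio test; the default policy is backward elimination from
the full adjustment set, dropping the least significant term until all
remaining have p < α (default 0.05); forward and "none" are selectable,
and α ≥ 1 disables selection. Ties in the LRT — including the exact
lossless removal created by the overcompleteness — are detected on the
χ² statistic scale (the p-value scale is infinitely steep at 0 and would
amplify solver noise) and resolved by dropping the smallest |δ̂|, so a
genuinely needed adjustment is never discarded by the tie.

**Stacked regression.** Maximum-likelihood logistic regression of the
outcome on the M linear predictors. Near-collinear predictor sets (e.g.
duplicated models) are refused with an error naming the aliased models
(pivoted-QR detection, condition threshold 1e8). The optional
non-negativity constraint on the weights is imposed by bound-constrained
quasi-Newton maximisation of the same likelihood; the unconstrained
variant is the default.

**Hybrid method.** The design is `[LP_1 … LP_M, x_1 … x_P]` with an
unpenalised intercept. Estimation maximises mean log-likelihood minus
`λ Σ ν_r |θ_r|` by cyclic coordinate descent on the weighted
least-squares subproblem inside IRLS, with an active-set strategy between
full sweeps; convergence when the maximum coefficient change falls below
1e-7 (1e-5 inside cross-validation folds, where the out-of-fold deviance
is insensitive far below that level). Columns are internally centred and
scaled to unit variance; penalty weights apply on that standardised
scale, and results are returned on the original scale. Weight ν_r = 0
means unpenalised (the coefficient is never zeroed); ν_r = +∞ excludes
the column. The λ grid has 100 points, log-spaced from λ_max (the
smallest λ that zeroes every penalised coefficient, computed from the
weighted score at the model containing only unpenalised columns) down to
1e-4·λ_max. Cross-validation uses 10 outcome-stratified folds from the
run seed and selects λ minimising the mean out-of-fold binomial
deviance, breaking ties towards the larger (sparser) λ; the 1-SE rule is
deliberately not used. Case 3 first fits the same design under a
squared-magnitude penalty (50-point grid spanning 1e3·λ_max down to
1e-4·λ_max, since ridge has no finite λ_max; same CV policy) and sets
ν_r to the inverse absolute standardised ridge coefficient, with
coefficients below 1e-8 in magnitude excluded outright.

Reduction identities hold and are tested: one model plus λ = 0
reproduces unpenalised revision/extension; λ → ∞ under case 1 leaves the
event-rate intercept `logit(ȳ)`; λ → ∞ under case 2 leaves plain stacked
regression; one model in the stack reproduces recalibration.

**Re-development.** Backward AIC starts from the full logistic model and
repeatedly removes the covariate whose removal most decreases AIC
(deterministic, ties by candidate order, no re-entry). Ridge
re-development reuses the penalised machinery and CV policy above with
uniform weights.

**Validation.** Calibration intercept and slope are both read from one
unconstrained logistic fit of the outcome on the logit of predicted risk
(not the offset-based calibration-in-the-large); this reproduces the
exact (0, 1) apparent calibration of any maximum-likelihood model on its
training data, a score-equation identity the tests assert at 1e-6. AUC
is the tie-aware rank-sum statistic with a DeLong interval; Wald
intervals for calibration parameters. Optimism correction is Harrell's
bootstrap: the *complete* modelling recipe (including selection and CV)
is refit on each resample, optimism is its resample-minus-original
performance, and the mean over replicates (default 100) is subtracted
from apparent performance. Resamples with a single outcome class are
redrawn (≤ 10 attempts); replicates where the recipe itself fails are
counted and skipped.

## Synthetic study generator

Six populations share 50 covariates in 10 clusters of 5 serially
correlated variables (latent AR-1, ρ = 0.4, independent across
clusters), mimicking families of related risk factors. Within each
cluster, positions alternate binary/continuous/binary/continuous/binary;
binary covariates threshold their latent at the 80th percentile
(prevalence 20%). The generating logistic model puts coefficient 0.76 on
the first covariate of each cluster (binary risk factors, odds ratio
≈ 2.1) and zero elsewhere; per population, each nonzero coefficient
receives independent N(0, σ²) noise, so the expected per-coefficient
range across the six populations is σ·E[range of 6 standard normals]
≈ 2.534σ. The intercept is solved by bisection (tolerance 1e-4) so each
population's mean generating risk is 25%; outcomes are Bernoulli.

The prevalence/coefficient pair was calibrated once, analytically, so
the generating model's validation AUC sits in the operating regime of
TAVI-style mortality models — about 0.74 at σ = 0 rising to about 0.81
at σ = 0.75 — and then frozen; every constant is a visible, overridable
field of `SyntheticDesign`.

Five populations of 5000 each yield one "published" CPM: a maximum-
likelihood logistic fit restricted to a resampled subset containing each
true predictor with probability 0.8 plus 5 uniformly drawn noise
covariates (resampled every iteration; separation triggers a subset
redraw). The sixth population provides the IPD (n ∈ {200 … 5000}) and an
independent validation sample of 5000 drawn from the same generating
model (IPD and validation rows are generated jointly so they share one
intercept). IPD covariates are restricted to the union of the five CPM
supports. Per iteration all requested methods are fitted on the IPD and
evaluated on the validation sample (MSE against generating risk,
calibration, AUC, plus the generating model's own AUC); means and
empirical standard errors are reported, and per-iteration child seeds
make scenarios reproducible and parallelisable. Method failures are
recorded and skipped, never fatal.

## Registry-style study generator

Outcomes over a realistic covariate table follow a logistic model whose
coefficient for covariate p is the mean of the four published TAVI
coefficients — denominator always 4, absent coefficients counting as
zero — plus ε_p ~ N(0, σ_p²) with σ_p² ~ U(0, 0.75), under a sign
restriction: a perturbed coefficient whose sign opposes the published
mean is set to zero. Four unmeasured binary covariates (coefficients
U(1.4, 1.6), prevalences U(0.30, 0.40), drawn once per replicate)
contribute to outcomes but are typed out of reach of every fitting
routine. The intercept is solved for a 25% overall event rate on the
realised table.

Because the underlying registry is not distributable, a synthetic
covariate table stands in for it (`synthesize_covariate_table`; the
docstring and this note flag it as synthetic). Age, BMI, LVEF and eGFR
bands are derived from one shared continuous draw per quantity, so
overlapping band definitions from different models are mutually
consistent; per-5-unit terms are centred increments of the same draws
(age−80)/5 and (eGFR−55)/5 — uncentred values of ~16 units under
±N(0, 0.75) coefficient noise would swing the linear predictor by ±10
and destroy the event-rate regime. Access route and acuity are exclusive
categories; comorbidity prevalences are configuration constants chosen
for marginal plausibility of an elderly valve-intervention cohort. The
table reproduces marginal behaviour only — no attempt is made to match
the registry's joint distribution, so passing tests say nothing about
covariate interactions in real registry data. The covariate union
contains one exact logical redundancy (non-TF access = TA + other
access); backward AIC receives a de-aliased candidate list, penalised
methods handle it natively. Per replicate, development cohorts of 200,
500 and 1000 are drawn without replacement and all methods are validated
on the remaining rows (calibration slope and AUC). Revision of the
20-covariate German AV model quasi-separates in some 200-observation
cohorts; such replicates are recorded as failures.

## Problem sizes and numerical choices

The packaged acceptance script runs 100 iterations for the small-IPD
scenarios and 40–60 for the n = 5000 scenarios; per-iteration validation
AUC has SD 0.01–0.06, so the Monte-Carlo standard error of each reported
mean is a few thousandths. The test suite uses smaller replication
counts with tolerances stated per test. Probabilities are clamped to
[1e-5, 1−1e-5] inside IRLS weights and to [1e-12, 1−1e-12] in deviance
evaluations; predicted risks at exactly 0/1 are clamped with a warning
before calibration. Quantiles use linear interpolation between order
statistics. Suspected separation (absolute coefficients above 50, or
non-finite estimates) raises rather than returning silently absurd
models.

## Known limitations

- Missing data are rejected, not imputed; systematically missing
  covariates (a CPM covariate absent from the IPD) are out of scope.
- The per-model penalty constants are user-suppliable but not selected
  by cross-validation (computationally prohibitive).
- Minimum-deviance CV keeps occasional noise adjustments; it does not
  deliver the all-zero adjustment model in every no-signal replicate the
  way a 1-SE rule would.
- Time-to-event outcomes and calibration-drift re-updating are not
  implemented.
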