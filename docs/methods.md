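# Methods

This note documents the models, numerical choices and known limitations of
`plasmoderf`. It describes what the package computes; every number quoted in
the README is printed by the code itself.

## The population model

The synthetic population stands in for a large registry extract with mostly
sparse binary predictors (indicator codes for prescriptions and
hospital diagnoses) plus a couple of numeric covariates (age/year
analogues, standardized). Its design targets three published fingerprints of
such data: prevalence quartiles of the binary predictors at
(1/3371, 1/1530, 1/112), a weak-outcome event rate of 0.558, and a
weak-outcome forest discrimination in the mid-0.6 AUROC range.

**Prevalence law.** A single two-parameter log-uniform cannot pin three
quartiles: the log of the target median (−7.33) is not the midpoint of the
log quartiles (−8.12, −4.72). We therefore use a *two-piece* log-uniform:
half the mass uniform in log prevalence on [q1²/m, m], half on [m, q3²/m],
where (q1, m, q3) are the target quartiles. The law's 25/50/75% quantiles
then equal the targets exactly, and the heavy left skew of registry
indicator prevalences is preserved. Realized per-column means reproduce the
targets to within sampling error (tested at p = 1150, averaged over seeds).

**Outcome model.** The weak outcome is a sparse additive logistic model.
A fixed `round(signal_fraction · p)` subset of the binary predictors carries
signal; membership is drawn with probability proportional to q(1−q), so
better-supported variables are more likely informative — an ultra-sparse
indicator (a handful of carriers in the whole population) cannot carry
learnable signal either way. Effect magnitudes are exponential with mean
`effect_scale`, signs fair-coin. The numeric covariates carry no effect by
default, keeping the signal inside the sparse-binary structure the study is
about; they still enter every model as candidates. The intercept is solved
by root bracketing (Brent, tolerance 1e-10 on [−40, 40]) so the *expected*
event rate equals the target; the solver fails loudly if the bracket cannot
contain a solution.

Defaults: `signal_fraction = 0.05`; `effect_scale = 0.45` at the full-scale
p = 1150 and 0.8 at the p = 400 profiles. These were calibrated once so the
weak outcome's oracle AUROC (true linear predictor against the outcome)
sits around 0.65–0.72 and a cross-fitted forest attains ≈ 0.61–0.67 —
the weak-predictability regime the study is about — and then frozen.

**Quantile rule.** Prevalence quartiles are computed with linear
interpolation (numpy's default, the type-7 convention).

**What the generator does not emulate.** Columns are independent; real
indicator codes are correlated (e.g., negatively correlated substance
indicators from prescriber preference). No prevalence histogram beyond the
three quartiles, no ICD/ATC semantics, no nonadditive outcome structure.
Directional conclusions transfer only insofar as they are driven by
sparsity, dilution and selection stability rather than by correlation
structure.

## Outcome reinforcement

The strong outcome is built exactly as a property of the population: a
random split into 4 near-equal disjoint folds; a probability forest trained
on the complement of each fold with all predictors; out-of-fold probability
predictions transformed to log odds, multiplied by c = 3.5 and
back-transformed; one Bernoulli draw per row. The result is frozen — every
scenario subsample reuses the same `y_strong`. Because the forest returns
probabilities of exactly 0 or 1 for some rows, probabilities are clipped to
[1e-6, 1 − 1e-6] before the logit. Reinforcement is order-preserving and
scales the logit variance by c², both enforced by tests. The forest
hyperparameters of this step default to the same probability-forest
defaults as everywhere else.

## Preceding-study selectors

**Lasso.** L1-penalized logistic regression over a data-driven geometric
penalty path from λ_max (the smallest penalty with all coefficients zero,
max|Xᵀ(y−ȳ)|/n) down to λ_max · r with r = 0.01 when p > n, 1e-4
otherwise. The penalty is chosen at the minimum mean 10-fold
cross-validated deviance (stratified, shuffled, seeded folds) and the model
refitted on the full sample. Predictors are deliberately **not
standardized**: all binary predictors share the 0/1 scale, and
standardizing would up-weight rare columns; this choice changes selection
and is therefore stated prominently. The optimizer is liblinear with the
intercept attached at scaling 100 so its effective penalization is
negligible; a `fixed_lambda` mode skips CV for oracle comparisons (at
λ → 0 the fit reproduces the unpenalized MLE, tested against an IRLS fit).

**Univariate screening.** Each candidate is tested with a Wald test on the
slope of a univariable logistic model; "significant" is p < α = 0.05. For
binary predictors the univariable MLE has the 2×2-table closed form
(log odds ratio, SE = √(Σ 1/cell)); an empty cell yields p = 1 (the Wald
statistic degenerates — such a variable cannot be declared significant).
The closed form is tested against an iterative GLM fit. Survivors enter one
multivariable logistic fit. Separation and non-convergence are common with
sparse binary columns at n = 250; when the plain fit fails (non-convergence,
non-finite or implausibly large coefficients), a ridge-stabilized fit with a
tiny total L2 penalty (1e-6) replaces it and the result is flagged. An empty
selection publishes the intercept-only model (logit of the event rate).

A selection's published model is applied "unchanged" to new data by
evaluating all its terms; a selected variable that is degenerate in the new
sample simply contributes its constant observed value.

## Strategies and the probability forest

The candidate sets M1–M5 and their fallback ladder are resolved per
replication against the current sample's non-degenerate columns, preserving
column order so that identical sets yield bitwise-identical forests.
M5's winner is the preceding model with the higher AUROC on the current
sample; ties go to the Lasso model (the methodologically stronger preceding
study). If degeneracy filtering empties a resolved set, the fallback ladder
re-fires (other model, then all variables).

The probability forest grows unpruned trees on bootstrap resamples of size
n with the Gini split criterion and random mtry-sized candidate subsets;
predictions are ensemble averages of terminal-node class fractions, the
consistent probability-machine estimator for binary outcomes. Defaults:
500 trees (100 in the compact profile), mtry = ⌊√p⌋, minimal node size
eligible for splitting = 10 observations (a fractional value, e.g. 0.1 for
the 10%-of-n variant, is accepted). All other tree parameters are the
implementation defaults.

## Performance measures

Computed on the validation set: AUROC (rank-sum formulation, ties count ½ —
ties are guaranteed with forest probabilities on sparse data); Brier score
(mean squared error); cross-entropy as the **sum** of per-observation
negative Bernoulli log-likelihoods plus the maximum single contribution;
calibration slope as the slope of a logistic regression (with intercept) of
the outcome on the predicted log odds. One clipping constant (1e-6) is
shared by every logarithm/logit. A degenerate slope fit (constant log odds,
non-convergence) returns NaN and is excluded from means/SDs with an
exclusion count in the aggregate output; the MSE of log slopes additionally
excludes non-positive slopes. Calibration plots group predictions by
deciles (merging tied groups with a warning) and overlay the recalibration
curve.

## Study orchestration

Per replication, four mutually disjoint samples are drawn without
replacement — two preceding studies and the current study of the scenario's
sample size, plus the validation set — so no information leaks between
"independent studies". Draws leaving any training sample with a single
outcome class are retried with a fresh permutation up to 5 times, then the
replication is rejected with a logged reason (at event rate 0.56 and
n ≥ 250 this is astronomically rare). Every stochastic component (sampling,
Lasso CV folds, forest, Bernoulli draws) derives its seed from
(base seed, sample size, arm, replication, component tag) via hashed seed
sequences, so results are independent of worker scheduling; a failed method
yields a flagged NaN record rather than a crashed replication. Aggregation
produces per-(scenario, method) means and SDs, the MSE of log slopes, the
mean maximum cross-entropy contribution, and descriptive selection counts
(mean/min/max of non-degenerate, Lasso, univariate, union and intersection
counts).

## Problem sizes

Three profiles ship with the package, all the same code path:

* `default_config` — the full-scale design: 200k population, p = 1150,
  5 sample sizes × 2 arms, 1000 replications, validation 10,000.
* `desk_config` — 20k population, p = 400, 4 sample sizes, 100
  replications, validation 2000.
* `compact_config` — the profile used by the shipped end-to-end checks and
  `scripts/acceptance.py`: 12k population, p = 400 (+2 numeric),
  n = 250 only, 200 replications per arm, validation 1000, 100-tree
  forests, 12-point penalty path. Chosen as the smallest design in which
  the directional phenomena of interest (naive-forest underfit under strong
  predictability, naive-forest optimality under weak) are stable across
  replications on a single CPU.

The directional checks are deliberately qualitative: mean calibration slope
of M1 above 1 and above M4's under strong predictability at n = 250, and M1
attaining the lowest mean cross-entropy among M1–M5 under weak
predictability. Absolute table values of the original registry population
are properties of restricted data and are not reproduction targets.

## Known limitations

* Independent predictors (no correlation control is exposed; with
  correlated predictors the Lasso/union contrast would likely shift).
* The liblinear L1 path is not glmnet's coordinate descent; selected sets
  can differ near ties on the path, though the deviance-minimizing rule is
  the same.
* The univariable Wald test is one of several defensible screening tests
  (score and likelihood-ratio variants are not implemented).
* Reinforcement strength is fixed by the constant c; it is not tuned to hit
  any particular AUROC.
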