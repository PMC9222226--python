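# plasmoderf

**Does a random forest benefit from variable preselection done by earlier
studies?** Clinical prediction modelers routinely face registries with
thousands of candidate predictors — most of them sparse binary indicators of
prescriptions or diagnoses — and a literature of "preceding studies" that
selected variables with Lasso regression or univariate significance
screening. `plasmoderf` is a plasmode-style simulation pipeline for
quantifying whether feeding those published variable sets into a probability
random forest improves its out-of-sample discrimination and, in particular,
its **calibration**.

The package is aimed at biostatisticians and methods researchers studying
prediction-model development under realistic predictor sparsity.

## The simulation in brief

A synthetic "population" emulates a pharmacoepidemiologic registry extract:
`p` independent binary predictors whose prevalences follow a heavy
left-skewed law pinned to the quartiles (1/3371, 1/1530, 1/112), two
standardized numeric covariates, and a weakly predictable binary outcome
with event rate 0.558 drawn from a sparse additive logistic model

> Pr(Y = 1 | x) = expit(β₀ + Σⱼ βⱼ xⱼ),

with β₀ solved so the event rate hits its target. A second, strongly
predictable outcome `Y_strong` is created by *reinforcement*: 4-fold
cross-fitted probability-forest predictions are transformed to log odds,
multiplied by a constant c = 3.5, back-transformed, and used as Bernoulli
parameters for a fresh outcome draw.

Each replication of a scenario (sample size n × predictability arm) draws
four disjoint samples: two preceding studies, a current study, and a
validation set. Preceding study 1 runs cross-validated Lasso logistic
regression (penalty at minimum 10-fold CV deviance); preceding study 2 keeps
predictors significant at α = 0.05 in univariable logistic models and refits
them jointly. The current study trains a probability random forest on one of
five candidate sets:

| Method | Candidate variables |
|--------|--------------------|
| M1 | all non-degenerate variables (naive forest) |
| M2 | Lasso selection |
| M3 | intersection of Lasso and univariate selection |
| M4 | union of Lasso and univariate selection |
| M5 | selection of the better-discriminating preceding model |

Empty selections trigger fallback rules (all variables / the union / the
other model). A Lasso model fitted on the current sample is the parametric
comparator. Validation-set performance is measured by AUROC, Brier score,
calibration slope (of a logistic recalibration of the outcome on the
predicted log odds; ideal 1) and summed cross-entropy with its maximum
per-observation contribution; replications are summarized by means, SDs and
the mean squared log calibration slope.

## Worked example

```python
from plasmoderf import compact_config, run_study
from plasmoderf.runner import build_population

cfg = compact_config(seed=1, n_replications=20)
pop, info = build_population(cfg)
print(f"weak event rate {info['event_rate_weak']:.3f}, "
      f"strong {info['event_rate_strong']:.3f}, "
      f"cross-fitted forest AUROC {info['reinforcement_oof_auroc']:.3f}")

result = run_study(cfg, pop=pop)
cols = ["mean_auroc", "mean_cal_slope", "mean_cross_entropy"]
print(result.aggregates.set_index(["scenario_id", "method"])[cols].round(3))
```

prints (seed 1, 20 replications per arm at n = 250, validation sets of 1000):

```
weak event rate 0.554, strong 0.623, cross-fitted forest AUROC 0.674

                     mean_auroc  mean_cal_slope  mean_cross_entropy
scenario_id method
strong_n250 LASSO         0.763           1.006             539.435
            M1            0.751           1.196             560.640
            M2            0.737           0.882             573.615
            M3            0.690           0.833             591.957
            M4            0.739           0.906             567.215
            M5            0.733           0.836             577.637
weak_n250   LASSO         0.616           0.919             660.885
            M1            0.614           0.663             673.140
            M2            0.604           0.483             699.118
            M3            0.592           0.872             679.452
            M4            0.610           0.461             697.311
            M5            0.606           0.460             699.424
```

Read: under **strong** predictability the naive forest (M1) discriminates
well but is the worst calibrated — its mean slope 1.20 exceeds 1
(predictions squeezed toward the event rate by the many noise candidates),
while preselection (M2/M4) pulls the slope back toward 1. Under **weak**
predictability preselection has nothing reliable to offer: the naive forest
attains the lowest mean cross-entropy, and the preceding selections (slopes
far below 1) mostly inject noise.

There is also a CLI:

```bash
plasmoderf make-population --profile compact --seed 1 --out pop.csv
plasmoderf simulate --profile compact --reps 50 --out results/
plasmoderf report --records results/records.csv --out results/tables/
```

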