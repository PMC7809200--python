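# efspan

Scoring and curvilinear age-trajectory modelling for a lifespan
executive-function (EF) battery.

Cross-sectional studies of executive function across the lifespan (here,
ages 10–86) measure four components — inhibitory control (Stroop
colour-word), working memory (operation span), cognitive flexibility
(alternating-runs task switching) and planning (Tower of Hanoi) — and ask
when each ability peaks and when it declines.  `efspan` implements that
analysis as a tested, reusable pipeline: trial-level scoring with the
standard filtering rules, orthogonal-polynomial regression of each score on
age with IQ and SES covariates, multi-index model selection, trajectory
equality testing, and raw plus age-adjusted correlations.  A bundled
synthetic-cohort simulator reproduces the task designs so the whole
pipeline runs end to end with no external data.

## The model

For each EF score *y* and age *a*, the package fits

```
z(y) ~ β₁ P₁(a) + β₂ P₂(a) + β₃ P₃(a) + β_IQ z(IQ) + β_SES z(SES)
```

where P₁…P₃ are orthonormal polynomial scores of age anchored to the
analysis sample (zero-sum, unit-norm, mutually orthogonal columns), and all
variables are z-scored so the coefficients are standardized betas.  Models
of degree 1, 2 and 3 are compared hierarchically (1 vs 2, winner vs 3);
each comparison is decided by a majority of four goodness-of-fit indices —
nested-F p < .05, likelihood-ratio p < .05, lower AIC, lower BIC — with
ties going to the simpler model.  The Gaussian log-likelihood is
−n/2·(ln 2π + ln(RSS/n) + 1) and the information criteria count the
residual variance as a parameter (k = coefficients + 1), so
`BIC − AIC = k (ln n − 2)`.

Scoring follows the field's conventions: RT measures use accurate responses
above 200 ms and within 2.5 SD of the participant's overall task mean,
natural-log-transformed per trial, and are reverse-scored so higher always
means better.  The Stroop congruency effect is −(mean log RT incongruent −
congruent); the switch cost is −(switch − non-switch) and the mixing cost
−(non-switch − single-task) on the log scale; operation span yields
absolute (sum of perfectly recalled set sizes) and partial (letters in
correct serial position) scores; Tower of Hanoi is the sum of step counts
of trials solved in exactly the minimum number of moves (maximum 104 over
the 16-trial design).

## Worked example

Simulate a 350-participant cohort, run the full pipeline, and inspect the
selected trajectories:

```
$ efspan run-all --mode simulate --seed 1 --n 350 --out demo
selected degrees: {'stroop_effect': 2, 'ospan_partial': 2, 'switch_cost': 1,
                   'mixing_cost': 1, 'toh_score': 3}

$ efspan model --scores demo/scores.csv
stroop_effect: degree 2 (n=335, R^2=0.172, AIC=898.55, BIC=921.43)
ospan_partial: degree 2 (n=321, R^2=0.110, AIC=884.61, BIC=907.23)
switch_cost: degree 1 (n=318, R^2=0.043, AIC=897.38, BIC=916.19)
mixing_cost: degree 1 (n=318, R^2=0.125, AIC=868.82, BIC=887.63)
toh_score: degree 3 (n=339, R^2=0.161, AIC=915.59, BIC=942.37)
```

Inhibition and working memory are selected as quadratic in age (rise into
young adulthood, then decline), the two task-switching costs as linear with
opposite signs (switch costs shrink with age while mixing costs grow), and
planning as cubic (rise, fall, small late upturn) — the pattern the
simulator was configured to produce.  `n` is the number of model-wise
complete participants per measure (each task has its own missingness).  The
run directory holds `scores.csv` (one row per participant),
`table3.csv` (descriptives by the five age bands 10–17 / 18–29 / 30–49 /
50–64 / 65–86), `table4.csv` (all fit indices and the best-model flag),
`table5.csv` (correlations with age-adjusted partial correlations in
parentheses, e.g. `0.18** (0.12*)`), `trajectory_comparisons.csv`,
`fits.json` and `run.log`.

`analyze` mode runs the identical pipeline on user-supplied CSV trial
tables (see `efspan.io.REQUIRED_COLUMNS` for the schemas); `--no-log-transform`
reproduces the untransformed-RT variant of the analysis and
`--no-covariates` the age-only refits.

The same functionality is available as a library, organised as
scikit-learn-style estimators:

```python
from efspan import CohortSpec, simulate_cohort, score_participants
from efspan import TrajectoryDegreeSelector

tables = simulate_cohort(CohortSpec(master_seed=1))
scores = score_participants(tables["participants"], stroop=tables["stroop"],
                            switching=tables["switching"],
                            ospan=tables["ospan"], toh=tables["toh"])
sub = scores[["age_years", "ospan_partial", "fsiq", "ses_index"]].dropna()
sel = TrajectoryDegreeSelector().fit(sub[["age_years", "fsiq", "ses_index"]],
                                     sub["ospan_partial"])
sel.best_degree_       # 2
sel.best_model_.result_.coefficients  # standardized betas
```

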