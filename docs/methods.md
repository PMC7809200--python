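# Methods

## Scope and model

`efspan` models cross-sectional age-related differences in four executive
functions from trial-level task records.  Each derived score is regressed
on orthonormal polynomial scores of age (degree 1–3) with full-scale IQ and
an SES index as covariates; the polynomial degree is chosen by a majority
of goodness-of-fit indices; measures sharing a degree can be tested for
trajectory equality; and relationships among measures are summarised as
Pearson correlations with age-adjusted partial correlations.  The design is
strictly cross-sectional: the models describe age *differences*, not
within-person change, and no longitudinal, mixed-effects or spline
machinery is included.

## Trial scoring

**RT filtering.**  For each participant and task, eligible trials are
accurate, not timed out (task switching times out at 5000 ms; timeouts are
treated as inaccurate), and slower than 200 ms.  The trimming mean and SD
are computed once over all eligible trials of that task, pooled across
conditions, on the raw-millisecond scale ("overall trial mean" is read as
task-level; no iterative re-trimming).  Trials beyond 2.5 SD are dropped.
A `trim_on_log` flag switches the window to the log scale, since the
original convention is not documented.  Single-task and mixed-task
switching trials are trimmed as separate tasks.  With fewer than two
eligible trials the SD is undefined; the eligible trials are kept untrimmed
and a warning is emitted.

**Transform and reverse scoring.**  Trimming precedes the log transform;
the natural log is used (typical log-RT magnitudes of 6.3–7.2 correspond to
600–1400 ms).  The Stroop congruency effect and both switching costs are
negated so that higher scores mean better performance on every measure.
A `log_transform=False` path supports the untransformed sensitivity
analysis.

**Block-initial mixed trials.**  In the alternating-runs design the
switch/non-switch status of a trial is defined by the transition from the
previous trial; block-initial trials have none and are excluded from both
mixed-task condition means.

**Operation span.**  Recall matching is strict positional equality.  A set
is perfect only when the recalled sequence equals the presented sequence
exactly, with no extra or missing entries; blank markers occupy a position
and never match.  The partial score counts correct-position letters, so
partial ≥ absolute always.

**Tower of Hanoi.**  The absolute score sums the required step counts of
trials solved perfectly (no errors, exactly the minimum number of moves);
the 16-trial design (two trials at each of 3–10 steps) caps it at 104.

**Reliability.**  `reliability()` is a generic participants × items routine
(listwise deletion, ≥ 2 items, ≥ 3 complete rows) reporting raw Cronbach's
alpha from the covariance decomposition, the mean pairwise inter-item
correlation, and optionally the standardized alpha
k·r̄/(1 + (k−1)·r̄).  Which trials constitute "items" for the RT tasks is
not standardised; the pipeline applies the routine where the item basis is
unambiguous (the 16 per-trial Tower of Hanoi scores), and any other item
convention is the caller's documented choice.

**Missingness.**  Any missing SES component makes the index missing; any
absent task makes that score missing.  Analyses are model-wise complete per
measure (trajectory models) or pairwise complete (correlations), so each
measure has its own n.

## Age-trajectory models

**Basis.**  Orthonormal polynomial columns are built by the Forsythe
three-term recurrence on the analysis sample's ages (the same convention as
R's `poly()`): each column sums to zero, has unit norm, and is orthogonal
to the others to 1e-10.  The recurrence constants are stored so fitted
curves can be evaluated at arbitrary ages; evaluation outside the anchor
range warns about extrapolation.

**Fitting.**  Ordinary least squares on
[intercept | P₁..P_degree | IQ | SES], with the outcome and every predictor
column z-scored (ddof = 1) so coefficients are standardized betas.  R² and
the overall F test are scale-invariant; RSS, log-likelihood, AIC and BIC
are reported on the standardized outcome scale.  The log-likelihood is the
profiled Gaussian form −n/2·(ln 2π + ln(RSS/n) + 1), and
k = (number of coefficients including the intercept) + 1 counts the
residual variance, so AIC = 2k − 2LL and BIC = k·ln n − 2LL and
BIC − AIC = k(ln n − 2) exactly on every fit.  A degree-1 model with two
covariates therefore has k = 5, which at n = 340 yields the 19.14 AIC–BIC
spread that identifies this convention.  Covariate-removed refits use the
identical machinery with an empty covariate block.  Zero outcome variance
is a degenerate case: the model fits a flat curve with undefined likelihood
(NaN indices) and warns.  Rank-deficient designs raise an error naming the
collinear columns.

**Nested comparison.**  F-change = ((RSS_s − RSS_c)/Δk) / (RSS_c/(n −
k_c)), with Δk the coefficient-count difference and k_c the complex model's
coefficient count; the likelihood-ratio χ² is 2(LL_c − LL_s) on Δk df.

**Selection.**  Hierarchical majority vote: degree 1 vs 2, then the winner
vs 3.  Four indices vote per comparison — nested-F p < .05, LR p < .05,
lower AIC, lower BIC — and the complex model needs at least 3 of 4; 2–2
ties go to the simpler model (parsimony).  RSS is reported but never votes,
since it always favours the complex model.  The vote record and an audit
trail are retained so the chosen degree is reproducible from the votes.

## Trajectory equality

Both measures are z-scored within their own samples, stacked, and the
orthonormal basis is rebuilt on the stacked age vector.  The shared-slope
model is tested against one adding a group × age-term interaction for every
polynomial term (nested F, df1 = degree).  A group main effect is *not*
added: after per-measure z-scoring both group means are exactly zero, so
the main effect contributes no sum of squares while inflating df1; in null
simulations including it depressed the type-I error to ~0.02, while the
interactions-only test rejects at the nominal ~0.05.  Measures whose best
models differ in degree are refused (their trajectories already differ in
form).  Participants contributing both measures appear in both groups and
observations are treated as independent — a documented limitation of the
stacked-ANOVA approach, which ignores within-person correlation.

## Correlations

Raw correlations are Pearson on pairwise-complete observations (listwise
deletion would discard more data given per-task missingness).  Partial
correlations correlate the residuals of each measure after regressing it on
its own best-fitting age polynomial (intercept included); with a single
linear age term this equals the textbook first-order partial correlation to
1e-10.  Partial p-values use df = n − 2 − (number of age terms partialled);
when the two measures were adjusted with different degrees the larger is
used (a conservative, documented choice).  Correlations are computed on the
reverse-scored (higher-is-better) scales.  Cells with fewer than 3
pairwise-complete observations are missing.

## Synthetic cohort

The generator reproduces the battery's printed designs exactly: Stroop
50/50/50 experimental trials (plus 20 practice) under the
no-repeated-word/colour adjacency constraints, built by constrained
sequential sampling with whole-sequence retry; task switching as two
32-trial single-task blocks plus four 32-trial mixed blocks with clockwise
quadrant rotation from upper-left, predictable switch/non-switch
alternation and no repeated coloured shape; operation span as three trials
at each span 2–7 from the 12-letter pool; Tower of Hanoi as three practice
(1, 2, 2 steps) plus 16 experimental problems, two at each of 3–10 steps,
with initial/target states sampled uniformly among state pairs at the
required shortest-path distance (verified by BFS over the 81-state
legal-move graph) excluding practice targets.  How the original task chose
its configurations is unknown; uniform sampling at fixed distance is a
declared choice.

Performance generation: each participant draws an age band (62/60/76/74/78
weights over 10–17/18–29/30–49/50–64/65–86, uniform within band; a uniform
option exists for power studies), band-specific full-scale IQ, and three
SES component codes.  Latent abilities per EF follow polynomial
trajectories on age rescaled to [0, 1] (so coefficients are portable across
age ranges) plus Gaussian person-level noise and an IQ loading.  RTs are
log-normal: log RT = baseline(age) + condition shift − ability + trial
noise, with a linear monotone general-slowing baseline calibrated so
single-task log-RT band means fall in 6.27–6.59.  Operation-span recall is
per-letter Bernoulli with a logistic link in working-memory ability, span
and a per-trial disturbance (which induces the within-trial dependence that
makes perfect sets realistically common); Tower of Hanoi success is
Bernoulli with a logistic link in planning ability and step count.
Accuracy is a constant high per-trial rate minus a small condition penalty
(the analysis uses RT only, so accuracy merely feeds the filter); the maths
task is summarised as a per-trial accuracy count floored at the 85%
criterion; the five-errors-in-a-row early termination is not modelled.

Default trajectory shapes and amplitudes encode the emulated study's
conditions — quadratic inhibition and working memory peaking near age
30–32, opposite-signed linear switch and mixing trends, cubic planning with
a peak near 33 and trough near 75 — with amplitudes and noise calibrated
once against the printed condition means, cost magnitudes, standardized
betas and R² range (0.04–0.28), then frozen.  Per-task missingness defaults
to the observed 3/347, 16/334, 17/333, 2/348 pattern.  All randomness flows
from one master seed through spawned per-participant substreams, so a
cohort is bit-identical across runs.

What the generator does **not** emulate: within-person correlation between
abilities beyond the shared IQ loading, non-monotone general slowing
(adolescents in real data are slower than young adults; the default
baseline is linear in age), sequential effects within trial streams
(fatigue, learning, post-error slowing), non-normal ability distributions,
and informative missingness.  Passing recovery tests therefore show that
the pipeline correctly recovers the generative structure it targets, not
that real data satisfy that structure.

## Problem sizes and numerical choices

Simulation-based tests use: 500 replicates (n = 350 per group) for the
type-I calibration of the equality test; 100 replicates per scenario
(n = 350, score-level generation from the default trajectories) for
degree-recovery, with an 80% recovery threshold fixed in the suite; one
full trial-level cohort (n = 350) for the end-to-end qualitative pattern;
200 replicates for the opposite-trajectory power check.  Orthonormality is
asserted at 1e-10, oracle agreement for OLS/residualization at 1e-8–1e-10,
and hand-arithmetic scoring examples at float tolerance (stored RTs are
rounded to 0.1 ms, so degenerate zero-noise scores are exact to ~1e-3).
Shortest-path distances are cross-checked against an exhaustive
adjacency-matrix-power oracle.  Ties in the selection vote go to the
simpler model; BFS over the 81-state graph is exact, so no tolerance is
involved in problem generation.

## Known limitations

Standardized betas are computed by z-scoring all variables, one of several
conventions; analysis n per measure depends on the missingness pattern, so
printed coefficients are comparable only within a fitted sample.  The
equality test inherits the independence assumption noted above.  The
reliability item basis for RT tasks is not standardised.  SES component
coding distributions are plausible rather than estimated from data.
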