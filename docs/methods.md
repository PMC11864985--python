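# Methods

## Survival model

The core model is a proportional-hazards regression whose log-relative
hazard is a one-hidden-layer neural network: h(t|x) = h0(t)·exp(f(x)) with
f(x) = W2·ρ(W1ᵀx + b1) + b2, ρ the rectifier, and hidden width fixed at 10×
the input width. The baseline hazard h0 is never estimated; fitting
maximizes the Cox partial likelihood over risk sets, with Breslow's
approximation for tied event times, computed per mini-batch after sorting by
time. The loss and its gradient are normalized by the number of events in
the batch so the learning rate is insensitive to batch size.

Training schedule: Adam (default moments), staged learning rates
1e-2 → 1e-3 → 1e-4, each stage at most 50 epochs with early stopping
(patience 10) on the validation partial likelihood; the weights returned are
those of the best validation epoch seen so far, and each stage restarts from
them. Dropout rate 0.5 is applied during training to the hidden activations
and, separately, to the inputs. Input dropout masks *variables*, not
columns: the two slots of a feature-expanded pair are dropped together,
because a half-dropped pair (x, 0) would be indistinguishable from a partly
observed value and collides with the (0, 0) missingness code. Input and
hidden masks are independent. Weights are initialized Kaiming-uniform
(U(−1/√fan_in, 1/√fan_in), the default of the torch Linear layers used by
DeepSurv-style implementations); larger He-normal initializations train
unstably at learning rate 0.01.

Evaluation is five-fold cross-validation stratified on cancer-entity labels
(entities with fewer than 5 patients are merged into an "other" stratum):
per fold, 80% train / 10% validation / 10% test. Harrell's concordance is
reported pan-cohort per fold and per entity, discarding per-entity values
from test subsets with fewer than 10 patients or fewer than 5 events.
Concordance uses the standard comparable-pair definition under right
censoring with risk ties counted 0.5 (computed via lifelines; an exhaustive
pair-enumeration oracle cross-checks it in the tests).

## Relevance propagation

The predicted risk is redistributed input-ward with the generalized
LRP-gamma rule (γ ≥ 0, default 0.01). Each neuron's relevance splits over
its inputs in proportion to γ-reweighted contributions a_j±(w_jk + γ w_jk±),
with the branch chosen by the sign of the receiving activation; the bias
enters every denominator as a unit neuron and its share accumulates into a
per-patient `bias_absorbed` term, reported separately rather than
redistributed. No epsilon stabilizer is added to denominators; a zero
denominator receiving nonzero relevance routes that relevance to
`bias_absorbed` and logs a warning. Consequences that the tests verify
exactly: Σ RC + bias_absorbed equals the predicted risk to machine
precision; a feature-expanded marker that is missing — input (0, 0) —
receives exactly zero RC; on effectively linear, sign-homogeneous networks
the attribution reduces to RC_j = w_j x_j for any γ.

Propagation starts at the raw scalar risk, including when it is negative
(handled by the a_k < 0 branch). Rows are explained independently, so cohort
explanation is order-independent and parallelizable.

## Preprocessing

Continuous markers: a single-pass outlier rule removes values more than 3
sample standard deviations from the mean (both computed once, over the raw
non-missing entries); removed values become missing — the patient stays.
Survivors are standardized with the post-removal mean and sample sd; a
constant marker is centered and divided by 1 (flagged). Ordinal scores pass
through as integer levels, binary indicators as {0, 1}. Standardization is
global by default (computed before any splitting); the fitted
`Preprocessor` can be reused to transform new data with stored parameters
for leakage-free workflows.

Feature expansion applies only to markers with at least one missing value:
x → (x, 1−x), missing → (0, 0). Markers without missingness keep one column,
so the expansion decision is part of the fitted layout and is reused on new
data.

## Synthetic cohorts

The generator emulates a multimodal registry cohort at desk scale. Defaults:
2000 patients; 12 continuous (lab), 4 ordinal 0–4 (clinical score) and 4
binary markers (alternately a testable biomarker modality and an excluded
comorbidity-code modality); 4 cancer entities drawn uniformly, shifting
continuous marker means by N(0, 0.3) before marginal re-standardization;
45% censoring (the order seen in large treatment-outcome registries); 20%
missingness per marker, missing-completely-at-random by default with an
optional value-dependent (MAR) mode. Event times follow
h(t|x) = h0(t)·exp(βᵀx + Σ γ_ij x_i x_j) with a Weibull baseline (shape 1.3,
scale 365 days) sampled by inverse transform; censoring times are
independent exponentials whose rate is bisected so the realized censored
fraction lands within ±0.005 of the target. Missingness is applied after
outcomes. The default β is evenly spaced in [−0.8, 0.8] across markers —
a realistic mix of protective, neutral and adverse effects on the
standardized scale. TTNT endpoints reuse the same linear predictor on a
halved baseline scale, preserving the expected earlier-event ordering; the
joint OS/TTNT dependence is a modelling convenience, not a data-derived
claim. Per-cell measurement ages (uniform 0–3 years) support the
recency filter of the explainable KM report.

`true_attribution` exposes the ground-truth additive decomposition of the
log-hazard (β_j x_j plus half of every product term the marker participates
in, optionally plus Gaussian scatter): it is the independent oracle for
attribution-consuming stages.

What the generator does **not** emulate: informative censoring, correlated
markers within modalities, laboratory reference ranges, code semantics, or
measurement-time dynamics. Passing tests therefore demonstrate correctness
of the machinery and recoverability under the stated generating model, not
clinical performance.

## Marker statistics

Marker importance: MI = Σ|RC| / n_present per marker; for subcohorts RCs are
first centered by the full-cohort per-marker mean, so subcohort MI measures
deviation from cohort-typical attribution. The cumulative-importance curve
ranks markers by total absolute relevance mass (Σ|RC|, not per-patient MI)
and reports the minimal top-k reaching a mass fraction; raw (uncentered)
relevance is used. RC slopes are ordinary least squares of RC on the
standardized marker value; univariate Cox log hazard ratios are fitted by
lifelines on the same standardized values, and fits that do not converge or
fall below their null model's partial likelihood are excluded. Note that
univariate hazard ratios are attenuated relative to the multivariable
generating coefficients (omitted-covariate non-collapsibility); the
slope-vs-log-HR comparison is therefore a correlation across markers, not an
equality.

## Interaction screen

For each ordered pair (primary, secondary), patients are conditioned on the
secondary marker being high (top decile, boundary ties on the extreme side)
or low (bottom decile); ordinal/binary secondaries grow extreme levels until
each side holds ≥ 10% of non-missing samples, discarding the pair if the
sides would overlap. Pairs observed in fewer than 100 samples are discarded.
Within the high∪low subset, a mixed linear model with a random intercept
over the two condition classes and a class-specific slope of the primary
value is compared against a common-slope baseline by a 1-df likelihood-ratio
test; Holm's step-down correction runs over all pairs actually tested.
Markers of the medication / diagnosis-code / procedure-code / cancer-type
modalities are excluded (their levels are too unbalanced to condition on).
A two-level random intercept often sits on its variance boundary; when the
mixed fit degenerates, both models are refitted by OLS (the boundary case)
before the test. The proportional-hazards validation refits the
class-specific effect of the primary marker against survival with a
class-stratified Cox model (the stratified baseline hazard playing the role
of the per-class intercept) and compares the sign of the effect difference
with the RC-based slope difference; fits below their common-slope baseline
are discarded.

**Known limitation.** The screen treats RCs as noisy observations. LRP
attributions of a trained network are, at fixed inputs, *deterministic*; on
small synthetic cohorts with few markers their residual scatter around the
class-specific line can be of order 1e-2, and the likelihood-ratio test then
resolves the network's own approximation micro-structure — slope differences
of a few hundredths reach p ≈ 0 on hundreds of patients. This is faithful
reporting of what the network learned, but it means Holm-significance counts
on near-noise-free attributions reflect network wiggle rather than
generating-model interactions. The screen's operating characteristics
(type-I error, family-wise error, power, sign recovery) are therefore
validated on ground-truth attributions with realistic scatter (sd 1.0, about
a sixth of the systematic RC range, comparable to published attribution
clouds); the trained-network path remains fully supported for data analysis.

## Benchmarks

The parsimonious baseline selects markers with an elastic-net-penalized Cox
path (mixing 0.9 toward the lasso, scikit-survival), bisecting the penalty
(≤ 50 iterations, geometric midpoint) until exactly k = 10 coefficients are
active; if the active-set path jumps over k, the nearest achievable set of
size ≤ k is used and logged. An unpenalized linear Cox model is then
refitted on the active set (missing values entering as 0, the standardized
mean). Bare clinical scores are benchmarked as sole risk predictors by their
test-split concordance among patients with the score present; a constant
score scores 0.5 by the tie convention. Paired contenders are compared with
a two-sided Wilcoxon signed-rank test over per-split concordances, zeros
dropped, exact null for ≤ 25 pairs and a continuity-corrected normal
approximation above.

## Reports

Kaplan–Meier curves use the product-limit estimator (lifelines); the median
is the first time with S(t) ≤ 0.5, reported as beyond follow-up when never
reached. Risk groups are near-equal-size quantile strata of predicted risk
(ties broken by stable patient order). The explainable KM report orders
deceased patients by observed survival (the pseudo-timeline) and smooths
each marker's |RC| with a Gaussian kernel over this ordering (bandwidth 10%
of the deceased count, configurable), min-max scaling each line to [0, 1]
(a numerically constant profile maps to 0); markers observed in fewer than
40 deceased patients, or only through measurements older than the 2-year
recency window (judged against per-cell measurement ages when available),
are dropped. The clinician's guide lists a patient's present markers sorted
by RC and reports the KM median survival of the 100 patients nearest in
predicted risk (absolute difference, ties by patient order, the whole cohort
when smaller). All reports are emitted as data tables first; figures render
those tables.

## Problem sizes and determinism

The test suite and the acceptance script run on cohorts of 400–2000 patients
with 8–50 markers, five CV folds, 20 seeds for the screen's power check and
200 reduced-scale replicates for its family-wise error — sizes chosen so the
full validation runs on a single CPU in minutes while every check retains
its statistical meaning. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; two runs of the full pipeline with the
same configuration and seed produce byte-identical CSV artifacts.
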