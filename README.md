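# aidmark

Explainable neural survival modelling for multimodal tabular cancer cohorts.

`aidmark` trains a proportional-hazards neural network on a patients × markers
table with right-censored outcomes, then decomposes every patient's predicted
risk into per-marker **risk contributions (RC)** with layer-wise relevance
propagation (LRP). The pair *(marker value, RC)* — an *AI-derived (AID)
marker* — lets clinicians and analysts see not only *that* a patient is high
risk but *which* laboratory values, clinical scores and comorbidity flags
drive that assessment, patient by patient. On top of the attributions the
package derives cohort-level statistics: marker importance rankings,
linearized RC slopes checked against classical Cox hazard ratios, a
decile-conditioned screen for pairwise marker interactions, a parsimonious
penalized-Cox baseline, and survival reports (risk-group and explainable
Kaplan–Meier curves, per-patient clinician's guides).

Because real multimodal clinical registries are access-restricted, the
package ships a first-class synthetic-cohort generator with a known
ground-truth hazard, so every stage of the pipeline is testable against the
generating truth.

## The model

Patient covariates x (continuous labs standardized, ordinal scores as integer
levels, binary indicators one-hot, missing values encoded by feature
expansion x → (x, 1−x) with missing = (0, 0)) enter a one-hidden-layer
network with hidden width 10× the input and rectifier activation. The scalar
output f(x) is the log-relative hazard in a Cox model,

    h(t | x) = h0(t) · exp(f(x)),

trained by minimizing the negative Cox partial log-likelihood (Breslow ties)
with Adam, staged learning rates 1e-2 → 1e-3 → 1e-4 (up to 50 epochs per
stage, early stopping on validation partial likelihood), dropout 0.5 on the
hidden layer and on whole input variables. Evaluation uses five-fold,
cancer-entity-balanced cross-validation with Harrell's concordance index.

The predicted risk R = f(x) is redistributed onto the inputs with the
generalized LRP-gamma rule (γ = 0.01 by default): for consecutive layers with
activations a_j, a_k and weights w_jk (bias as a unit neuron a_0 = 1),

    R_j = Σ_k [a_j⁺(w_jk + γ w_jk⁺) + a_j⁻(w_jk + γ w_jk⁻)]
            / [Σ_{0,j} a_j⁺(w_jk + γ w_jk⁺) + a_j⁻(w_jk + γ w_jk⁻)] · 1{a_k>0} · R_k
        + (same with γ-terms swapped) · 1{a_k<0} · R_k,

with (.)⁺ = max(0, ·) and (.)⁻ = min(0, ·). Relevance is conserved exactly:
Σ_j RC_j + bias_absorbed = f(x). The RC of a feature-expanded marker is the
sum over its (x, 1−x) pair, so a missing marker receives exactly zero.

## Worked example

```python
from aidmark import GeneratorConfig, generate_cohort, Preprocessor, CoxRiskNet, TrainConfig
from aidmark import aidstats
from aidmark.preprocess import collapse_to_encoded
from aidmark.report import clinician_guide

cfg = GeneratorConfig(n_patients=2000, censor_rate=0.45, seed=7)
cohort, outcome, truth = generate_cohort(cfg)

pp = Preprocessor()
X = pp.fit_transform(cohort)
results = CoxRiskNet(X, outcome).fit(TrainConfig(seed=7))
print(results.summary())
```

```
Cox partial-likelihood neural network
==============================================
patients:            2000
events:              1100 (55.0%)
endpoint:            OS
input width:         40
hidden width:        400
lr stages:           [0.01, 0.001, 0.0001]
epochs per stage:    [17, 11, 11]
best val loss:       4.26009
train concordance:   0.7957
```

The training concordance of 0.80 says the network orders patient survival
well above chance (0.5). Explaining the cohort and ranking markers:

```python
rc = results.explain(gamma=0.01)
mi = aidstats.marker_importance(rc, collapse_to_encoded(X).isna())
print(mi.ranked().head(5).round(3))

table = aidstats.slope_table(collapse_to_encoded(X), rc, outcome=outcome)
r, p = aidstats.slope_hr_agreement(table["slope"], table["log_hr"])
print(f"slope vs log-HR agreement: r = {r:.3f} (p = {p:.2g})")
```

```
            mi  n_present  total_abs_rc
lab_1    0.175       1598       279.020
lab_0    0.168       1602       268.604
lab_3    0.133       1598       213.320
lab_2    0.127       1601       203.504
score_3  0.107       1596       170.180

slope vs log-HR agreement: r = 0.981 (p = 2.6e-14)
```

The marker-importance ranking recovers the markers the generator gave the
largest coefficients, and the per-marker linearized RC slopes correlate at
r = 0.98 with univariate Cox log hazard ratios — the network's attributions
agree with classical survival modelling where the truth is linear. A
per-patient report:

```python
g = clinician_guide(3, cohort, rc, results.predict_risk(), outcome)
print(f"patient 3: risk {g.risk:.2f}, median survival of {g.n_similar} "
      f"similar-risk patients: {g.median_survival_similar:.0f} days")
```

```
patient 3: risk 0.38, median survival of 100 similar-risk patients: 11 days
```

The same workflow is available from the shell:

```bash
aidmark simulate --seed 7 --out run/cohort
aidmark preprocess --cohort run/cohort --out run/prep
aidmark train --expanded run/prep --outcome run/cohort/outcome.csv --seed 7 --out run/model
aidmark explain --model run/model/model.json --expanded run/prep --out run/rc.csv
aidmark stats --rc run/rc.csv --cohort run/cohort --outcome run/cohort/outcome.csv --out run/stats
aidmark interactions --rc run/rc.csv --cohort run/cohort --out run/interactions.csv
aidmark report --rc run/rc.csv --risks run/model/risks.csv --cohort run/cohort \
    --outcome run/cohort/outcome.csv --patient 3 --out run/report
```

## Layout

- `src/aidmark/simulate.py` — synthetic cohorts with known Weibull-baseline hazard
- `src/aidmark/preprocess.py` — outlier rule, standardization, feature expansion
- `src/aidmark/coxnn.py` — the Cox-loss network, training, CV, concordance
- `src/aidmark/lrp.py` — the LRP-gamma backward pass and risk stratification
- `src/aidmark/aidstats.py` — marker importance, RC slopes, Cox agreement
- `src/aidmark/interactions.py` — decile-conditioned mixed-effects screen
- `src/aidmark/benchmark.py` — parsimonious Cox, score baselines, Wilcoxon
- `src/aidmark/report.py` — Kaplan–Meier reports and clinician's guides
- `docs/methods.md` — modelling assumptions, parameters, numerical choices
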