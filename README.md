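# tpscore

Temporal-pattern marker discovery in binary electronic-health-record (EHR)
event data.

Clinical markers do not all behave the same way over the course of a
disease: some separate dying from recovering patients throughout the whole
pre-discharge window (*monotonic* markers), others only start diverging as
the outcome approaches (*fluctuating* markers). Classical variable-importance
methods — Gini feature importance, permutation importance, SHAP — are blind
to this distinction. `tpscore` is for researchers working with
MIMIC-style ICU event tables (labs, procedures, prescriptions) who want to
rank event variables by *how well their effect matches a queried temporal
trend pattern*.

## Method

The data are a binary tensor `X ∈ {0,1}^{N×T×F}` (N admissions, T = 10 days
D−10…D−1 before death/discharge, F event variables; 1 = abnormal lab result
or active procedure/prescription that day) and outcomes `Y ∈ {0,1}^N`
(1 = death). A recurrent mortality predictor M (GRU/LSTM/RNN, trained with
binary cross-entropy, Adam and early stopping) serves as backbone. Each
variable f is probed by counterfactual simulation over a day set D:

    Δ(D) = E[M(X[:,D,f] ← 1)] − E[M(X[:,D,f] ← 0)]

With H(f) the Bernoulli entropy of f's pooled occurrence rate and the
window split into far (D−10…D−6) and near (D−5…D−1) halves:

* monotonic score: `TPS(f) = Δ(all days) · H(f)^w`
* none→mortality: `PS(f) = exp(−c·|Δ(far)|) · Δ(near) · H(f)^w`
* none→recovery: same with `−Δ(near)`
* recovery→mortality: `relu(−Δ(far)) · relu(Δ(near)) · H(f)^w`
* mortality→recovery: `relu(Δ(far)) · relu(−Δ(near)) · H(f)^w`

Features are ranked per pattern; the same package provides the baselines
(Gini FI from tree node statistics, permutation importance, exact Shapley
values by coalition enumeration) and the union-top-k rank comparison across
methods. See `docs/methods.md` for assumptions, parameter choices and
limitations.

## Worked example

Generate a synthetic cohort with one planted monotonic mortality marker
(feature 0: daily occurrence rate 0.8 in the mortality group vs 0.1 in the
recovery group, nine outcome-independent background features at rate 0.3),
train a GRU backbone, and score all features:

```bash
$ tpscore simulate --config cohort.json --out ds
simulated N=400 T=10 F=10 (1 planted markers, seed=5) -> ds
$ tpscore train --dataset ds --kind gru --hidden 16 --seed 1 --out ckpt
trained gru (hidden=16, seed=1) -> ckpt
$ tpscore score --dataset ds --checkpoint ckpt --pattern monotonic_mortality \
    --top 3 --out scores.csv
pattern=monotonic_mortality top-3: lab:F0000, lab:F0006, lab:F0009
$ head -4 scores.csv
feature_id,pattern,score,rank
lab:F0000,monotonic_mortality,0.9781503950256121,1
lab:F0006,monotonic_mortality,0.04452274317194955,2
lab:F0009,monotonic_mortality,0.024251544992475286,3
```

The planted marker `lab:F0000` is ranked first with a score an order of
magnitude above the best background feature: forcing it to "occurred" on
every day raises mean predicted mortality by ≈ 0.98 relative to forcing it
to "absent" (times an entropy weight near 1). Background features pick up
only estimation noise. `tpscore encode` builds the same tensor from
MIMIC-schema CSV tables (ADMISSIONS, DIAGNOSES_ICD, LABEVENTS,
PROCEDUREEVENTS_MV, PRESCRIPTIONS), `tpscore plot` draws the group-wise
occurrence-frequency curves, and `tpscore compare` produces the TPS vs
FI/PI/SHAP rank heatmap. Exit codes: 0 success, 1 contract violation or bad
input, 2 usage error.

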