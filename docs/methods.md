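# Methods

## Problem and data model

`tpscore` detects *temporal-pattern markers* in binary electronic-health-record
event data. The input is a tensor `X ∈ {0,1}^{N×T×F}`: for each of N cases
(one hospital admission each), T calendar days before the case's reference
date D0 (the day of discharge or death), and F medical event variables,
`X[i,t,f] = 1` means the event occurred — a lab result outside its normal
range, a procedure performed, or a prescription active that day. The outcome
`Y ∈ {0,1}^N` is 1 for death at discharge, 0 for recovery. The default window
is T = 10 days (D−10 … D−1); D0 itself is excluded so the encoding cannot
leak the outcome.

Day binning: day D−k is the half-open calendar interval k days before D0 in
local record time. A prescription spanning `[STARTDATE, ENDDATE]` is active on
every overlapped window day. Labs with no abnormal flag count as normal.
Features that never occur in the cohort are pruned. Feature identifiers carry
their source table as a prefix (`lab:`, `proc:`, `rx:`) so item ids cannot
collide across tables.

## Pattern scores

A mortality predictor M (the *backbone*) is trained once on (X, Y). The
effect of variable f over a day set D is then probed counterfactually:

    delta(D) = mean_i M(X with x[i,D,f] ← 1) − mean_i M(X with x[i,D,f] ← 0)

Only the cells in D are modified; the complementary period keeps its observed
values, and the model predicts from the full, partially modified sequence.
Every score carries a Bernoulli-entropy weight H(f)^w, where H is the base-2
entropy of the feature's pooled occurrence rate over all N×T cells: variables
that almost never (or always) occur are down-weighted, and w (default 1) lets
a user shift the balance toward common or rare markers. Zero-entropy
(constant) features score exactly 0 under every pattern.

With the window split into a far half (D−10 … D−6) and a near half
(D−5 … D−1):

| pattern | score |
|---|---|
| monotonic (mortality/recovery) | `delta(all) · H^w` — mortality markers large positive, recovery markers most negative |
| none → mortality | `exp(−c·abs(delta(far))) · delta(near) · H^w` |
| none → recovery | `exp(−c·abs(delta(far))) · (−delta(near)) · H^w` |
| recovery → mortality | `relu(−delta(far)) · relu(delta(near)) · H^w` |
| mortality → recovery | `relu(delta(far)) · relu(−delta(near)) · H^w` |

Ranking direction is explicit per pattern (descending score except monotonic
recovery, which ranks ascending); ties break lexicographically by feature id.

### The gate constant c

The exponential factor in the none-to-* scores is a *no-far-effect gate*: it
should be ≈ 1 when the far-period counterfactual effect is indistinguishable
from estimation noise and decay quickly once a genuine far-period effect
exists. Because `delta` is a difference of mean predicted probabilities
(range [−1, 1], estimation noise O(n^−1/2)), the default is c = 10, which
places the gate's e-folding at a far-period effect of 0.1 while leaving it
essentially open within noise. Much larger constants (c ~ 10^4) push the gate
below double-precision resolution — `exp(−c·|delta|)` underflows to exactly
0 for `|delta| > 0.075` — so nearly every feature's score collapses to an
exact-zero tie and the ranking degenerates to tie-breaking; measured
recurrent backbones retain systematic far-period counterfactual responses of
0.05–0.16 even for features with no far-period signal (see "Counterfactual
robustness" below), which such a gate would amplify into noise-dominated
rankings. c is a `PatternSpec` field and a CLI flag for sensitivity studies.

## Backbones

Temporal backbones are single-layer recurrent networks (tanh RNN, GRU, LSTM)
with a sigmoid read-out on the final hidden state, implemented in NumPy with
exact backpropagation through time (verified against central finite
differences in the test suite). Training minimizes binary cross-entropy with
Adam (lr 1e−3, batch 64), an internal stratified validation split (20%),
early stopping (patience 10, max 300 epochs, best-validation weights
restored) and decoupled weight decay 1e−3 on the weight matrices. Defaults:
hidden size 32, GRU. Non-temporal backbones (logistic regression, decision
tree, random forest, gradient boosting via scikit-learn) consume the
time-collapsed union matrix `X' = OR over t of X`.

### Counterfactual robustness

The occurrence/non-occurrence probes evaluate the model off the data
manifold (e.g. five consecutive forced occurrences). An interpolating
network shows spurious sensitivity there; the weight decay above keeps the
fitted network closer to the smallest model consistent with the data. Even
so, a feature that is informative only in the near period retains a
systematic positive far-period response in a trained recurrent net, because
input weights are shared across time and the all-day occurrence count is
itself informative; the gate scaling discussion above accounts for this.

Model comparison uses repeated stratified 80/20 train/test splits (default
10 repetitions) scored by AUROC — the stated 80/20 ratio is kept rather
than classical 10-fold's 90/10.

## Baseline importance methods

* **Gini feature importance** — per-node impurity decrease
  `I(n) = w_n G(n) − w_L G(L) − w_R G(R)` computed from the fitted trees'
  class proportions, summed per split feature, normalized within each tree,
  averaged over the ensemble. Defined only for classification-tree
  backbones; cross-checked against scikit-learn's own attribute in tests.
* **Permutation importance** — baseline score minus mean score after
  permuting one feature column across cases (whole day-vectors for tensors),
  default scorer AUROC, seeded.
* **Shapley values** — exact enumeration of all 2^F coalitions for F ≤ 12
  with a mask-to-0 value function (0 = "event never occurred", the natural
  reference in an occurrence encoding); Monte Carlo permutation sampling
  with an explicit budget beyond that; a literal retrain-per-coalition mode
  exists for F ≤ 6 as an oracle for the masking shortcut. Exact mode
  satisfies efficiency `Σφ_i = f(x) − f(0)` to 1e−9 per case. For temporal
  backbones the T×F grid is flattened to T·F players and |φ| is summed over
  days per feature (an aggregation choice, documented here).

The cross-method comparison takes each method's top-k features by absolute
score, forms their union, and reports every union feature's full-universe
rank per method as a heatmap-ready matrix.

## Synthetic cohorts

The generator emulates the structure of the ICU pneumonia study data:
default T = 10 days, mortality fraction 0.61, background occurrence rate
0.3 for null features (outcome-independent by construction, so any score
they receive is estimation noise — they define the null). Planted markers
draw each cell Bernoulli with group-specific (mortality vs recovery) and
period-specific (far = first ⌈T/2⌉ days) rates consistent with their
declared pattern. Draw order is fixed (outcomes, then features by index),
so a seed pins the cohort bit-for-bit.

What it does *not* emulate: inter-feature correlation, per-case temporal
autocorrelation beyond the rate schedule, missing-data mechanisms, or the
long-tailed frequency spectrum of real EHR vocabularies. Passing recovery
tests therefore show the scoring machinery identifies the patterns it is
designed for under clean conditions; they do not certify performance on
real, correlated EHR data.

A second generator produces cohorts whose class signal lives *purely in
temporal placement*: every feature occurs on exactly 3 of 10 days for every
case, so the collapsed union matrix is all-ones and carries zero class
information, while signal features place occurrences in the near half for
mortality cases and the far half for recovery cases. This isolates the
advantage of sequence models over collapsed-matrix models.

## Experiment sizes and defaults

The packaged experiments (`tpscore.experiments`) use n = 2000 cases,
F = 51 variables and 20 seeded replicates for marker recovery and pattern
specificity (monotonic marker rates 0.7 vs 0.2; fluctuating marker far 0.3
both groups, near 0.7 vs 0.2; background 0.3), and n = 600, F = 20 with 10
CV repetitions for the temporal-advantage comparison. These sizes give
stable success rates while a full replicate set runs in minutes on one CPU.

## Numerical notes and limitations

* Probabilities from the recurrent nets use a numerically stable sigmoid;
  entropy uses the 0·log 0 := 0 convention.
* Scores of bit-identical feature columns are identical by functional
  determinism; rank ties break lexicographically, so tables are fully
  deterministic given a model and tensor.
* `simulate_assign` copies its input; the original tensor is never mutated.
* Single-class outcomes, empty cohorts, all-zero feature sets and layout
  mismatches between checkpoints and tensors raise descriptive errors.
* The Shapley exact mode is exponential in F; it exists for rigor on small
  unions, not for scoring thousands of variables.
* Scores come with no uncertainty quantification; replicate over seeds (as
  the experiment helpers do) to gauge stability.
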