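# Methods

## Model

Both ensemble members are multilayer perceptrons with one hidden layer
(default 16 units), sigmoid activations on hidden and output layers, and
a single output unit read as the positive-class probability. The loss
is the half squared error E = ½ Σ (y − d)²; optimization is plain
mini-batch gradient descent (no momentum). Squared error rather than
cross-entropy is a deliberate fidelity choice: the ensembling scheme is
defined around this training recipe, and for a single sigmoid output on
a well-separated tabular problem the practical difference is small.

Integer questionnaire codes are min-max scaled to [0, 1] using the
*schema's* code ranges, not the data's — scaling is data-independent, so
train and test transforms agree by construction. Scaling can be
disabled (`TrainConfig(scale=False)`).

Dropout is inverted: during a training-mode forward pass each hidden
unit is zeroed with probability *p* and survivors are scaled by
1/(1−*p*); inference applies no mask and no rescaling. Dropout is never
applied to input or output layers. The FCNN is literally the DNN with
*p* = 0 — one code path, bit-identical outputs — so ablation comparisons
cannot be confounded by implementation differences.

A caveat worth stating precisely: inverted dropout keeps the *linear*
part of the computation unbiased — the expectation of the output-layer
pre-activation over masks equals its mask-free value. The post-sigmoid
output is *not* unbiased (Jensen's inequality); the dropout-expectation
test therefore asserts the pre-activation identity, which is the true
one.

## Ensemble weights

w₁ = (A₁/(A₁+A₂) + D₁/(D₁+D₂))/2 and symmetrically for w₂, where A are
final-epoch training-set accuracies (not best-epoch — "accuracy on the
training set" is read as the accuracy of the model actually returned)
and D are the configured dropout rates. When D₁ + D₂ = 0 the dropout
shares are ½/½ (symmetric limit; the formula is otherwise 0/0). The
weighted average is applied to member *probabilities* and then
thresholded at 0.5 (ties predict positive — screening favors recall);
averaging probabilities preserves information that hard labels discard
and makes the convexity invariant (ensemble probability bounded by the
member probabilities) testable. With D₁ = 0 the formula hands the
dropout network ~¾ of the mass whenever accuracies are comparable; this
is implemented as stated and surfaced in tests rather than "fixed".

## Synthetic cohort generator

The generator emulates the reported statistical structure of the study
cohort — 1,503 records, ~65% positive, weak pairwise Pearson
correlations peaking at r ≈ 0.36 between "Feeling sad or Tearful" and
"Overeating or loss of appetite" — via a latent Gaussian copula, the
minimal mechanism that controls marginals and pairwise correlation
independently.

Stated-world defaults (chosen once, fixed):

| Parameter | Default | Why |
|---|---|---|
| n | 1503 | cohort size |
| positive fraction | 0.65 | reported class balance |
| symptom marginals | 45 / 25 / 30 % | mild skew toward "yes" in a symptomatic cohort |
| Age marginals | uniform over 5 bands | no reported age table |
| background latent ρ | 0.12 (symptom pairs) | observed \|r\| stays ≲ 0.1 ("weak") |
| headline latent ρ | 0.453 | calibrated so observed ordinal r ≈ 0.36 |
| outcome coefficients | −1.8 per symptom code step, −0.05 for Age | Bayes-optimal accuracy ≈ 0.91, the regime a well-tuned classifier reaches on the real cohort |

Thresholding attenuates correlation (3-level ordinal items lose ~20%),
so the latent ρ for the headline pair is found by monotone bisection on
ρ with a fixed 400k-draw Monte-Carlo sample per evaluation
(`calibrate_latent_correlation`); common random numbers keep the
response monotone in ρ. The logistic intercept is auto-calibrated by
bisection on a 100,000-draw seed-derived calibration sample so the
expected positive share equals the target.

What a green test does and does not establish: the generator reproduces
the cohort's size, class balance, schema and headline correlation, but
real questionnaire data has marginals, higher-order dependence and
label noise the copula does not model. Headline benchmark numbers
measured on synthetic data characterize the *harness*, not the study
cohort; running on the real CSV via `--data` is supported but never a
test gate.

## Evaluation

Nine metrics from the confusion matrix (positive = anxious): accuracy,
precision, recall, F1, MCC, specificity, NPV, FPR, FNR. Any metric
with a zero denominator (possible on tiny test sets) is reported as 0
and flagged in `zero_denominator` instead of NaN, so downstream tables
never propagate NaNs silently.

Splits are stratified by default (the 65/35 imbalance makes 9:1
unstratified splits unstable); test size is round(n·(1−f)) with
half-away-from-zero ties, allocated across classes by largest
remainder. Split sizes depend only on n and f, never the seed.

Repeated-run benchmarks (default k = 30) re-draw both the stratified
split and the network initialization each run from run-indexed derived
seeds; `protocol="fixed-split"` pins the split and varies only the
initialization. Summary statistics use the sample (k−1) STD.

The Mann–Whitney U comparison is two-sided. For pooled samples of at
most 12 tie-free values the p-value is exact (complete enumeration).
Otherwise a normal approximation is used with midranks, tie-corrected
variance, continuity correction, and an Edgeworth fourth-moment term:
the null distribution of U is platykurtic, and at 6+6 the plain
continuity-corrected normal deviates from the exact two-sided p by up
to 0.0155 for mid-range U, while the kurtosis term (closed-form excess
kurtosis −(6/5)(n₁²+n₂²+n₁n₂+n₁+n₂)/(n₁n₂(n+1)), verified against
enumeration) brings the worst case below 0.002. With ties present the
kurtosis term is dropped (no closed tied form); the tie-corrected
variance is kept.

Baselines (SVM, KNN, DT, RF, NBC, LR, LDA, AdaBoost) enter through a
fit/predict adapter contract and delegate to scikit-learn. Adapter
failures are isolated per classifier. Convolutional and recurrent
baselines are not bundled — no deep-learning framework is assumed and
their tabular architectures are not standardized — but the contract
accepts user-supplied ones.

## Numerical choices and limitations

- All randomness flows through `numpy.random.Generator` seeded from
  explicit config seeds; derived per-run seeds come from
  `SeedSequence([base, stream])` reduced below 2³¹. Fixed seeds give
  bit-identical datasets, training trajectories and reports.
- Gradient correctness is enforced by central-difference checks at
  tolerance 1e−6·(1+|g|) on random small networks.
- Model serialization is JSON with full-precision floats (`repr`
  round-trip), giving bit-exact reload.
- Divergent training (non-finite loss or parameters) raises with the
  epoch index rather than returning garbage.
- Known limitations: single-output binary classification only; no
  momentum/adaptive optimizers; the exact Mann–Whitney branch is
  limited to pooled size 12 (enumeration cost); the copula generator
  does not model the five dropped survey attributes or missing values
  (missing values are rejected at the schema layer, not imputed).
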