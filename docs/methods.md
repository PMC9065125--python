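# Methods

This note documents the models and procedures `icufair` implements, the
defaults it ships, the numerical choices that were genuinely open, and what
the synthetic-cohort validation does and does not establish.

## The synthetic cohort generator

The generator (`icufair.synthetic`) emulates the *shape* of a preprocessed
ICU mortality dataset — N stays × T=24 hourly steps × F features split into
temporal / demographic / admission / comorbidity blocks (defaults
122/5/4/33, so F=164 and the min/max/mean tabular summary with one
sum-flagged feature has F′=409 columns) — not ICU physiology.

* **Temporal features** are stationary Gaussian AR(1) processes
  `x_t = μ + φ(x_{t−1} − μ) + σ√(1−φ²)·ε_t` (defaults μ=0, σ=1, φ=0.5,
  overridable per feature). AR(1) is the simplest process with hourly
  correlation structure; nothing downstream depends on more.
* **Demographics** are sampled independently of the temporal block:
  continuous age (Normal(65, 16) clipped to [15, 99], binned downstream at
  55/67/78 years) and categorical ethnicity / gender / marital status /
  insurance with plausible ICU level probabilities. These are placeholders,
  not calibrated to any published demographic table.
* **Admission and comorbidity features** are Bernoulli flags (defaults 0.3
  and 0.1 prevalence).
* **Mortality labels** follow a logistic model: logit = intercept +
  Σ coef·summary(feature) + group offsets, where each planted feature
  contributes through its per-stay mean, max, or min over the T hours, and
  group offsets attach to demographic levels (default: elevated risk for
  the two oldest age bins, which also plants a group-dependent
  performance/mortality gradient for fairness experiments). The intercept
  is bisected so the cohort-mean event probability equals the target
  prevalence (7% by default, matching the low prevalence that motivates
  AUC-based auditing).
* **Treatments**: per ventilation category (HighFlow, InvasiveVent,
  NonInvasiveVent, Oxygen, Trach) and group level, a Bernoulli adoption
  probability and an exponential span duration. The default plants a 0.30
  adoption gap and a 15 h mean-duration gap on InvasiveVent between the
  WHITE and BLACK/AFRICAN AMERICAN levels, so the fairness module's
  estimators have a known target.
* **Missingness** is MCAR: each temporal event is deleted independently
  with probability `missing_rate` (default 0.1). Static feature events are
  never deleted — a stay losing its ethnicity record would silently fall
  back to a train-mean code, which is not a failure mode worth simulating.
  Informative (MNAR) missingness is out of scope.
* **Events** are emitted exactly on hour marks by default so that a
  missingness-free cohort round-trips through the preprocessing pipeline to
  the generator's latent `(N, T, F)` array bit-exactly (a strong
  correctness oracle); `time_jitter` spreads timestamps within the hour to
  exercise binning.

Everything is a pure function of `SimConfig` including its seed
(independent `SeedSequence` streams per component), so cohorts are
bit-reproducible.

## Preprocessing

Cohort selection keeps first-known ICU stays of patients at least 15 years
old with stay length between 12 h and 10 days. Cleaning converts units via
the feature spec, replaces range tokens `"lo-hi"` by their midpoint, and
collapses duplicate (stay, feature, time) rows — mean for numeric, first
appearance for categorical. Stays are kept when their event span from the
*anchor* — the earliest record within 6 h before admission — covers 24 h to
10 days. Hourly aggregation averages events in half-open bins
`[anchor+h, anchor+h+1)` (half-open avoids double-counting boundary
events); events at or beyond `anchor + T` are dropped, and events earlier
than the anchor are ignored. Imputation is forward- then backward-fill
along time, with features entirely missing for a stay filled from
training-split means only (computed after the 60/20/20 split, preventing
leakage). Categorical features are label-encoded in first-appearance order
and the dictionary is stored with the matrix. No leakage-trimming of late
hours is applied.

Open details resolved here: duplicates are averaged *after* unit
conversion; events between −6 h and an anchor later than −6 h are ignored
(they precede hour 0 by construction).

## Reference models

The classifier contract is `fit(X, y, seed)` / `predict_proba` /
`input_gradient` / optional `glassbox_importance`, with gradients taken on
the pre-threshold positive-class probability — consistently for every
attribution method. Four deliberately small models (well under 50k
parameters) implement it in numpy with analytic gradients, so
remove-and-retrain stays cheap and gradient correctness is testable against
finite differences:

* `linear` — L2-regularized logistic regression (scikit-learn backend).
* `mlp` — one tanh hidden layer (16 units), full-batch Adam, 250 epochs,
  L2 = 1e-2. The relatively strong weight decay is a calibration choice: a
  weakly regularized network driven to extreme margins predicts ~0
  everywhere off the data manifold, which both hurts held-out AUROC and
  degenerates perturbation-based attributions evaluated at baseline points
  (ArchDetect's discrete quotients collapse to zero for most samples).
* `recurrent` — a plain tanh RNN over `(T, F)` inputs, prediction from the
  last hidden state, trained by backpropagation through time.
* `attention_glassbox` — logistic model with a softmax attention gate,
  `p = σ(Σ_j a_j w_j x_j + b)`, `a = softmax(u)`; its published importance
  is `a ⊙ |w|` normalized to sum 1, combining where the model attends with
  how strongly the attended value moves the output.

All models standardize inputs internally on the training split; gradients
chain through the standardization. Training hyperparameters are config
defaults — none are prescribed by the problem.

## Attribution: numerical choices

* **IntegratedGradients** uses a midpoint Riemann sum (`ig_steps`, default
  50). Midpoint has O(steps⁻²) error versus O(steps⁻¹) for the one-sided
  rules, keeps all linear closed forms exact, and holds the completeness
  identity |Σᵢ IGᵢ − (M(x) − M(x′))| below 1e-2 at 200 steps with large
  margin on every reference model.
* **ArchDetect** uses the zero baseline and scores
  `((M(x_i e_i) − M(0))/x_i)²`, with score 0 when |x_i| < 1e-12 (the
  quotient is otherwise undefined at the baseline itself).
* **ShapleySampling** averages marginal contributions over `shapley_draws`
  random feature permutations (default 25) — an unbiased estimator of the
  Shapley value, verified against full 720-permutation enumeration at d=6.
* **FeaturePermutation**'s batch is the full evaluation set; each feature
  is shuffled once per call (seeded) and the mean absolute output change is
  broadcast to every sample.
* **Occlusion** slides a (time × feature) window (default 1×1, at which it
  equals FeatureAblation) with stride 1; overlapping windows are averaged.
* **Baselines** default to coordinate-wise U[0, 1] draws; zeros, fixed
  vectors and user samplers are available. ArchDetect always measures
  against zero.
* **Rankings** are deterministic everywhere: ordinal ranks (ties broken
  toward the lower feature index) wherever a total order is required —
  top-k ablation and global rank aggregation — and dense ranks (ties share
  a rank) in subgroup rank profiles, where "all features tied" should read
  as "all rank 1".
* Gradient-based methods refuse models without `gradient_available` rather
  than silently substituting a perturbation estimate.

## ROAR and trustworthiness

The drop-ratio grid includes 0 (anchoring the trapezoid) through 1 in steps
of 0.1; curve AUC is the trapezoidal integral divided by the ratio span, so
a constant curve has AUC equal to its value. `k = round(ratio·d)`, with a
minimum of 1 whenever ratio > 0. Ablation is per-sample (each sample's own
ranking), with a global-ranking mode available by passing a single
importance vector. One retraining happens per ratio with a seed derived
from (base seed, ratio); the retrained model's test predictions feed both
the classification metrics and the trust score, so the two curves are
mutually consistent by construction. Fillers are per-flattened-feature
training means.

NetTrustScore uses confidence in the predicted class (threshold 0.5),
reward exponent α and penalty exponent β; α = β = 1 throughout, where T_M
is the mean probability assigned to the true class and the ratio-1.0 point
of any ROAR run should approach the constant-predictor closed form
p² + (1−p)².

## Fairness and interaction conventions

Age bins default to the fixed cut points 55/67/78 (left-closed); recomputing
quartiles from a training split is available since "grouped by quartiles"
is ambiguous between the two. Unclear attribute values ('None', 'Unknown',
'Unable to obtain', case-insensitive) are dropped from every group
statistic. Groups with a single outcome class have undefined AUC and are
excluded from min/macro/minority summaries (not imputed at 0.5). Treatment
duration tables report both a per-patient mean (non-adopters contribute 0)
and a per-adopter mean, since either convention is defensible. The overall
AUC is always computed on the pooled set, never reconstructed from group
AUCs. Importance of a protected attribute is the importance of its encoded
feature column (summed over columns if one-hot encoded upstream), and rank
correlations are reported alongside Pearson in importance-vs-fairness
trends because attribution scales differ across methods. Top-k set
comparisons default to k = 50.

## What the validation shows — and does not

The test suite and `scripts/acceptance.py` establish, on synthetic cohorts:

* closed-form attribution identities and the IG/Shapley quadrature errors;
* that ROAR separates a ground-truth importance ranking from a random one
  (oracle curve AUC below random in ≥ 9/10 seeds at n = 2000, T = 24,
  F = 20, five planted coefficients ≥ 2, mlp model, ratios 0–1 step 0.1);
* that ArchDetect-derived rankings beat random rankings under ROAR for the
  flattened-input models (linear, mlp, attention glassbox) on mean-only
  tabular summaries;
* the trustworthiness closed form, planted treatment-gap recovery within
  binomial error, near-zero AUC gaps for identically distributed groups,
  exact interaction identities, and the default pipeline shapes
  (N, 24, 164) and (N, 409).

Two redundancy effects deserve note. With full min/max/mean summaries, the
min/max columns of a planted feature are correlated substitutes for its
mean column: after retraining, a model recovers much of the removed signal
from them, and ranking quality is masked at desk scale — hence the
ArchDetect ordering experiment uses mean-only summaries, where the ranking
itself drives the curve. Likewise, on the flattened hourly sequence each of
the T entries of a planted feature carries ~1/T of the mean-signal, and the
recurrent model re-aggregates the surviving hours; the qualitative
ArchDetect-vs-random ordering is therefore not asserted for the sequence
model at these problem sizes.

More generally, passing on this generator shows the estimators and the
evaluation protocol are implemented correctly, not that any particular
method is best on real ICU data: the synthetic cohorts have linear-logit
signal, MCAR missingness, independent demographics, and no physiologic
structure, all of which real extracts violate. Published results on
access-controlled clinical datasets are not reproduced here.
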