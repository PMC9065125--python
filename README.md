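# icufair

Interpretability and fairness auditing for ICU in-hospital mortality
predictors, exercised end to end on synthetic electronic-health-record
cohorts with planted ground truth.

Clinical risk models are increasingly audited along two axes: *which
features drive their predictions* (feature attribution) and *whether their
performance and the care they describe are equitable across patient groups*
(fairness). This package implements that audit workflow as a tested,
reusable pipeline for the binary in-hospital mortality task on hourly ICU
time series: long-format event tables are cleaned, anchored, aggregated into
an `(N, T, F)` hourly tensor and an `(N, F′)` tabular summary; small
reference classifiers are trained behind a uniform contract; a battery of
attribution methods scores feature importance; rankings are evaluated by
remove-and-retrain; and predictions are audited for group fairness and
treatment disparity.

Real ICU extracts (e.g. MIMIC-IV) are access-controlled, so the package
ships a synthetic cohort generator whose planted coefficients, group
effects and treatment-assignment gaps provide exact ground truth for every
downstream stage. User-supplied event tables in the same delimited-text
schema work identically.

## Methods at a glance

* **Attribution** (module `interpret`), all on the flattened input `x` with
  baseline `x′`: Saliency `∂M/∂x`; IntegratedGradients
  `(x_i−x′_i)·∫₀¹ ∂M(x′+α(x−x′))/∂x_i dα`; GradientShap (expected gradients
  at noisy interpolants); a saliency noise tunnel (SmoothGrad);
  ShapleySampling (Monte-Carlo Shapley values); FeaturePermutation;
  FeatureAblation `M(x)−M(x_{i→x′_i})`; Occlusion (sliding window on the
  `(T, F)` grid); ArchDetect `((M(x_i e_i)−M(0))/x_i)²`; a glassbox reader
  for models exposing their own importance; and a random-ranking baseline.
  Importance is the absolute value of the signed score.
* **ROAR** (module `roar`): replace each sample's top-`k` features (at drop
  ratios 0, 0.1, …, 1) with their training-set means, retrain from scratch,
  and measure AUPRC/AUROC on the equally modified test set. A better
  ranking gives a *lower* area under the metric-vs-ratio curve.
* **Trustworthiness** (module `roar`): NetTrustScore
  `T_M = mean Q(x, z)` with `Q = C(y|x)^α` for correct predictions and
  `(1−C(y|x))^β` otherwise; with `α = β = 1` this is the mean probability
  assigned to the true class, and a constant predictor at prevalence `p`
  has `T_M = p² + (1−p)²` exactly.
* **Fairness** (module `fairness`): stratified AUROC over protected
  attributes (ethnicity, gender, marital status, age quartile, insurance),
  summarized as AUC(min) / AUC(macro-avg) / AUC(minority); ventilation
  adoption rates and summed span durations per subgroup; the Pearson
  correlation between group mortality rates and group AUCs.
* **Interaction** (module `interaction`): group feature importance
  `g_{i,A} = (1/N_A) Σ_j φ_i^j`, subgroup rank profiles, importance-vs-min-AUC
  pairs, Jaccard similarity of top-k feature sets, and overlap with a
  domain-knowledge feature set.

## Worked example

```python
import numpy as np
from icufair import synthetic, preprocess, interpret, roar
from icufair.models import (PredictionSet, SplitSpec, binary_metrics,
                            make_model, split_dataset)
from icufair.fairness import build_group_report

cfg = synthetic.SimConfig(
    n_stays=1500,
    feature_counts={"temporal": 10, "demographic": 5, "admission": 2, "comorbidity": 3},
    planted_features=[synthetic.PlantedFeature("temp_000", 3.0, "mean"),
                      synthetic.PlantedFeature("temp_001", -2.5, "mean")],
    missing_rate=0.1,
    seed=42,
)
cohort = synthetic.generate_cohort(cfg)

spec = preprocess.default_spec(cfg.feature_counts, sum_features=())
clean = preprocess.clean_events(cohort.events, spec)
matrix = preprocess.build_matrix(clean, list(cohort.labels.index), spec, t_hours=24)
train, valid, test = split_dataset(cfg.n_stays, SplitSpec(seed=42))
means = preprocess.train_feature_means(matrix, train)
tabular = preprocess.summarize_tabular(preprocess.impute(matrix, means))

X, y = tabular.values, cohort.labels.to_numpy()
model = make_model("mlp").fit(X[train], y[train], seed=42)
preds = PredictionSet(test, model.predict_proba(X[test]), y[test])
print("test AUPRC = %.3f, AUROC = %.3f" % binary_metrics(preds))

attr = interpret.arch_detect(model, X[test])
order = interpret.aggregate_global_rank(attr)
print("ArchDetect top columns:",
      ", ".join(f"{f}:{k}" for f, k in (tabular.columns[i] for i in order[:4])))

data = roar.SplitData(X[train], y[train], X[test], y[test])
plan = roar.AblationPlan(ratios=(0.0, 0.25, 0.5, 0.75, 1.0), base_seed=42)
res = roar.run_roar_trust(data, lambda: make_model("mlp"),
                          lambda m, Z: interpret.arch_detect(m, Z).importance, plan)
print(f"ROAR curve AUC (AUROC) = {res.roar.auc_auroc:.3f}, "
      f"trust curve AUC = {res.trust.auc:.3f}")

report = build_group_report(preds, cohort.stays.iloc[test].reset_index(drop=True),
                            treatments=cohort.treatments)
print(report.summaries.round(3).to_string(index=False))
```

prints

```
test AUPRC = 0.276, AUROC = 0.682
ArchDetect top columns: temp_001:mean, temp_000:mean, temp_003:mean, temp_009:mean
ROAR curve AUC (AUROC) = 0.556, trust curve AUC = 0.844
     attribute  auc_overall  auc_min  auc_macro  auc_minority
     ethnicity        0.682    0.406      0.762         1.000
        gender        0.682    0.675      0.686         0.696
marital_status        0.682    0.327      0.589         0.327
           age        0.682    0.573      0.658         0.729
     insurance        0.682    0.643      0.678         0.643
```

ArchDetect puts the two planted mean columns first; the ROAR curve AUC
(0.556) sits well below an uninformative ranking's (~0.7+ here), meaning the
ranking removes real signal fast; and the per-attribute AUC summaries show
the small-group noise (minority groups of a few dozen stays) a fairness
audit has to contend with.

The same stages are available from the shell (`icufair simulate`,
`preprocess`, `train`, `attribute`, `roar`, `fairness`, `interact`); run
`icufair --help` or `icufair simulate --show-defaults`.

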