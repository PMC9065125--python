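"""Canned end-to-end experiments on synthetic cohorts.

These are the study-condition experiments the package's validation rests on:
planted-signal cohorts pushed through the full preprocessing pipeline, ROAR
oracle-vs-random separation, trustworthiness closed-form checks, and
fairness parameter recovery.  Both the test suite and the reproduction
script call these functions so the numbers they report come from one code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess, synthetic
from .interpret import random_ranking
from .models import PredictionSet, SplitSpec, binary_metrics, make_model, split_dataset
from .roar import AblationPlan, SplitData, run_roar_trust
from .fairness import ProtectedAttribute, group_auc, resolve_groups, treatment_summary

DEFAULT_PLANTED_COEFFS = (3.0, -2.5, 2.5, -2.0, 2.0)


@dataclass
class PlantedTabular:
    """A planted-signal cohort reduced to its tabular summary."""

    X: np.ndarray
    y: np.ndarray
    tabular: preprocess.TabularSummary
    cohort: synthetic.SyntheticCohort
    oracle_importance: np.ndarray  # (d,) |coef| on the planted summary columns


def make_planted_tabular(
    seed: int,
    n_stays: int = 2000,
    t_hours: int = 24,
    n_temporal: int = 20,
    coeffs: tuple[float, ...] = DEFAULT_PLANTED_COEFFS,
    missing_rate: float = 0.0,
    summaries: tuple[str, ...] = ("min", "max", "mean"),
) -> PlantedTabular:
    """Generate a temporal-only cohort and run it through the full pipeline.

    The planted features act on the per-stay mean of the first
    ``len(coeffs)`` temporal features; the oracle importance vector carries
    |coef| on exactly those tabular mean columns.  ``summaries`` selects the
    per-feature summary columns; a mean-only summary removes the min/max
    columns that otherwise act as correlated substitutes for the signal.
    """
    counts = {"temporal": n_temporal, "demographic": 0, "admission": 0, "comorbidity": 0}
    cfg = synthetic.SimConfig(
        n_stays=n_stays,
        t_hours=t_hours,
        feature_counts=counts,
        planted_features=[
            synthetic.PlantedFeature(f"temp_{i:03d}", c, "mean") for i, c in enumerate(coeffs)
        ],
        group_levels={},
        demographic_effects={},
        treatment_config=[],
        missing_rate=missing_rate,
        seed=seed,
    )
    cohort = synthetic.generate_cohort(cfg)
    if summaries == ("min", "max", "mean"):
        spec = preprocess.default_spec(counts, sum_features=())
    else:
        spec = preprocess.FeatureSpec(
            [
                preprocess.FeatureDef(f"temp_{i:03d}", "temporal", summaries=summaries)
                for i in range(n_temporal)
            ]
        )
    clean = preprocess.clean_events(cohort.events, spec)
    matrix = preprocess.build_matrix(clean, list(cohort.labels.index), spec, t_hours=t_hours)
    means = preprocess.train_feature_means(matrix, np.arange(n_stays))
    tab = preprocess.summarize_tabular(preprocess.impute(matrix, means))
    oracle = np.zeros(tab.values.shape[1])
    for pf in cohort.ground_truth.planted_features:
        oracle[tab.column_index(pf.feature_id, pf.summary)] = abs(pf.coefficient)
    return PlantedTabular(
        X=tab.values, y=cohort.labels.to_numpy(), tabular=tab, cohort=cohort, oracle_importance=oracle
    )


@dataclass
class SeparationRun:
    oracle_auc: float
    random_auc: float
    auroc_at_full_drop: float
    trust_at_full_drop: float
    prevalence: float


def roar_separation_run(
    seed: int,
    n_stays: int = 2000,
    n_temporal: int = 20,
    model_kind: str = "mlp",
    ratios: tuple[float, ...] | None = None,
) -> SeparationRun:
    """One seed of the oracle-vs-random ROAR separation experiment."""
    pt = make_planted_tabular(seed, n_stays=n_stays, n_temporal=n_temporal)
    tr, _, te = split_dataset(len(pt.X), SplitSpec(seed=seed))
    data = SplitData(pt.X[tr], pt.y[tr], pt.X[te], pt.y[te])
    d = pt.X.shape[1]
    imp_oracle = (
        np.tile(pt.oracle_importance, (len(tr), 1)),
        np.tile(pt.oracle_importance, (len(te), 1)),
    )
    imp_random = (
        random_ranking(d, 2 * seed + 1, len(tr)).importance,
        random_ranking(d, 2 * seed + 2, len(te)).importance,
    )
    plan = AblationPlan(base_seed=seed) if ratios is None else AblationPlan(ratios, base_seed=seed)
    res_o = run_roar_trust(data, lambda: make_model(model_kind), imp_oracle, plan)
    res_r = run_roar_trust(data, lambda: make_model(model_kind), imp_random, plan)
    return SeparationRun(
        oracle_auc=res_o.roar.auc_auroc,
        random_auc=res_r.roar.auc_auroc,
        auroc_at_full_drop=res_o.roar.auroc[-1],
        trust_at_full_drop=res_o.trust.trust[-1],
        prevalence=float(np.mean(data.y_test)),
    )


def arch_vs_random_run(
    seed: int,
    model_kind: str = "mlp",
    n_stays: int = 1500,
    t_hours: int = 8,
    n_temporal: int = 20,
) -> tuple[float, float]:
    """ROAR curve AUCs (ArchDetect, random ranking) on a planted cohort.

    Uses a mean-only tabular summary so the ranking quality itself — not the
    presence of correlated min/max substitute columns — drives the curve; a
    good ranking yields the lower area.  Returns (arch_auc, random_auc).
    """
    from .interpret import arch_detect

    pt = make_planted_tabular(
        seed, n_stays=n_stays, t_hours=t_hours, n_temporal=n_temporal, summaries=("mean",)
    )
    tr, _, te = split_dataset(len(pt.X), SplitSpec(seed=seed))
    data = SplitData(pt.X[tr], pt.y[tr], pt.X[te], pt.y[te])
    d = pt.X.shape[1]
    imp_arch = lambda m, Z: arch_detect(m, Z).importance
    imp_rand = (
        random_ranking(d, 3 * seed + 1, len(tr)).importance,
        random_ranking(d, 3 * seed + 2, len(te)).importance,
    )
    plan = AblationPlan(ratios=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), base_seed=seed)
    factory = lambda: make_model(model_kind)
    arch_auc = run_roar_trust(data, factory, imp_arch, plan).roar.auc_auroc
    rand_auc = run_roar_trust(data, factory, imp_rand, plan).roar.auc_auroc
    return arch_auc, rand_auc


def fairness_recovery_run(seed: int, n_stays: int = 2000) -> dict:
    """Recover the planted InvasiveVent adoption gap (WHITE vs BLACK) from a cohort."""
    cfg = synthetic.SimConfig(
        n_stays=n_stays,
        feature_counts={"temporal": 5, "demographic": 5, "admission": 0, "comorbidity": 0},
        planted_features=[synthetic.PlantedFeature("temp_000", 2.5, "mean")],
        missing_rate=0.0,
        seed=seed,
    )
    cohort = synthetic.generate_cohort(cfg)
    groups = resolve_groups(cohort.stays, "ethnicity")
    table = treatment_summary(cohort.treatments, cohort.stays, groups)
    iv = table.loc[table["category"] == "InvasiveVent"].set_index("level")
    p_w, p_b = iv.loc["WHITE", "adoption_rate"], iv.loc["BLACK/AFRICAN AMERICAN", "adoption_rate"]
    n_w, n_b = int(iv.loc["WHITE", "n"]), int(iv.loc["BLACK/AFRICAN AMERICAN", "n"])
    se = float(np.sqrt(p_w * (1 - p_w) / n_w + p_b * (1 - p_b) / n_b))
    rule = next(r for r in cfg.treatment_config if r.category == "InvasiveVent")
    true_gap = rule.adoption["WHITE"] - rule.adoption["BLACK/AFRICAN AMERICAN"]
    dur_w = iv.loc["WHITE", "mean_duration_adopters"]
    dur_b = iv.loc["BLACK/AFRICAN AMERICAN", "mean_duration_adopters"]
    true_dur_gap = rule.mean_duration["WHITE"] - rule.mean_duration["BLACK/AFRICAN AMERICAN"]
    # exponential durations: SE of the adopter mean is mean/sqrt(k)
    k_w, k_b = p_w * n_w, p_b * n_b
    dur_se = float(
        np.sqrt(rule.mean_duration["WHITE"] ** 2 / k_w + rule.mean_duration["BLACK/AFRICAN AMERICAN"] ** 2 / k_b)
    )
    return {
        "adoption_gap": float(p_w - p_b),
        "adoption_gap_true": float(true_gap),
        "adoption_gap_se": se,
        "duration_gap": float(dur_w - dur_b),
        "duration_gap_true": float(true_dur_gap),
        "duration_gap_se": dur_se,
    }


def identical_groups_auc_gap(seed: int, n_per_group: int = 5000, n_groups: int = 3) -> float:
    """Max pairwise AUC gap between groups drawn from one score/label distribution."""
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    risk = rng.normal(size=n)
    scores = 1.0 / (1.0 + np.exp(-risk))
    labels = (rng.random(n) < scores).astype(int)
    import pandas as pd

    group_labels = np.repeat([f"G{i}" for i in range(n_groups)], n_per_group)
    groups = ProtectedAttribute(
        "synthetic", pd.Series(group_labels), tuple(f"G{i}" for i in range(n_groups))
    )
    preds = PredictionSet(np.arange(n), scores, labels)
    aucs = [a for a in group_auc(preds, groups).values() if a is not None]
    return float(max(aucs) - min(aucs))
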