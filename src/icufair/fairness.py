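"""Group-fairness auditing: treatment disparity and stratified-AUC reports.

Prediction fairness is audited by stratifying a test prediction set over
protected attributes (ethnicity, gender, marital status, age quartile,
insurance), computing the AUROC per subgroup, and summarizing with the
minimum, macro-average and smallest-group AUC.  AUC is used because it is
threshold-agnostic and robust to the low (~7%) mortality prevalence.
Samples with unclear attribute values ('None', 'Unknown', 'Unable to
obtain') are dropped from all group statistics.

Treatment disparity compares ventilation adoption rates and summed span
durations across subgroups; both a per-patient mean (non-adopters count 0)
and a per-adopter mean duration are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import PredictionSet, binary_metrics

__all__ = [
    "UNCLEAR_TOKENS",
    "DEFAULT_AGE_CUTS",
    "AGE_BIN_LABELS",
    "ProtectedAttribute",
    "resolve_groups",
    "treatment_summary",
    "group_auc",
    "fairness_summary",
    "mortality_auc_correlation",
    "group_mortality_rates",
    "GroupReport",
    "build_group_report",
]

UNCLEAR_TOKENS = frozenset({"none", "unknown", "unable to obtain", ""})
AGE_BIN_LABELS = ("<55 YRS", "55-67 YRS", "67-78 YRS", ">=78 YRS")
DEFAULT_AGE_CUTS = (55.0, 67.0, 78.0)


@dataclass
class ProtectedAttribute:
    """Per-sample group labels for one protected attribute; None = unclear."""

    name: str
    labels: pd.Series  # indexed like the stays frame; None/NaN for unclear
    levels: tuple[str, ...]

    def defined_mask(self) -> np.ndarray:
        return self.labels.notna().to_numpy()


def resolve_groups(
    stays: pd.DataFrame,
    attribute: str,
    mapping: Mapping[str, str] | None = None,
    age_cuts: Sequence[float] = DEFAULT_AGE_CUTS,
    age_column: str = "age_at_admission",
) -> ProtectedAttribute:
    """Map raw attribute values to analysis levels; unclear values are excluded.

    ``age`` is binned from the continuous age column using left-closed cut
    points (defaults <55 / 55-67 / 67-78 / >=78).  Raw values matching an
    unclear token (case-insensitive) or absent from an explicit ``mapping``
    become None and are excluded from every group statistic.
    """
    if attribute == "age":
        age = stays[age_column].to_numpy(dtype=float)
        idx = np.searchsorted(np.asarray(age_cuts, dtype=float), age, side="right")
        lab = np.asarray(AGE_BIN_LABELS[: len(age_cuts) + 1], dtype=object)[idx]
        labels = pd.Series(lab, index=stays.index)
        return ProtectedAttribute("age", labels, AGE_BIN_LABELS[: len(age_cuts) + 1])

    raw = stays[attribute].astype(object)
    unmapped: set[str] = set()

    def _map(v):
        if pd.isna(v):
            return None
        s = str(v)
        if s.strip().lower() in UNCLEAR_TOKENS:
            return None
        if mapping is not None:
            if s in mapping:
                return mapping[s]
            unmapped.add(s)
            return None
        return s

    labels = raw.map(_map)
    if unmapped:
        warnings.warn(
            f"resolve_groups({attribute}): {len(unmapped)} raw label(s) without a mapping "
            f"treated as unclear: {sorted(unmapped)[:5]}",
            stacklevel=2,
        )
    levels = tuple(pd.unique(labels.dropna()))
    if not levels:
        warnings.warn(f"resolve_groups({attribute}): all samples unclear", stacklevel=2)
    return ProtectedAttribute(attribute, labels, levels)


def treatment_summary(
    treatments: pd.DataFrame,
    stays: pd.DataFrame,
    groups: ProtectedAttribute,
) -> pd.DataFrame:
    """Adoption rate and mean treatment duration per category x group level.

    A stay with no span for a category is a non-adopter; a stay's duration is
    the sum of its individual spans.  Two duration conventions are reported:
    ``mean_duration_all`` averages over every stay in the group (non-adopters
    contribute 0) and ``mean_duration_adopters`` averages over adopters only.
    """
    stay_ids = stays["stay_id"].to_numpy(dtype=object)
    lab = groups.labels
    if not lab.index.equals(stays.index):
        lab = lab.reindex(stays.index)
    rows = []
    if len(treatments):
        dur = treatments.assign(_d=treatments["end_hours"] - treatments["start_hours"])
        per_stay = dur.groupby(["category", "stay_id"], sort=False)["_d"].sum()
    else:
        per_stay = pd.Series(dtype=float)
    categories = sorted(treatments["category"].unique()) if len(treatments) else []
    for cat in categories:
        cat_dur = per_stay.loc[cat] if cat in per_stay.index.get_level_values(0) else pd.Series(dtype=float)
        for level in groups.levels:
            in_group = stay_ids[(lab == level).to_numpy()]
            n = len(in_group)
            if n == 0:
                continue
            d = cat_dur.reindex(in_group).fillna(0.0)
            adopters = (d > 0).sum()
            rows.append(
                {
                    "category": cat,
                    "attribute": groups.name,
                    "level": level,
                    "n": n,
                    "adoption_rate": adopters / n,
                    "mean_duration_all": float(d.mean()),
                    "mean_duration_adopters": float(d[d > 0].mean()) if adopters else np.nan,
                }
            )
    return pd.DataFrame(rows)


def group_auc(preds: PredictionSet, groups: ProtectedAttribute) -> dict[str, float | None]:
    """AUROC restricted to each group; single-class groups map to None."""
    lab = np.asarray(groups.labels, dtype=object)
    out: dict[str, float | None] = {}
    for level in groups.levels:
        mask = lab == level
        if mask.sum() == 0:
            out[level] = None
            continue
        sub = PredictionSet(
            np.asarray(preds.sample_ids)[mask],
            np.asarray(preds.scores)[mask],
            np.asarray(preds.labels)[mask],
        )
        try:
            _, auroc = binary_metrics(sub)
            out[level] = auroc
        except ValueError:
            warnings.warn(
                f"group_auc: group {level!r} of {groups.name} has a single class; AUC undefined",
                stacklevel=2,
            )
            out[level] = None
    return out

def fairness_summary(
    aucs: Mapping[str, float | None], sizes: Mapping[str, int]
) -> tuple[float, float, float]:
    """(min, macro-average, minority) over groups with a defined AUC.

    Minority = AUC of the smallest group among those with a defined AUC;
    undefined (single-class) groups are excluded rather than imputed.
    """
    defined = {g: a for g, a in aucs.items() if a is not None}
    if not defined:
        raise ValueError("no group has a defined AUC")
    vals = np.array(list(defined.values()), dtype=float)
    smallest = min(defined, key=lambda g: (sizes[g], g))
    return float(vals.min()), float(vals.mean()), float(defined[smallest])


def group_mortality_rates(labels: np.ndarray, groups: ProtectedAttribute) -> dict[str, float]:
    lab = np.asarray(groups.labels, dtype=object)
    y = np.asarray(labels, dtype=float)
    return {
        level: float(y[lab == level].mean())
        for level in groups.levels
        if (lab == level).any()
    }


def mortality_auc_correlation(
    rates: Sequence[float], aucs: Sequence[float]
) -> tuple[float | None, float | None]:
    """Pearson correlation between group mortality rates and group AUCs.

    Returns (None, None) when either side is constant (correlation undefined).
    """
    x = np.asarray(rates, dtype=float)
    y = np.asarray(aucs, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupReport:
    """Full fairness audit over several protected attributes."""

    per_group: pd.DataFrame  # attribute, level, n, mortality_rate, auc
    summaries: pd.DataFrame  # attribute, auc_overall, auc_min, auc_macro, auc_minority
    treatment: pd.DataFrame = field(default_factory=pd.DataFrame)
    pearson_r: float | None = None
    pearson_p: float | None = None


def build_group_report(
    preds: PredictionSet,
    stays: pd.DataFrame,
    attributes: Sequence[str] = ("ethnicity", "gender", "marital_status", "age", "insurance"),
    treatments: pd.DataFrame | None = None,
    age_cuts: Sequence[float] = DEFAULT_AGE_CUTS,
) -> GroupReport:
    """Audit a prediction set across protected attributes.

    The overall AUC is always computed on the pooled set (never reconstructed
    from group AUCs); the mortality-rate/AUC Pearson correlation pools the
    (rate, AUC) pairs of every defined group across attributes.
    """
    _, overall = binary_metrics(preds)
    rows, summ, pooled_rates, pooled_aucs = [], [], [], []
    treat_frames = []
    for attr in attributes:
        groups = resolve_groups(stays, attr, age_cuts=age_cuts)
        if not groups.levels:
            continue
        aucs = group_auc(preds, groups)
        rates = group_mortality_rates(np.asarray(preds.labels), groups)
        lab = np.asarray(groups.labels, dtype=object)
        sizes = {level: int((lab == level).sum()) for level in groups.levels}
        for level in groups.levels:
            rows.append(
                {
                    "attribute": attr,
                    "level": level,
                    "n": sizes[level],
                    "mortality_rate": rates.get(level),
                    "auc": aucs[level],
                }
            )
            if aucs[level] is not None:
                pooled_rates.append(rates[level])
                pooled_aucs.append(aucs[level])
        try:
            mn, macro, minority = fairness_summary(aucs, sizes)
            summ.append(
                {
                    "attribute": attr,
                    "auc_overall": overall,
                    "auc_min": mn,
                    "auc_macro": macro,
                    "auc_minority": minority,
                }
            )
        except ValueError:
            pass
        if treatments is not None and len(treatments):
            treat_frames.append(treatment_summary(treatments, stays, groups))
    r, p = mortality_auc_correlation(pooled_rates, pooled_aucs)
    return GroupReport(
        per_group=pd.DataFrame(rows),
        summaries=pd.DataFrame(summ),
        treatment=pd.concat(treat_frames, ignore_index=True) if treat_frames else pd.DataFrame(),
        pearson_r=r,
        pearson_p=p,
    )
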