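"""Interactions between interpretability and fairness.

Connects per-sample feature attributions with protected-group structure:

* group feature importance g(i, A): the mean importance of feature i over the
  members of group A, and its max-min disparity across an attribute's levels,
* rank profiles: where each demographic feature's time-averaged importance
  ranks among all F features within a subgroup (dense ranks, 1 = top),
* importance-vs-min-AUC pairs across protected attributes with Pearson and
  Spearman coefficients (rank correlation is reported because attribution
  scales differ wildly across interpreters),
* Jaccard similarity of top-k feature sets across models/interpreters,
* overlap partitions against a user-supplied domain-knowledge feature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .interpret import Attribution
from .fairness import ProtectedAttribute
from .ranking import dense_rank, top_k_indices

__all__ = [
    "GroupImportance",
    "group_feature_importance",
    "importance_disparity_null",
    "rank_profile",
    "importance_fairness_pairs",
    "jaccard_topk",
    "compare_domain_knowledge",
]


@dataclass
class GroupImportance:
    feature: int | str
    attribute: str
    per_level: dict[str, float]  # level -> mean importance over members
    disparity: float  # max - min over defined levels


def group_feature_importance(
    attr: Attribution | np.ndarray,
    groups: ProtectedAttribute,
    feature: int,
) -> GroupImportance:
    """Exact mean importance of one feature per group level.

    Empty levels are omitted from ``per_level`` (and hence from the
    disparity).  The size-weighted mean of the level means equals the overall
    mean over all grouped samples by construction.
    """
    imp = attr.importance if isinstance(attr, Attribution) else np.abs(np.asarray(attr, dtype=float))
    lab = np.asarray(groups.labels, dtype=object)
    if len(lab) != len(imp):
        raise ValueError("attribution and groups are not aligned by sample")
    per_level: dict[str, float] = {}
    for level in groups.levels:
        mask = lab == level
        if mask.sum() == 0:
            continue
        per_level[level] = float(imp[mask, feature].mean())
    vals = list(per_level.values())
    disparity = float(max(vals) - min(vals)) if vals else float("nan")
    return GroupImportance(feature, groups.name, per_level, disparity)


def importance_disparity_null(
    attr: Attribution | np.ndarray,
    groups: ProtectedAttribute,
    feature: int,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the disparity under random relabeling of groups."""
    imp = attr.importance if isinstance(attr, Attribution) else np.abs(np.asarray(attr, dtype=float))
    lab = np.asarray(groups.labels, dtype=object)
    rng = np.random.default_rng(seed)
    col = imp[:, feature]
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(lab))
        shuffled = lab[perm]
        means = [col[shuffled == level].mean() for level in groups.levels if (shuffled == level).any()]
        null[b] = max(means) - min(means) if means else np.nan
    return null


def rank_profile(
    attr: Attribution | np.ndarray,
    groups: ProtectedAttribute,
    input_shape: tuple[int, int],
    demographic_columns: Mapping[str, int],
) -> dict[str, dict[str, int]]:
    """Rank each demographic feature's importance within each subgroup.

    Importance is first averaged across time steps (the attribution lives on
    the flattened T x F grid), then averaged over the subgroup's members, and
    each demographic feature is dense-ranked among all F features within the
    subgroup (rank 1 = most important, ties share a rank).
    Returns {level: {demographic feature: rank}}.
    """
    imp = attr.importance if isinstance(attr, Attribution) else np.abs(np.asarray(attr, dtype=float))
    t, f = input_shape
    if imp.shape[1] == t * f:
        per_feature = imp.reshape(len(imp), t, f).mean(axis=1)
    elif imp.shape[1] == f:
        per_feature = imp
    else:
        raise ValueError(f"attribution width {imp.shape[1]} matches neither T*F={t*f} nor F={f}")
    lab = np.asarray(groups.labels, dtype=object)
    out: dict[str, dict[str, int]] = {}
    for level in groups.levels:
        mask = lab == level
        if mask.sum() == 0:
            continue
        mean_imp = per_feature[mask].mean(axis=0)
        ranks = dense_rank(mean_imp)
        out[level] = {name: int(ranks[col]) for name, col in demographic_columns.items()}
    return out


def importance_fairness_pairs(
    attribute_importance: Mapping[str, float],
    min_auc: Mapping[str, float],
) -> dict:
    """Pair each protected attribute's mean importance with its min group AUC.

    Returns the paired table plus Pearson and Spearman coefficients; both are
    None when either coordinate is constant.
    """
    attrs = [a for a in attribute_importance if a in min_auc]
    x = np.array([attribute_importance[a] for a in attrs], dtype=float)
    y = np.array([min_auc[a] for a in attrs], dtype=float)
    result = {
        "attributes": attrs,
        "importance": x,
        "min_auc": y,
        "pearson_r": None,
        "pearson_p": None,
        "spearman_rho": None,
        "spearman_p": None,
    }
    if len(attrs) >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        pr, pp = stats.pearsonr(x, y)
        sr, sp = stats.spearmanr(x, y)
        result.update(
            pearson_r=float(pr), pearson_p=float(pp), spearman_rho=float(sr), spearman_p=float(sp)
        )
    return result


def jaccard_topk(
    ordering_a: Sequence[int] | np.ndarray,
    ordering_b: Sequence[int] | np.ndarray,
    k: int = 50,
) -> float:
    """Jaccard similarity of the top-k sets of two feature orderings."""
    a = set(np.asarray(ordering_a)[:k].tolist())
    b = set(np.asarray(ordering_b)[:k].tolist())
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def compare_domain_knowledge(dk: set, identified: set) -> dict:
    """Partition a domain-knowledge feature set against identified features."""
    inter = dk & identified
    return {
        "intersection": inter,
        "dk_only": dk - identified,
        "identified_only": identified - dk,
        "n_intersection": len(inter),
        "n_dk_only": len(dk - identified),
        "n_identified_only": len(identified - dk),
        "overlap_fraction": len(inter) / len(dk) if dk else float("nan"),
    }
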