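"""Remove-and-retrain (ROAR) evaluation and trustworthiness curves.

ROAR scores an importance ranking by replacing each sample's top-ranked
features — at a grid of drop ratios — with an uninformative filler (the
feature's training-set mean), retraining the model from scratch on the
modified training set, and measuring AUPRC/AUROC on the equally modified test
set.  A ranking that finds the truly informative features makes the curve
fall fast, i.e. yields a *lower* area under the metric-vs-ratio curve.

The trustworthiness curve reuses the very same retrained models and records
the NetTrustScore T_M at each ratio.  With reward and penalty exponents
alpha = beta = 1, T_M reduces to the mean probability the model assigns to
the true class; a constant predictor emitting the prevalence p has
T_M = p^2 + (1-p)^2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .interpret import Attribution
from .models import ModelContract, PredictionSet, binary_metrics
from .ranking import top_k_indices

__all__ = [
    "SplitData",
    "AblationPlan",
    "RoarCurve",
    "TrustSpec",
    "TrustCurve",
    "RoarResult",
    "uninformative_values",
    "ablate_topk",
    "trust_score",
    "run_roar_trust",
    "run_roar",
    "run_trust_curve",
    "curve_auc",
]

DEFAULT_RATIOS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class SplitData:
    """A fixed train/test split of flattened inputs (the split precedes any ablation)."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class AblationPlan:
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    fillers: np.ndarray | None = None  # per flattened feature; default: train means
    base_seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise ValueError("drop ratios must be strictly increasing")
        if r.min() < 0 or r.max() > 1:
            raise ValueError("drop ratios must lie in [0, 1]")


@dataclass
class RoarCurve:
    ratios: np.ndarray
    auprc: np.ndarray
    auroc: np.ndarray

    @property
    def auc_auprc(self) -> float:
        return curve_auc(self.ratios, self.auprc)

    @property
    def auc_auroc(self) -> float:
        return curve_auc(self.ratios, self.auroc)


@dataclass(frozen=True)
class TrustSpec:
    alpha: float = 1.0  # reward exponent on confidence in correct predictions
    beta: float = 1.0  # penalty exponent on confidence in wrong predictions


@dataclass
class TrustCurve:
    ratios: np.ndarray
    trust: np.ndarray

    @property
    def auc(self) -> float:
        return curve_auc(self.ratios, self.trust)


@dataclass
class RoarResult:
    roar: RoarCurve
    trust: TrustCurve
    predictions: list[PredictionSet] = field(default_factory=list)


def curve_auc(ratios: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a metric-vs-ratio curve, normalized by ratio span."""
    r = np.asarray(ratios, dtype=float)
    v = np.asarray(values, dtype=float)
    return float(np.trapezoid(v, r) / (r[-1] - r[0]))


def uninformative_values(train_inputs: np.ndarray) -> np.ndarray:
    """Per-flattened-feature mean over the training rows."""
    return np.asarray(train_inputs, dtype=float).mean(axis=0)


def ablate_topk(
    inputs: np.ndarray,
    importance: np.ndarray | Attribution,
    ratio: float,
    fillers: np.ndarray,
) -> np.ndarray:
    """Replace each sample's own top round(ratio*d) features with the fillers.

    ``importance`` is (n, d) per-sample scores or a single (d,) ranking applied
    to every sample; ties break toward the lower feature index.  For any
    ratio > 0 at least one feature is replaced.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    X = np.array(inputs, dtype=float, copy=True)
    n, d = X.shape
    if ratio == 0.0:
        return X
    k = max(1, int(round(ratio * d)))
    imp = importance.importance if isinstance(importance, Attribution) else np.asarray(importance)
    fillers = np.asarray(fillers, dtype=float)
    if imp.ndim == 1:
        idx = top_k_indices(imp, k)
        X[:, idx] = fillers[idx]
        return X
    if imp.shape != X.shape:
        raise ValueError(f"importance shape {imp.shape} does not match inputs {X.shape}")
    for i in range(n):
        idx = top_k_indices(imp[i], k)
        X[i, idx] = fillers[idx]
    return X


def trust_score(preds: PredictionSet, spec: TrustSpec = TrustSpec()) -> float:
    """NetTrustScore over a prediction set.

    Confidence is the probability of the predicted class (threshold 0.5);
    correct predictions contribute confidence**alpha, wrong ones
    (1 - confidence)**beta.  With alpha = beta = 1 this is the mean
    probability assigned to the true class.
    """
    p = np.asarray(preds.scores, dtype=float)
    y = np.asarray(preds.labels, dtype=int)
    pred = (p >= 0.5).astype(int)
    conf = np.where(pred == 1, p, 1.0 - p)
    q = np.where(pred == y, conf ** spec.alpha, (1.0 - conf) ** spec.beta)
    return float(q.mean())


def _ratio_seed(base_seed: int, ratio: float) -> int:
    return (base_seed * 1009 + int(round(ratio * 100)) + 1) % (2**31 - 1)


def run_roar_trust(
    data: SplitData,
    model_factory: Callable[[], ModelContract],
    importance: tuple[np.ndarray, np.ndarray] | Callable[[ModelContract, np.ndarray], np.ndarray],
    plan: AblationPlan,
    trust_spec: TrustSpec = TrustSpec(),
) -> RoarResult:
    """Run the full remove-and-retrain protocol once.

    ``importance`` is either a pair of per-sample importance arrays
    (train, test) fixed in advance (oracle/random sources), or a callable
    applied to a model fitted on the unmodified data — the paper-style flow
    where the attribution method itself supplies the ranking.  The retrained
    model at each ratio produces one PredictionSet from which both the
    classification metrics and the trust score are read, so the two curves are
    always mutually consistent.
    """
    fillers = plan.fillers if plan.fillers is not None else uninformative_values(data.X_train)

    if callable(importance):
        base_model = model_factory().fit(data.X_train, data.y_train, seed=_ratio_seed(plan.base_seed, -0.01))
        imp_train = np.atleast_2d(importance(base_model, data.X_train))
        imp_test = np.atleast_2d(importance(base_model, data.X_test))
    else:
        imp_train, imp_test = importance

    ratios = np.asarray(plan.ratios, dtype=float)
    auprc = np.empty(len(ratios))
    auroc = np.empty(len(ratios))
    trust = np.empty(len(ratios))
    predictions: list[PredictionSet] = []
    for i, r in enumerate(ratios):
        Xtr = ablate_topk(data.X_train, imp_train, r, fillers)
        Xte = ablate_topk(data.X_test, imp_test, r, fillers)
        model = model_factory().fit(Xtr, data.y_train, seed=_ratio_seed(plan.base_seed, r))
        scores = model.predict_proba(Xte)
        preds = PredictionSet(np.arange(len(scores)), scores, np.asarray(data.y_test))
        auprc[i], auroc[i] = binary_metrics(preds)
        trust[i] = trust_score(preds, trust_spec)
        predictions.append(preds)
    return RoarResult(
        roar=RoarCurve(ratios, auprc, auroc),
        trust=TrustCurve(ratios, trust),
        predictions=predictions,
    )


def run_roar(data, model_factory, importance, plan: AblationPlan) -> RoarCurve:
    return run_roar_trust(data, model_factory, importance, plan).roar


def run_trust_curve(
    data, model_factory, importance, plan: AblationPlan, spec: TrustSpec = TrustSpec()
) -> TrustCurve:
    return run_roar_trust(data, model_factory, importance, plan, spec).trust
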