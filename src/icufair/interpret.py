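"""Feature-importance estimators over flattened model inputs.

Each estimator takes a fitted model honouring the ``ModelContract``, a batch
of inputs of shape (n, d_in), a baseline specification and a method
configuration, and returns an :class:`Attribution`: signed per-entry scores
whose absolute values are the importance scores used everywhere downstream.

Gradient methods (saliency, integrated gradients, GradientShap, the saliency
noise tunnel) require ``gradient_available``; perturbation methods (Shapley
sampling, feature permutation, feature ablation, occlusion, ArchDetect) only
need ``predict_proba``.  The default baseline draws each coordinate from
U[0, 1]; ArchDetect always measures against the zero baseline, squaring a
discrete difference quotient so its scores are nonnegative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models import ModelContract
from .ranking import ordinal_rank

__all__ = [
    "CapabilityError",
    "BaselineSpec",
    "InterpreterConfig",
    "Attribution",
    "saliency",
    "integrated_gradients",
    "gradient_shap",
    "saliency_noise_tunnel",
    "shapley_sampling",
    "feature_permutation",
    "feature_ablation",
    "occlusion",
    "arch_detect",
    "glassbox",
    "random_ranking",
    "aggregate_global_rank",
    "METHODS",
]


class CapabilityError(RuntimeError):
    """The model lacks a capability (gradients, glassbox weights) the method needs."""


@dataclass(frozen=True)
class BaselineSpec:
    """How to materialize the reference input x'.

    ``zeros`` — the all-zero vector; ``uniform_random`` — each coordinate
    U[0, 1]; ``fixed_vector`` — a user vector; ``distribution_sampler`` — a
    callable ``(rng, n, d) -> (n, d)`` drawing baselines.
    """

    mode: str = "uniform_random"
    n_draws: int = 1
    seed: int = 0
    vector: np.ndarray | None = None
    sampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None

    def draw(self, d: int, n_draws: int | None = None) -> np.ndarray:
        k = n_draws if n_draws is not None else self.n_draws
        rng = np.random.default_rng(self.seed)
        if self.mode == "zeros":
            return np.zeros((k, d))
        if self.mode == "uniform_random":
            return rng.random((k, d))
        if self.mode == "fixed_vector":
            if self.vector is None:
                raise ValueError("fixed_vector baseline needs a vector")
            return np.tile(np.asarray(self.vector, dtype=float)[None, :], (k, 1))
        if self.mode == "distribution_sampler":
            if self.sampler is None:
                raise ValueError("distribution_sampler baseline needs a sampler")
            return np.asarray(self.sampler(rng, k, d), dtype=float)
        raise ValueError(f"unknown baseline mode {self.mode!r}")

    def single(self, d: int) -> np.ndarray:
        return self.draw(d, 1)[0]


@dataclass(frozen=True)
class InterpreterConfig:
    ig_steps: int = 50
    shapley_draws: int = 25
    noise_std: float = 0.1
    noise_draws: int = 20
    occlusion_window: tuple[int, int] = (1, 1)  # (time span, feature span)
    input_shape: tuple[int, int] | None = None  # (T, F) grid for occlusion
    seed: int = 0

    def __post_init__(self):
        if min(self.ig_steps, self.shapley_draws, self.noise_draws) < 1:
            raise ValueError("step/draw counts must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class Attribution:
    signed: np.ndarray  # (n_samples, d_in)
    method: str
    model: ModelContract | None = None

    @property
    def importance(self) -> np.ndarray:
        return np.abs(self.signed)

    @property
    def d_in(self) -> int:
        return self.signed.shape[1]


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def _need_gradient(model: ModelContract, method: str):
    if not model.gradient_available:
        raise CapabilityError(f"{method} requires a gradient-capable model")


# ---------------------------------------------------------------------------
# gradient methods
# ---------------------------------------------------------------------------

def saliency(model, inputs, baseline: BaselineSpec | None = None,
             config: InterpreterConfig | None = None) -> Attribution:
    """Raw input gradient of the positive-class probability."""
    _need_gradient(model, "saliency")
    X = _as2d(inputs)
    return Attribution(model.input_gradient(X), "saliency", model)


def integrated_gradients(model, inputs, baseline: BaselineSpec | None = None,
                         config: InterpreterConfig | None = None) -> Attribution:
    """(x - x') times the path integral of gradients from x' to x.

    The integral is a midpoint Riemann sum over ``ig_steps`` points (error
    O(steps^-2)), so scores satisfy the completeness property
    sum_i IG_i ~= M(x) - M(x') to quadrature accuracy.
    """
    _need_gradient(model, "integrated_gradients")
    cfg = config or InterpreterConfig()
    X = _as2d(inputs)
    n, d = X.shape
    bl = (baseline or BaselineSpec()).single(d)
    total = np.zeros_like(X)
    alphas = (np.arange(cfg.ig_steps) + 0.5) / cfg.ig_steps  # midpoint nodes
    for a in alphas:
        total += model.input_gradient(bl[None, :] + a * (X - bl[None, :]))
    return Attribution((X - bl[None, :]) * total / cfg.ig_steps, "integrated_gradients", model)


def gradient_shap(model, inputs, baseline: BaselineSpec | None = None,
                  config: InterpreterConfig | None = None) -> Attribution:
    """Expected gradients at noisy interpolants times (x - mean baseline)."""
    _need_gradient(model, "gradient_shap")
    cfg = config or InterpreterConfig()
    bspec = baseline or BaselineSpec()
    X = _as2d(inputs)
    n, d = X.shape
    rng = np.random.default_rng(cfg.seed)
    draws = max(cfg.noise_draws, 1)
    baselines = bspec.draw(d, draws)
    grad_sum = np.zeros_like(X)
    for k in range(draws):
        noise = cfg.noise_std * rng.standard_normal(X.shape) if cfg.noise_std > 0 else 0.0
        alpha = rng.random((n, 1))
        point = baselines[k][None, :] + alpha * (X + noise - baselines[k][None, :])
        grad_sum += model.input_gradient(point)
    signed = grad_sum / draws * (X - baselines.mean(axis=0)[None, :])
    return Attribution(signed, "gradient_shap", model)


def saliency_noise_tunnel(model, inputs, baseline: BaselineSpec | None = None,
                          config: InterpreterConfig | None = None) -> Attribution:
    """Saliency averaged over Gaussian perturbations of the input (SmoothGrad)."""
    _need_gradient(model, "saliency_noise_tunnel")
    cfg = config or InterpreterConfig()
    X = _as2d(inputs)
    rng = np.random.default_rng(cfg.seed)
    total = np.zeros_like(X)
    for _ in range(cfg.noise_draws):
        noise = cfg.noise_std * rng.standard_normal(X.shape) if cfg.noise_std > 0 else 0.0
        total += model.input_gradient(X + noise)
    return Attribution(total / cfg.noise_draws, "saliency_noise_tunnel", model)


# ---------------------------------------------------------------------------
# perturbation methods
# ---------------------------------------------------------------------------

def shapley_sampling(model, inputs, baseline: BaselineSpec | None = None,
                     config: InterpreterConfig | None = None) -> Attribution:
    """Monte-Carlo Shapley values: average marginal contribution over sampled
    feature permutations, features switched between x and the baseline."""
    cfg = config or InterpreterConfig()
    X = _as2d(inputs)
    n, d = X.shape
    bl = (baseline or BaselineSpec()).single(d)
    rng = np.random.default_rng(cfg.seed)
    signed = np.zeros_like(X)
    for _ in range(cfg.shapley_draws):
        perm = rng.permutation(d)
        current = np.tile(bl[None, :], (n, 1))
        prev_out = model.predict_proba(current)
        for j in perm:
            current[:, j] = X[:, j]
            out = model.predict_proba(current)
            signed[:, j] += out - prev_out
            prev_out = out
    return Attribution(signed / cfg.shapley_draws, "shapley_sampling", model)


def feature_permutation(model, inputs, baseline: BaselineSpec | None = None,
                        config: InterpreterConfig | None = None) -> Attribution:
    """Shuffle each feature's column across the batch (one seeded shuffle per
    feature) and record the mean absolute output change, broadcast per sample."""
    cfg = config or InterpreterConfig()
    X = _as2d(inputs)
    n, d = X.shape
    rng = np.random.default_rng(cfg.seed)
    base_out = model.predict_proba(X)
    scores = np.zeros(d)
    for j in range(d):
        perm = rng.permutation(n)
        Xp = X.copy()
        Xp[:, j] = X[perm, j]
        scores[j] = np.abs(base_out - model.predict_proba(Xp)).mean()
    return Attribution(np.tile(scores[None, :], (n, 1)), "feature_permutation", model)


def feature_ablation(model, inputs, baseline: BaselineSpec | None = None,
                     config: InterpreterConfig | None = None) -> Attribution:
    """M(x) - M(x with x_i replaced by the baseline value), per feature."""
    X = _as2d(inputs)
    n, d = X.shape
    bl = (baseline or BaselineSpec()).single(d)
    base_out = model.predict_proba(X)
    signed = np.empty_like(X)
    for j in range(d):
        Xa = X.copy()
        Xa[:, j] = bl[j]
        signed[:, j] = base_out - model.predict_proba(Xa)
    return Attribution(signed, "feature_ablation", model)


def occlusion(model, inputs, baseline: BaselineSpec | None = None,
              config: InterpreterConfig | None = None) -> Attribution:
    """Slide a (time x feature) window over the (T, F) grid with stride 1;
    each cell's score is the mean output change over windows covering it."""
    cfg = config or InterpreterConfig()
    X = _as2d(inputs)
    n, d = X.shape
    if cfg.input_shape is not None:
        T, F = cfg.input_shape
    else:
        T, F = 1, d
    if T * F != d:
        raise ValueError(f"input_shape {cfg.input_shape} incompatible with d_in={d}")
    wt, wf = cfg.occlusion_window
    wt, wf = min(wt, T), min(wf, F)
    bl = (baseline or BaselineSpec()).single(d).reshape(T, F)
    Xg = X.reshape(n, T, F)
    base_out = model.predict_proba(X)
    sums = np.zeros((n, T, F))
    counts = np.zeros((T, F))
    for t0 in range(T - wt + 1):
        for f0 in range(F - wf + 1):
            Xo = Xg.copy()
            Xo[:, t0 : t0 + wt, f0 : f0 + wf] = bl[t0 : t0 + wt, f0 : f0 + wf]
            delta = base_out - model.predict_proba(Xo.reshape(n, d))
            sums[:, t0 : t0 + wt, f0 : f0 + wf] += delta[:, None, None]
            counts[t0 : t0 + wt, f0 : f0 + wf] += 1
    signed = (sums / counts[None, :, :]).reshape(n, d)
    return Attribution(signed, "occlusion", model)


def arch_detect(model, inputs, baseline: BaselineSpec | None = None,
                config: InterpreterConfig | None = None) -> Attribution:
    """Squared discrete difference quotient against the zero baseline.

    score_i = ((M(x_i e_i) - M(0)) / x_i)^2, with score 0 when |x_i| is
    numerically zero (the quotient is otherwise undefined there).
    """
    X = _as2d(inputs)
    n, d = X.shape
    zero = np.zeros(d)
    m0 = model.predict_proba(zero[None, :])[0]
    signed = np.zeros_like(X)
    for j in range(d):
        pts = np.zeros((n, d))
        pts[:, j] = X[:, j]
        out = model.predict_proba(pts)
        denom = X[:, j]
        ok = np.abs(denom) >= 1e-12
        signed[ok, j] = ((out[ok] - m0) / denom[ok]) ** 2
    return Attribution(signed, "arch_detect", model)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def glassbox(model, inputs=None, baseline=None, config=None) -> Attribution:
    """Broadcast the model's own importance weights to every sample."""
    if not model.glassbox_available:
        raise CapabilityError("model does not provide glassbox importance")
    w = np.asarray(model.glassbox_importance(), dtype=float)
    n = len(_as2d(inputs)) if inputs is not None else 1
    return Attribution(np.tile(w[None, :], (n, 1)), "glassbox", model)


def random_ranking(d_in: int, seed: int, n_samples: int = 1) -> Attribution:
    """Per-sample random permutation of ranks, as an importance baseline.

    The score of a feature is d_in + 1 - rank, so higher = more important and
    the induced ordering is the seeded permutation itself.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty((n_samples, d_in))
    for i in range(n_samples):
        scores[i] = rng.permutation(d_in) + 1.0
    return Attribution(scores, "random")


def aggregate_global_rank(attr: Attribution) -> np.ndarray:
    """Global feature ordering: rank per sample, average ranks, sort ascending.

    Ranks are 1 = most important with ties broken toward the lower feature
    index; the returned array lists feature indices from globally most to
    least important.
    """
    ranks = ordinal_rank(attr.importance)
    avg = ranks.mean(axis=0)
    return np.argsort(avg, kind="stable")


METHODS: dict[str, Callable] = {
    "saliency": saliency,
    "integrated_gradients": integrated_gradients,
    "gradient_shap": gradient_shap,
    "saliency_noise_tunnel": saliency_noise_tunnel,
    "shapley_sampling": shapley_sampling,
    "feature_permutation": feature_permutation,
    "feature_ablation": feature_ablation,
    "occlusion": occlusion,
    "arch_detect": arch_detect,
    "glassbox": glassbox,
}
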