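"""Multi-headed MLP for conditional average treatment effect estimation.

The network is a T-learner variant whose per-arm outcome models share a
common trunk: one shared ReLU hidden layer feeds one arm-specific ReLU hidden
layer plus a scalar output per treatment arm. Each head predicts the
potential-outcome EDSS slope mu_t(x); the CATE estimate for a (treatment,
control) pair is -(mu_t(x) - mu_c(x)), sign-flipped so that positive values
mean predicted benefit (slower worsening on treatment).

Training is plain mini-batch gradient descent with momentum on the weighted
factual loss (only the head matching a patient's allocated arm contributes,
weighted by n_s/(m*n_t) to offset allocation imbalance), with dropout, L2
penalty and a max-norm constraint on incoming weight vectors. Implemented
directly in numpy: manual forward/backward passes, fully deterministic under
a fixed seed.

Model selection uses 4-fold cross-validation with per-fold early stopping;
the early-stopped fold models form the inference ensemble, and validation
metrics are "crogged" (all out-of-fold predictions pooled before computing a
single MSE / AD_wabc). Random hyperparameter search selects the candidate
with the best crogged AD_wabc among those within one SD of the best crogged
MSE. Transfer learning pre-trains a 5-headed model on an RRMS-like cohort,
freezes the trunk, and fine-tunes fresh heads on the progressive-MS cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    DivergenceError,
    ParameterError,
    StratificationError,
    ValidationError,
)
from . import survival_eval


@dataclass(frozen=True)
class HyperParams:
    """Tunable optimization/architecture settings for one training run."""

    hidden_width: int = 64
    learning_rate: float = 0.02
    momentum: float = 0.9
    l2: float = 1e-4
    dropout: float = 0.1
    max_norm: float = 3.0
    batch_size: int = 64
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.hidden_width < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("width, batch size and epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ParameterError("dropout probability must be in [0, 1)")
        if self.max_norm <= 0 or self.learning_rate <= 0:
            raise ParameterError("max_norm and learning_rate must be positive")


#: default random-search space for the six tuned hyperparameters
DEFAULT_SEARCH_SPACE: dict = {
    "learning_rate": ("log_uniform", 1e-4, 1e-1),
    "momentum": ("uniform", 0.5, 0.99),
    "l2": ("log_uniform", 1e-6, 1e-2),
    "hidden_width": ("choice", (16, 32, 64, 128)),
    "max_norm": ("uniform", 1.0, 5.0),
    "dropout": ("uniform", 0.0, 0.5),
}


def _he_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / shape[0])
    return rng.uniform(-limit, limit, size=shape)


class MultiHeadMLP:
    """Shared trunk + per-arm heads; parameters are plain numpy arrays."""

    def __init__(self, n_features: int, arm_ids: Sequence[str], hidden_width: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.arm_ids = tuple(arm_ids)
        self.n_features = n_features
        self.hidden_width = hidden_width
        w = hidden_width
        self.params = {
            "trunk_W": _he_uniform(rng, (n_features, w)),
            "trunk_b": np.zeros(w),
        }
        for arm in self.arm_ids:
            self.params[f"{arm}_W1"] = _he_uniform(rng, (w, w))
            self.params[f"{arm}_b1"] = np.zeros(w)
            self.params[f"{arm}_W2"] = _he_uniform(rng, (w, 1))
            self.params[f"{arm}_b2"] = np.zeros(1)
        self.trunk_frozen = False

    # -- inference -----------------------------------------------------------

    def arm_index(self, arm: str) -> int:
        try:
            return self.arm_ids.index(arm)
        except ValueError:
            raise ValidationError(f"arm {arm!r} not registered on this model") from None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Potential-outcome predictions, shape (n, n_arms), dropout off."""
        X = np.asarray(X, dtype=float)
        h0 = np.maximum(X @ self.params["trunk_W"] + self.params["trunk_b"], 0.0)
        out = np.empty((X.shape[0], len(self.arm_ids)))
        for a, arm in enumerate(self.arm_ids):
            h1 = np.maximum(h0 @ self.params[f"{arm}_W1"] + self.params[f"{arm}_b1"], 0.0)
            out[:, a] = (h1 @ self.params[f"{arm}_W2"] + self.params[f"{arm}_b2"])[:, 0]
        return out

    def predict_cate(self, X: np.ndarray, treatment_arm: str, control_arm: str) -> np.ndarray:
        """Benefit-positive CATE: -(mu_treatment - mu_control)."""
        preds = self.predict(X)
        return -(preds[:, self.arm_index(treatment_arm)] - preds[:, self.arm_index(control_arm)])

    # -- training step -------------------------------------------------------

    def _batch_step(self, X, y, alloc_idx, weights, hp: HyperParams, velocity, rng):
        """One SGD-with-momentum update on the weighted factual loss.

        Returns the batch's weighted factual MSE (pre-update forward pass).
        """
        n = X.shape[0]
        p = self.params
        drop = hp.dropout
        h0_pre = X @ p["trunk_W"] + p["trunk_b"]
        h0 = np.maximum(h0_pre, 0.0)
        if drop > 0:
            mask0 = (rng.random(h0.shape) >= drop) / (1.0 - drop)
            h0d = h0 * mask0
        else:
            mask0 = None
            h0d = h0

        grads = {k: None for k in p}
        d_h0d = np.zeros_like(h0d)
        loss = 0.0
        for a, arm in enumerate(self.arm_ids):
            rows = np.nonzero(alloc_idx == a)[0]
            if rows.size == 0:
                continue
            W1, b1 = p[f"{arm}_W1"], p[f"{arm}_b1"]
            W2, b2 = p[f"{arm}_W2"], p[f"{arm}_b2"]
            h1_pre = h0d[rows] @ W1 + b1
            h1 = np.maximum(h1_pre, 0.0)
            if drop > 0:
                mask1 = (rng.random(h1.shape) >= drop) / (1.0 - drop)
                h1d = h1 * mask1
            else:
                h1d = h1
            out = (h1d @ W2 + b2)[:, 0]
            err = out - y[rows]
            w = weights[a]
            loss += float(w * np.sum(err**2))
            d_out = (2.0 * w / n) * err  # dL/d out
            grads[f"{arm}_W2"] = h1d.T @ d_out[:, None]
            grads[f"{arm}_b2"] = np.array([d_out.sum()])
            d_h1d = d_out[:, None] @ W2.T
            d_h1 = d_h1d * mask1 if drop > 0 else d_h1d
            d_h1pre = d_h1 * (h1_pre > 0)
            grads[f"{arm}_W1"] = h0d[rows].T @ d_h1pre
            grads[f"{arm}_b1"] = d_h1pre.sum(axis=0)
            d_h0d[rows] += d_h1pre @ W1.T
        loss /= n

        if not self.trunk_frozen:
            d_h0 = d_h0d * mask0 if drop > 0 else d_h0d
            d_h0pre = d_h0 * (h0_pre > 0)
            grads["trunk_W"] = X.T @ d_h0pre
            grads["trunk_b"] = d_h0pre.sum(axis=0)

        for key, g in grads.items():
            if g is None:
                continue
            if p[key].ndim == 2:  # L2 penalty on weight matrices, not biases
                g = g + hp.l2 * p[key]
            v = velocity[key]
            v *= hp.momentum
            v -= hp.learning_rate * g
            p[key] += v
            # max-norm on incoming weight vectors (columns) of weight matrices
            if p[key].ndim == 2:
                norms = np.linalg.norm(p[key], axis=0)
                over = norms > hp.max_norm
                if over.any():
                    p[key][:, over] *= hp.max_norm / norms[over]
        return loss

    def copy(self) -> "MultiHeadMLP":
        new = MultiHeadMLP.__new__(MultiHeadMLP)
        new.arm_ids = self.arm_ids
        new.n_features = self.n_features
        new.hidden_width = self.hidden_width
        new.params = {k: v.copy() for k, v in self.params.items()}
        new.trunk_frozen = self.trunk_frozen
        return new

    def trunk_state(self) -> dict[str, np.ndarray]:
        return {k: self.params[k].copy() for k in ("trunk_W", "trunk_b")}

    def set_trunk(self, state: Mapping[str, np.ndarray], freeze: bool = False) -> None:
        if state["trunk_W"].shape != self.params["trunk_W"].shape:
            raise ValidationError("trunk shape mismatch between models")
        for k in ("trunk_W", "trunk_b"):
            self.params[k] = np.array(state[k], copy=True)
        self.trunk_frozen = freeze

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arm_ids": list(self.arm_ids),
            "n_features": self.n_features,
            "hidden_width": self.hidden_width,
            "trunk_frozen": self.trunk_frozen,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiHeadMLP":
        model = cls.__new__(cls)
        model.arm_ids = tuple(d["arm_ids"])
        model.n_features = int(d["n_features"])
        model.hidden_width = int(d["hidden_width"])
        model.trunk_frozen = bool(d["trunk_frozen"])
        model.params = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
        return model


def compute_loss_weights(allocations: Sequence[str], arm_ids: Sequence[str]) -> np.ndarray:
    """Per-arm factual-loss weights n_s/(m*n_t); indexable by arm position."""
    alloc = np.asarray(allocations)
    n_s = alloc.size
    m = len(arm_ids)
    weights = np.empty(m)
    for a, arm in enumerate(arm_ids):
        n_t = int((alloc == arm).sum())
        if n_t == 0:
            raise ValidationError(f"arm {arm!r} has no allocated patients")
        weights[a] = n_s / (m * n_t)
    return weights


def weighted_factual_loss(predictions, targets, allocations, weights, arm_ids=None) -> float:
    """Mean over patients of w(t_i) * (mu_{t_i}(x_i) - y_i)^2.

    ``predictions`` is (n, n_arms); only the allocated head's prediction
    enters each patient's term. ``weights`` may be the per-arm array from
    :func:`compute_loss_weights` or a mapping arm -> weight.
    """
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    alloc = np.asarray(allocations)
    if arm_ids is None:
        arm_ids = sorted(set(alloc))
    arm_pos = {arm: a for a, arm in enumerate(arm_ids)}
    try:
        idx = np.array([arm_pos[a] for a in alloc])
    except KeyError as e:
        raise ValidationError(f"allocation {e.args[0]!r} outside the arm registry") from None
    if isinstance(weights, Mapping):
        w = np.array([weights[a] for a in alloc], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)[idx]
    factual = preds[np.arange(y.size), idx]
    return float(np.mean(w * (factual - y) ** 2))


def _factual_mse(model: MultiHeadMLP, X, y, alloc_idx) -> float:
    preds = model.predict(X)
    factual = preds[np.arange(y.size), alloc_idx]
    return float(np.mean((factual - y) ** 2))


def _stratified_batches(alloc_idx, batch_size, rng):
    """Per-epoch mini-batches preserving arm proportions.

    Each arm's indices are shuffled, spread evenly over [0, 1) by within-arm
    rank, and the pooled order is chunked; the final short batch is kept.
    """
    fractions, order = [], []
    for a in np.unique(alloc_idx):
        rows = np.nonzero(alloc_idx == a)[0]
        perm = rng.permutation(rows)
        fractions.append((np.arange(perm.size) + rng.random(perm.size)) / perm.size)
        order.append(perm)
    fractions = np.concatenate(fractions)
    order = np.concatenate(order)
    pooled = order[np.argsort(fractions, kind="stable")]
    return [pooled[i : i + batch_size] for i in range(0, pooled.size, batch_size)]


def train_fold(
    X_train,
    y_train,
    alloc_train,
    X_val,
    y_val,
    alloc_val,
    hp: HyperParams,
    arm_ids: Sequence[str],
    init_model: MultiHeadMLP | None = None,
    freeze_trunk: bool = False,
) -> tuple[MultiHeadMLP, dict]:
    """Train one fold with early stopping on validation factual MSE.

    Returns the parameter snapshot from the best epoch and a history dict
    with per-epoch train/validation MSE and the selected epoch (1-based).
    """
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_train = np.asarray(y_train, float)
    y_val = np.asarray(y_val, float)
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValidationError("training and validation splits must be non-empty")

    arm_pos = {arm: a for a, arm in enumerate(arm_ids)}
    tr_idx = np.array([arm_pos[a] for a in np.asarray(alloc_train)])
    va_idx = np.array([arm_pos[a] for a in np.asarray(alloc_val)])
    weights = compute_loss_weights(alloc_train, arm_ids)

    model = init_model.copy() if init_model is not None else MultiHeadMLP(
        X_train.shape[1], arm_ids, hp.hidden_width, seed=hp.seed
    )
    if freeze_trunk:
        model.trunk_frozen = True
    rng = np.random.default_rng(hp.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}

    history = {"train_mse": [], "val_mse": []}
    best_val, best_params, best_epoch = np.inf, None, 0
    for epoch in range(1, hp.max_epochs + 1):
        epoch_loss, n_batches = 0.0, 0
        for batch in _stratified_batches(tr_idx, hp.batch_size, rng):
            loss = model._batch_step(
                X_train[batch], y_train[batch], tr_idx[batch], weights, hp, velocity, rng
            )
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            epoch_loss += loss
            n_batches += 1
        val_mse = _factual_mse(model, X_val, y_val, va_idx)
        if not np.isfinite(val_mse):
            raise DivergenceError(epoch)
        history["train_mse"].append(epoch_loss / max(n_batches, 1))
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
    model.params = best_params
    history["best_epoch"] = best_epoch
    return model, history


@dataclass
class EnsembleModel:
    """Mean-aggregated ensemble of early-stopped fold models."""

    members: list[MultiHeadMLP]
    arm_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError("ensemble needs at least one member")
        for m in self.members:
            if m.arm_ids != tuple(self.arm_ids):
                raise ValidationError("all ensemble members must share the arm registry")

    def predict(self, X) -> np.ndarray:
        return np.mean([m.predict(np.asarray(X, float)) for m in self.members], axis=0)

    def predict_cate(self, X, treatment_arm: str, control_arm: str) -> np.ndarray:
        return np.mean(
            [m.predict_cate(np.asarray(X, float), treatment_arm, control_arm) for m in self.members],
            axis=0,
        )

    def to_dict(self) -> dict:
        return {"arm_ids": list(self.arm_ids), "members": [m.to_dict() for m in self.members]}

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            members=[MultiHeadMLP.from_dict(m) for m in d["members"]],
            arm_ids=tuple(d["arm_ids"]),
        )


def predict_cate(ensemble, X, treatment_arm: str, control_arm: str) -> np.ndarray:
    """Benefit-positive ensemble CATE estimate (module-level convenience)."""
    return ensemble.predict_cate(X, treatment_arm, control_arm)


def cross_validated_ensemble(
    X,
    y,
    allocations,
    hp: HyperParams,
    k: int = 4,
    survival: tuple | None = None,
    cate_arms: tuple[str, str] | None = None,
    arm_ids: Sequence[str] | None = None,
    init_trunks: Sequence[Mapping[str, np.ndarray]] | None = None,
    freeze_trunk: bool = False,
    ad_grid=None,
) -> tuple[EnsembleModel, dict]:
    """k-fold CV (stratified by arm) with per-fold early stopping.

    The fold models form the returned ensemble. Metrics are crogged: all
    out-of-fold factual predictions are pooled before computing a single MSE,
    and — when ``survival`` = (times, events, treated) and ``cate_arms`` are
    given — a single out-of-fold AD_wabc. Per-fold validation MSEs are kept
    for the one-SD selection rule.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    alloc = np.asarray(allocations)
    if k < 2:
        raise ParameterError("k must be at least 2")
    if arm_ids is None:
        arm_ids = tuple(dict.fromkeys(alloc))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=hp.seed % (2**32))
    members, fold_mses = [], []
    oof_pred = np.full(y.size, np.nan)
    oof_cate = np.full(y.size, np.nan)
    for fold, (tr, va) in enumerate(skf.split(X, alloc)):
        if set(alloc[tr]) != set(arm_ids) or not set(alloc[va]) <= set(arm_ids):
            raise StratificationError(f"fold {fold} is missing a treatment arm")
        fold_hp = replace(hp, seed=hp.seed + fold)
        init_model = None
        if init_trunks is not None:
            init_model = MultiHeadMLP(X.shape[1], arm_ids, hp.hidden_width, seed=fold_hp.seed)
            init_model.set_trunk(init_trunks[fold % len(init_trunks)], freeze=freeze_trunk)
        model, _ = train_fold(
            X[tr], y[tr], alloc[tr], X[va], y[va], alloc[va],
            fold_hp, arm_ids, init_model=init_model, freeze_trunk=freeze_trunk,
        )
        members.append(model)
        arm_pos = {arm: a for a, arm in enumerate(arm_ids)}
        va_idx = np.array([arm_pos[a] for a in alloc[va]])
        preds = model.predict(X[va])
        oof_pred[va] = preds[np.arange(va.size), va_idx]
        fold_mses.append(float(np.mean((oof_pred[va] - y[va]) ** 2)))
        if cate_arms is not None:
            oof_cate[va] = model.predict_cate(X[va], *cate_arms)

    metrics = {
        "crogged_mse": float(np.mean((oof_pred - y) ** 2)),
        "fold_mses": fold_mses,
        "oof_predictions": oof_pred,
    }
    if cate_arms is not None:
        metrics["oof_cate"] = oof_cate
        if survival is not None:
            times, events, treated = survival
            curve = survival_eval.ad_curve(oof_cate, times, events, treated, grid=ad_grid)
            metrics["crogged_ad_wabc"] = survival_eval.ad_wabc(curve)
    return EnsembleModel(members=members, arm_ids=tuple(arm_ids)), metrics


# -- hyperparameter search ---------------------------------------------------


@dataclass
class SearchResult:
    candidates: list[dict] = field(default_factory=list)
    selected_index: int = -1

    @property
    def selected(self) -> dict:
        return self.candidates[self.selected_index]


def sample_hyperparams(space: Mapping, rng: np.random.Generator, base: HyperParams) -> HyperParams:
    kwargs = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            kwargs[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log_uniform":
            kwargs[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "choice":
            kwargs[name] = type(spec[1][0])(rng.choice(np.asarray(spec[1])))
        else:
            raise ParameterError(f"unknown search distribution {kind!r}")
    return replace(base, **kwargs)


def apply_one_sd_rule(crogged_mses, fold_mses_per_candidate, ad_wabcs) -> int:
    """Pick the candidate with the best AD_wabc among those whose crogged MSE
    lies within one SD (of the best candidate's per-fold MSEs) of the minimum.
    """
    mses = np.asarray(crogged_mses, float)
    best = int(np.argmin(mses))
    sd = float(np.std(np.asarray(fold_mses_per_candidate[best], float), ddof=1))
    eligible = np.nonzero(mses <= mses[best] + sd)[0]
    ads = np.asarray(
        [ad_wabcs[i] if ad_wabcs[i] is not None else -np.inf for i in range(mses.size)]
    )
    if np.all(np.isneginf(ads[eligible])):
        return best
    return int(eligible[np.argmax(ads[eligible])])


def random_search_select(
    X,
    y,
    allocations,
    search_space: Mapping | None = None,
    n_candidates: int = 20,
    seed: int = 0,
    k: int = 4,
    survival: tuple | None = None,
    cate_arms: tuple[str, str] | None = None,
    base_hp: HyperParams | None = None,
    **cv_kwargs,
) -> SearchResult:
    """Random hyperparameter search with the crogged one-SD selection rule."""
    if n_candidates < 1:
        raise ParameterError("need at least one candidate")
    space = DEFAULT_SEARCH_SPACE if search_space is None else search_space
    rng = np.random.default_rng(seed)
    base = base_hp or HyperParams(seed=seed)
    result = SearchResult()
    for _ in range(n_candidates):
        hp = sample_hyperparams(space, rng, base)
        _, metrics = cross_validated_ensemble(
            X, y, allocations, hp, k=k, survival=survival, cate_arms=cate_arms, **cv_kwargs
        )
        result.candidates.append(
            {
                "hp": hp,
                "crogged_mse": metrics["crogged_mse"],
                "fold_mses": metrics["fold_mses"],
                "crogged_ad_wabc": metrics.get("crogged_ad_wabc"),
            }
        )
    result.selected_index = apply_one_sd_rule(
        [c["crogged_mse"] for c in result.candidates],
        [c["fold_mses"] for c in result.candidates],
        [c["crogged_ad_wabc"] for c in result.candidates],
    )
    return result


# -- transfer learning -------------------------------------------------------


@dataclass
class FineTuneResult:
    """Fine-tuned ensemble plus the pre-trained one it inherited trunks from."""

    ensemble: EnsembleModel
    pretrained: EnsembleModel
    metrics: dict


def pretrain_and_finetune(
    rrms: tuple,
    ppms: tuple,
    hp_pre: HyperParams,
    hp_fine: HyperParams,
    k: int = 4,
    survival: tuple | None = None,
    cate_arms: tuple[str, str] = ("treatment", "placebo"),
    rrms_arm_ids: Sequence[str] | None = None,
    ppms_arm_ids: Sequence[str] | None = None,
) -> FineTuneResult:
    """Two-phase transfer scheme.

    Phase 1 trains a multi-headed model (one head per RRMS arm, typically 5)
    on RRMS slope labels via the CV-ensemble machinery. Phase 2 copies each
    fold member's trunk, freezes it, attaches freshly initialized heads for
    the two progressive-MS arms, and trains only the head parameters.
    ``rrms`` and ``ppms`` are (X, y, allocations) triples.
    """
    if hp_pre.hidden_width != hp_fine.hidden_width:
        raise ParameterError("pre-training and fine-tuning must share the trunk width")
    X_r, y_r, alloc_r = rrms
    X_p, y_p, alloc_p = ppms
    pre_ensemble, _ = cross_validated_ensemble(
        X_r, y_r, alloc_r, hp_pre, k=k, arm_ids=rrms_arm_ids
    )
    trunks = [m.trunk_state() for m in pre_ensemble.members]
    fine_ensemble, metrics = cross_validated_ensemble(
        X_p, y_p, alloc_p, hp_fine, k=k,
        survival=survival, cate_arms=cate_arms, arm_ids=ppms_arm_ids,
        init_trunks=trunks, freeze_trunk=True,
    )
    return FineTuneResult(ensemble=fine_ensemble, pretrained=pre_ensemble, metrics=metrics)
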