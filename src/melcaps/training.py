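"""Training protocol: optimizers, plateau decay, CV planning, TTA prediction.

The published protocol trains for 150 epochs with mini-batches of 8,
Xavier initialisation, and one of three optimizers at their recommended
rates (SGD 0.01, RMSProp 0.001 with beta1 0.9, ADAM 0.001 with beta1 0.9
and beta2 0.999); for the non-adaptive optimizer the learning rate is
multiplied by 0.2 whenever the monitored performance plateaus.  Evaluation
averages a 3-times repeated stratified 10-fold cross-validation.

Balancing happens inside each training fold only — the test fold is never
augmented for balance — and every source of randomness (fold assignment,
shuffling, augmentation draws) is seeded so a run is exactly repeatable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augmentation import (
    AugmentationPolicy,
    balance_by_augmentation,
    expand_test_image,
    lengths_to_probabilities,
    soft_vote,
)
from .capsule_core import MarginLossParams
from .data import LabeledImageSet
from .evaluation import ScoredPredictions, auc, mcc
from .network import Model

__all__ = [
    "OptimizerConfig",
    "TrainConfig",
    "CVPlan",
    "PRIMARY_CAPS_GRID",
    "CLASS_CAPS_GRID",
    "hypertuning_grid",
    "make_cv_folds",
    "plateau_scheduler",
    "train_model",
    "predict_with_tta",
]

#: Hyper-tuning grid of the two capsule dimensions.
PRIMARY_CAPS_GRID = (8, 16, 24, 32)
CLASS_CAPS_GRID = (16, 32, 48, 64)


def hypertuning_grid() -> list[tuple[int, int]]:
    """All (primary caps dim, class caps features) combinations of the grid."""
    return list(itertools.product(PRIMARY_CAPS_GRID, CLASS_CAPS_GRID))


@dataclass(frozen=True)
class OptimizerConfig:
    """Optimizer name and rates (defaults per the study configuration)."""

    name: str = "SGD"
    alpha: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999

    def __post_init__(self) -> None:
        if self.name.upper() not in ("SGD", "RMSPROP", "ADAM"):
            raise ValueError(f"unknown optimizer {self.name!r}")
        if self.alpha <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def sgd(cls) -> "OptimizerConfig":
        return cls("SGD", 0.01)

    @classmethod
    def rmsprop(cls) -> "OptimizerConfig":
        return cls("RMSProp", 0.001, 0.9)

    @classmethod
    def adam(cls) -> "OptimizerConfig":
        return cls("ADAM", 0.001, 0.9, 0.999)

    @property
    def adaptive(self) -> bool:
        return self.name.upper() != "SGD"


@dataclass
class TrainConfig:
    """Training-loop contract (protocol defaults: 150 epochs, batch 8)."""

    epochs: int = 150
    batch_size: int = 8
    plateau_factor: float = 0.2
    plateau_patience: int = 10
    min_lr: float = 1e-6
    loss_mode: str = "margin"  # "margin" | "bce"
    validation_fraction: float = 0.1
    seed: int = 0
    margin_params: MarginLossParams = field(default_factory=MarginLossParams)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")


@dataclass
class CVPlan:
    """Fold assignments of a repeated stratified k-fold split.

    ``fold_of[r, i]`` is the test fold of sample i in repeat r.
    """

    repeats: int
    folds: int
    seeds: tuple[int, ...]
    fold_of: np.ndarray

    def split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of[repeat] == fold)
        train = np.flatnonzero(self.fold_of[repeat] != fold)
        return train, test


def make_cv_folds(labels, seeds: tuple[int, ...] = (0, 1, 2), folds: int = 10) -> CVPlan:
    """Repeated stratified k-fold plan (3 x 10 by default).

    Each repeat is an independent stratified partition; per-fold class
    proportions stay within one sample of the global proportions.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"degenerate stratification: smallest class has {counts.min()} "
            f"samples, fewer than {folds} folds"
        )
    fold_of = np.empty((len(seeds), n), dtype=int)
    for r, seed in enumerate(seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            fold_of[r, test_idx] = f
    return CVPlan(repeats=len(seeds), folds=folds, seeds=tuple(seeds), fold_of=fold_of)


def plateau_scheduler(
    history,
    patience: int,
    factor: float = 0.2,
    current_lr: float = 0.01,
    min_lr: float = 1e-6,
) -> float:
    """Reduce the learning rate when the monitored metric plateaus.

    ``history`` is the per-epoch metric sequence (lower is better).  If the
    best value of the last ``patience`` epochs does not improve on the
    best of the earlier epochs, the rate is multiplied by ``factor``
    (floored at ``min_lr``); otherwise it is returned unchanged.
    """
    history = list(history)
    if len(history) <= patience:
        return current_lr
    recent_best = min(history[-patience:])
    earlier_best = min(history[:-patience])
    if recent_best >= earlier_best:
        return max(current_lr * factor, min_lr)
    return current_lr


class _Optimizer:
    """SGD / RMSProp / ADAM parameter updates on the model's param dict."""

    def __init__(self, cfg: OptimizerConfig):
        self.cfg = cfg
        self.lr = cfg.alpha
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        name = self.cfg.name.upper()
        self._t += 1
        for key, p in params.items():
            g = grads.get(key)
            if g is None:
                continue
            if name == "SGD":
                p -= self.lr * g
            elif name == "RMSPROP":
                v = self._v.setdefault(key, np.zeros_like(p))
                v *= self.cfg.beta1
                v += (1 - self.cfg.beta1) * g**2
                p -= self.lr * g / (np.sqrt(v) + 1e-7)
            else:  # ADAM
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= self.cfg.beta1
                m += (1 - self.cfg.beta1) * g
                v *= self.cfg.beta2
                v += (1 - self.cfg.beta2) * g**2
                mhat = m / (1 - self.cfg.beta1**self._t)
                vhat = v / (1 - self.cfg.beta2**self._t)
                p -= self.lr * mhat / (np.sqrt(vhat) + 1e-7)


def _onehot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_model(
    model: Model,
    train_set: LabeledImageSet,
    cfg: TrainConfig,
    opt: OptimizerConfig | None = None,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch log as a DataFrame.

    Runs ``epochs x ceil(n / batch)`` update steps with seeded per-epoch
    shuffling.  A stratified ``validation_fraction`` split is carved from
    the training set to monitor the plateau scheduler (non-adaptive
    optimizer only).  Aborts with a diagnostic if the loss goes non-finite.
    """
    opt = opt or OptimizerConfig.sgd()
    optimizer = _Optimizer(opt)
    rng = np.random.default_rng(cfg.seed)

    n = len(train_set)
    idx = np.arange(n)
    val_idx = np.array([], dtype=int)
    if cfg.validation_fraction > 0 and n >= 20:
        n_val = max(2, int(round(cfg.validation_fraction * n)))
        order = rng.permutation(n)
        # stratified pick: alternate classes until n_val reached
        by_class = [list(order[train_set.labels[order] == c]) for c in (0, 1)]
        picks: list[int] = []
        while len(picks) < n_val and (by_class[0] or by_class[1]):
            for c in (0, 1):
                if by_class[c] and len(picks) < n_val:
                    picks.append(by_class[c].pop(0))
        val_idx = np.array(sorted(picks), dtype=int)
        idx = np.setdiff1d(idx, val_idx)

    x_train = np.stack([train_set.images[i] for i in idx])
    y_train = train_set.labels[idx]
    x_val = np.stack([train_set.images[i] for i in val_idx]) if len(val_idx) else None
    y_val = train_set.labels[val_idx] if len(val_idx) else None

    log_rows = []
    val_history: list[float] = []
    decoder_spec = model.spec.decoder if model.decoder_layers else None
    for epoch in range(cfg.epochs):
        ep_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, epoch])
        order = ep_rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            lengths, caps = model.forward_capsules(xb, train=True)
            loss, grad_len = model.loss_and_grad(
                lengths, _onehot(yb), cfg.loss_mode, cfg.margin_params
            )
            extra = None
            if decoder_spec is not None:
                recon = model.decode(caps, yb, train=True)
                target = _decoder_targets(xb, decoder_spec)
                loss += decoder_spec.reconstruction_loss_weight * float(
                    ((recon - target) ** 2).sum()
                ) / len(xb)
                g = (
                    2.0
                    * decoder_spec.reconstruction_loss_weight
                    * (recon - target).reshape(len(xb), -1)
                    / len(xb)
                )
                for lyr in reversed(model.decoder_layers):
                    g = lyr.backward(g)
                extra = (g.reshape(caps.shape)) * model._dec_mask
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            _backward_with_extra(model, grad_len, extra)
            optimizer.step(model.parameters(), model.gradients())
            losses.append(loss)

        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "n_steps": len(losses),
            "lr": optimizer.lr,
        }
        if x_val is not None:
            vl, _ = model.loss_and_grad(
                model.forward(x_val), _onehot(y_val), cfg.loss_mode, cfg.margin_params
            )
            val_history.append(vl)
            row["val_loss"] = vl
            if not opt.adaptive:
                optimizer.lr = plateau_scheduler(
                    val_history, cfg.plateau_patience, cfg.plateau_factor,
                    optimizer.lr, cfg.min_lr,
                )
        log_rows.append(row)
    return pd.DataFrame(log_rows)


def _decoder_targets(xb: np.ndarray, decoder_spec) -> np.ndarray:
    from skimage.transform import resize

    tgt = decoder_spec.reconstruction_target_size
    if xb.shape[1:] == tuple(tgt):
        return xb
    return np.stack(
        [resize(img, tgt, anti_aliasing=True, preserve_range=True) for img in xb]
    )


def _backward_with_extra(model: Model, grad_lengths, extra_caps_grad=None) -> None:
    """Backward pass, injecting the decoder's capsule gradient (if any)
    just below the length head where the decoder branches off."""
    from .network import Length

    g = grad_lengths
    for lyr in reversed(model.layers):
        g = lyr.backward(g)
        if extra_caps_grad is not None and isinstance(lyr, Length):
            g = g + extra_caps_grad
            extra_caps_grad = None


def predict_with_tta(
    model: Model,
    test_set: LabeledImageSet,
    policy: AugmentationPolicy,
    n_replicates: int = 10,
    include_original: bool = True,
) -> ScoredPredictions:
    """Soft-voted prediction over the TTA views of each test image."""
    probs, labels = [], []
    for img, iid in zip(test_set.images, test_set.ids):
        bundle = expand_test_image(img, policy, iid, n_replicates)
        views = np.stack(bundle.views(include_original))
        lengths = model.forward(views)
        p = lengths_to_probabilities(lengths)
        label, mean_p = soft_vote(p)
        probs.append(mean_p[1])
        labels.append(label)
    return ScoredPredictions(
        melanoma_prob=np.asarray(probs),
        pred_label=np.asarray(labels),
        true_label=test_set.labels,
    )


def run_cv(
    dataset: LabeledImageSet,
    build,  # callable seed -> Model
    cfg: TrainConfig,
    opt: OptimizerConfig,
    policy: AugmentationPolicy | None = None,
    seeds: tuple[int, ...] = (0, 1, 2),
    folds: int = 10,
    tta: bool = True,
) -> pd.DataFrame:
    """Full repeated-CV protocol: balance each training fold, train, score.

    Returns one row per (repeat, fold) with MCC, AUC and class counts.
    """
    plan = make_cv_folds(dataset.labels, seeds=seeds, folds=folds)
    policy = policy or AugmentationPolicy(seed=cfg.seed)
    rows = []
    for r in range(plan.repeats):
        for f in range(plan.folds):
            train_idx, test_idx = plan.split(r, f)
            train_fold = balance_by_augmentation(dataset.subset(train_idx), policy)
            test_fold = dataset.subset(test_idx)
            model = build(seed=cfg.seed + 1000 * r + f)
            train_model(model, train_fold, cfg, opt)
            if tta:
                preds = predict_with_tta(model, test_fold, policy)
            else:
                lengths = model.forward(np.stack(test_fold.images))
                p = lengths_to_probabilities(lengths)
                preds = ScoredPredictions(
                    melanoma_prob=p[:, 1],
                    pred_label=(p[:, 1] > p[:, 0]).astype(int),
                    true_label=test_fold.labels,
                )
            rows.append(
                {
                    "repeat": r,
                    "fold": f,
                    "mcc": mcc(preds.confusion()),
                    "auc": auc(preds),
                    "n_test_nevus": int((test_fold.labels == 0).sum()),
                    "n_test_melanoma": int((test_fold.labels == 1).sum()),
                }
            )
    return pd.DataFrame(rows)
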