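"""Scikit-learn estimator front end for the capsule-network classifier.

:class:`MelCapClassifier` wraps architecture construction, optional
balancing augmentation, training and (optionally TTA soft-voted)
prediction behind the standard ``fit`` / ``predict`` / ``predict_proba``
surface, so the model composes with sklearn pipelines, cross-validation
and metric utilities.  ``X`` is an (n, h, w, 3) float array of RGB images
with pixels in [0, 1]; ``y`` is binary (0 = nevus, 1 = melanoma).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .architecture import (
    ArchitectureSpec,
    baseline_capsnet_spec,
    default_melcap_spec,
    reduced_melcap_spec,
)
from .augmentation import (
    AugmentationPolicy,
    balance_by_augmentation,
    lengths_to_probabilities,
)
from .data import LabeledImageSet
from .network import build_model
from .training import OptimizerConfig, TrainConfig, predict_with_tta, train_model

__all__ = ["MelCapClassifier"]

_OPTIMIZERS = {
    "sgd": OptimizerConfig.sgd,
    "rmsprop": OptimizerConfig.rmsprop,
    "adam": OptimizerConfig.adam,
}


class MelCapClassifier(BaseEstimator, ClassifierMixin):
    """Capsule-network melanoma classifier with an Inception-style stem.

    Parameters
    ----------
    architecture : {"reduced", "melcap", "baseline"} or ArchitectureSpec
        Which network to build.  "reduced" (default) is the width-reduced
        stem for small images; "melcap" the full published geometry;
        "baseline" the single-conv capsule network.
    primary_caps_dim, class_caps_features : int
        Capsule dimensions (tuned values 16 and 64).
    routing_iterations : int
        Routing-by-agreement iterations between primary and class caps.
    epochs, batch_size : int
        Training-loop contract (protocol values 150 and 8; the default
        epochs here is a desk-scale 10).
    optimizer : {"sgd", "rmsprop", "adam"}
    learning_rate : float or None
        Overrides the optimizer's recommended rate when given.
    loss : {"margin", "bce"}
        Margin loss (default) or binary cross-entropy on capsule lengths.
    balance : bool
        Oversample the minority class with augmented copies before
        training.
    tta : bool
        Predict through 10-replicate test-time augmentation with soft
        voting instead of a single forward pass.
    random_state : int
        Seeds initialisation, shuffling, balancing and TTA draws.
    """

    def __init__(
        self,
        architecture="reduced",
        *,
        primary_caps_dim: int = 16,
        class_caps_features: int = 64,
        routing_iterations: int = 1,
        epochs: int = 10,
        batch_size: int = 8,
        optimizer: str = "adam",
        learning_rate: float | None = None,
        loss: str = "margin",
        balance: bool = True,
        tta: bool = False,
        n_tta: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.primary_caps_dim = primary_caps_dim
        self.class_caps_features = class_caps_features
        self.routing_iterations = routing_iterations
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.loss = loss
        self.balance = balance
        self.tta = tta
        self.n_tta = n_tta
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_spec(self, input_size: int) -> ArchitectureSpec:
        if isinstance(self.architecture, ArchitectureSpec):
            return self.architecture
        kw = dict(
            primary_caps_dim=self.primary_caps_dim,
            class_caps_features=self.class_caps_features,
            routing_iterations=self.routing_iterations,
        )
        if self.architecture == "reduced":
            return reduced_melcap_spec(input_size, **kw)
        if self.architecture == "melcap":
            return default_melcap_spec(input_size, **kw)
        if self.architecture == "baseline":
            return baseline_capsnet_spec(
                self.primary_caps_dim,
                self.class_caps_features,
                input_size=input_size,
                routing_iterations=self.routing_iterations,
            )
        raise ValueError(f"unknown architecture {self.architecture!r}")

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be an (n, h, w, 3) image array, got {X.shape}")
        if X.shape[0] == 0:
            raise ValueError("X is empty")
        return X

    def fit(self, X, y) -> "MelCapClassifier":
        X = self._validate_X(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be binary 0/1 (0 = nevus, 1 = melanoma)")
        self.classes_ = np.array([0, 1])

        spec = self._make_spec(X.shape[1])
        self.model_ = build_model(spec, seed=self.random_state)
        data = LabeledImageSet(images=list(X), labels=y)
        self._policy = AugmentationPolicy(seed=self.random_state)
        if self.balance and len(classes) == 2:
            data = balance_by_augmentation(data, self._policy)

        opt = _OPTIMIZERS[self.optimizer.lower()]()
        if self.learning_rate is not None:
            opt = OptimizerConfig(opt.name, self.learning_rate, opt.beta1, opt.beta2)
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            loss_mode=self.loss,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.history_ = train_model(self.model_, data, cfg, opt)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        if self.tta:
            data = LabeledImageSet(images=list(X), labels=np.zeros(len(X), dtype=int))
            preds = predict_with_tta(self.model_, data, self._policy, self.n_tta)
            p1 = preds.melanoma_prob
            return np.column_stack([1 - p1, p1])
        lengths = self.model_.forward(X)
        return lengths_to_probabilities(lengths)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # exact tie goes to nevus (class 0)
        return (proba[:, 1] > proba[:, 0]).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
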