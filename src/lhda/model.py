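"""Feature-weighted hyperplane nearest-neighbor (FHKNN) classification.

A test sample is assigned to the class whose local hyperplane — the convex
hull of the sample's ``k`` nearest training neighbors within that class — is
closest in the learned weighted Manhattan metric:

    c* = argmin_j d(x, LH_{c_j}(x | w))

Test-time hyperplanes never exclude training samples; leave-one-out exclusion
is a training-only device.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LHDAConfig
from .data import FeatureWeights, LabeledDataset
from .exceptions import ValidationError
from .hyperplane import hyperplane_distance
from .learner import TrainingTrace, fit_weights

__all__ = ["TrainedModel", "fit", "fhknn_predict", "predict_batch", "select_features"]

DEFAULT_TAU = 0.01


def select_features(w, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Indices of features whose weight reaches ``tau`` of the maximum.

    A relative cut is scale-free (weights are only defined up to a positive
    factor).  ``tau = 0`` keeps every strictly positive weight.
    """
    w = np.asarray(w, dtype=float)
    if not np.any(w > 0):
        raise ValidationError("all-zero weight vector")
    if not 0.0 <= tau <= 1.0:
        raise ValidationError(f"tau must be in [0, 1], got {tau}")
    if tau == 0.0:
        return np.flatnonzero(w > 0)
    return np.flatnonzero(w >= tau * w.max())


@dataclass(frozen=True)
class TrainedModel:
    """A training set, learned feature weights, and the classifier config."""

    dataset: LabeledDataset
    weights: FeatureWeights
    config: LHDAConfig
    tau: float = DEFAULT_TAU
    selected_feature_indices: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "selected_feature_indices",
            select_features(self.weights.w, self.tau),
        )

    @property
    def n_selected(self) -> int:
        return self.selected_feature_indices.size


def fit(
    dataset: LabeledDataset,
    config: LHDAConfig | None = None,
    tau: float = DEFAULT_TAU,
) -> tuple[TrainedModel, TrainingTrace]:
    """Learn feature weights on ``dataset`` and wrap them as a model."""
    if config is None:
        config = LHDAConfig()
    weights, trace = fit_weights(dataset, config)
    return TrainedModel(dataset, weights, config, tau), trace


def fhknn_predict(x, model: TrainedModel) -> int:
    """Label of the class-local hyperplane closest to ``x``.

    One hyperplane is built per class from the model's training set (no
    exclusion); distance ties resolve to the smallest class label.
    """
    best_label, best_dist = None, np.inf
    for label in model.dataset.class_labels:  # ascending, so ties -> smallest
        hp = hyperplane_distance(
            x, model.dataset, int(label), model.config.k, model.weights.w,
            mode=model.config.solver_mode,
        )
        if hp.distance < best_dist:
            best_label, best_dist = int(label), hp.distance
    return best_label


def predict_batch(X, model: TrainedModel) -> np.ndarray:
    """Vector of :func:`fhknn_predict` labels for the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([fhknn_predict(x, model) for x in X], dtype=int)
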