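"""Cross-validation harnesses and the two-sample t-test prefilter.

Three evaluation protocols are provided.  ``loocv`` and ``kfold_cv`` evaluate
the hyperplane classifier with a *fixed* weight vector (weights learned once,
then the classifier assessed in the weighted space).  ``inner_loocv_loop``
re-runs the entire weight-learning procedure inside every split, so no
information from a held-out sample ever touches weight learning — the
leakage-free protocol appropriate for reporting feature-selection
performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold

from .config import LHDAConfig
from .data import FeatureWeights, LabeledDataset
from .exceptions import ConfigurationError, ValidationError
from .hyperplane import hyperplane_distance
from .learner import fit_weights
from .model import TrainedModel, predict_batch

__all__ = ["CVResult", "loocv", "kfold_cv", "inner_loocv_loop", "ttest_prefilter"]


@dataclass
class CVResult:
    """Predictions and summary statistics of one cross-validation run."""

    scheme: str
    sample_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    class_labels: np.ndarray
    seed: int | None = None
    config: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    @property
    def confusion(self) -> np.ndarray:
        """c x c count matrix, rows = true class, columns = predicted."""
        return _sk_confusion(self.y_true, self.y_pred, labels=self.class_labels)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "class_labels": self.class_labels.tolist(),
            "n_samples": int(self.y_true.size),
            "seed": self.seed,
            "config": self.config,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_predictions_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_index\ttrue_label\tpredicted_label\n")
            for i, yt, yp in zip(self.sample_indices, self.y_true, self.y_pred):
                fh.write(f"{i}\t{yt}\t{yp}\n")


def _predict_held_out(x, dataset, w, config, exclude_index):
    """Classify one sample against the dataset with itself excluded."""
    best_label, best_dist = None, np.inf
    for label in dataset.class_labels:
        hp = hyperplane_distance(
            x, dataset, int(label), config.k, w,
            mode=config.solver_mode, exclude_index=exclude_index,
        )
        if hp.distance < best_dist:
            best_label, best_dist = int(label), hp.distance
    return best_label


def loocv(
    dataset: LabeledDataset, weights: FeatureWeights, config: LHDAConfig
) -> CVResult:
    """Leave-one-out evaluation of the classifier at fixed weights."""
    n = dataset.n_samples
    preds = np.empty(n, dtype=int)
    for i in range(n):
        preds[i] = _predict_held_out(
            dataset.features[i], dataset, weights.w, config, exclude_index=i
        )
    return CVResult(
        scheme="loocv",
        sample_indices=np.arange(n),
        y_true=dataset.labels.copy(),
        y_pred=preds,
        class_labels=dataset.class_labels,
        config=config.to_dict(),
    )


def kfold_cv(
    dataset: LabeledDataset,
    weights: FeatureWeights,
    config: LHDAConfig,
    folds: int = 10,
    seed: int | None = None,
    stratified: bool = True,
) -> CVResult:
    """Seeded k-fold evaluation of the classifier at fixed weights.

    Stratified by default so each fold mirrors the class proportions (fold
    sizes per class differ by at most one); ``stratified=False`` gives plain
    shuffled folds, which also admits ``folds == n_samples``.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if stratified:
        for label in dataset.class_labels:
            size = int((dataset.labels == label).sum())
            if size < folds:
                raise ConfigurationError(
                    f"class {label} has {size} samples; stratified "
                    f"{folds}-fold CV needs at least {folds} per class"
                )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    idx_all, pred_all, true_all = [], [], []
    for train_idx, test_idx in splitter.split(dataset.features, dataset.labels):
        train = dataset.subset(train_idx)
        model = TrainedModel(train, weights, config)
        preds = predict_batch(dataset.features[test_idx], model)
        idx_all.append(test_idx)
        pred_all.append(preds)
        true_all.append(dataset.labels[test_idx])
    order = np.argsort(np.concatenate(idx_all))
    return CVResult(
        scheme=f"{folds}-fold" + ("" if stratified else "-unstratified"),
        sample_indices=np.concatenate(idx_all)[order],
        y_true=np.concatenate(true_all)[order],
        y_pred=np.concatenate(pred_all)[order],
        class_labels=dataset.class_labels,
        seed=seed,
        config=config.to_dict(),
    )


def inner_loocv_loop(dataset: LabeledDataset, config: LHDAConfig) -> CVResult:
    """Leave-one-out with weight learning re-run from scratch in every split.

    The held-out sample is removed *before* ``fit_weights`` runs, so the
    learned weights of each split are independent of it.  The per-split
    weight vectors are exposed under ``details["split_weights"]``.
    """
    n = dataset.n_samples
    preds = np.empty(n, dtype=int)
    split_weights = []
    for i in range(n):
        train = dataset.drop_sample(i)
        w_i, _ = fit_weights(train, config)
        model = TrainedModel(train, w_i, config)
        preds[i] = predict_batch(dataset.features[i], model)[0]
        split_weights.append(w_i.w)
    return CVResult(
        scheme="inner-loocv",
        sample_indices=np.arange(n),
        y_true=dataset.labels.copy(),
        y_pred=preds,
        class_labels=dataset.class_labels,
        config=config.to_dict(),
        details={"split_weights": split_weights},
    )


def ttest_prefilter(
    dataset: LabeledDataset,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[LabeledDataset, np.ndarray]:
    """Keep features that separate the two classes at level ``alpha``.

    Runs a per-feature two-sample t-test (pooled-variance Student form by
    default, Welch with ``equal_var=False``) and keeps features with
    ``p < alpha``, preserving column order.  Features with zero variance in
    both classes are dropped: their statistic is undefined.
    """
    labels = dataset.class_labels
    if labels.size != 2:
        raise ValidationError(
            f"t-test prefilter requires exactly 2 classes, got {labels.size}"
        )
    a = dataset.features[dataset.labels == labels[0]]
    b = dataset.features[dataset.labels == labels[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("each class needs at least 2 samples for a t-test")
    degenerate = (a.var(axis=0, ddof=1) == 0) & (b.var(axis=0, ddof=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        pvals = np.asarray(result.pvalue)
    keep = np.flatnonzero(~degenerate & (pvals < alpha))
    if keep.size == 0:
        raise ValidationError(
            f"no feature passes the t-test prefilter at alpha={alpha}"
        )
    return dataset.restrict_features(keep), keep
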