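"""Core containers: labeled sample-by-feature data and nonnegative feature weights.

A :class:`LabeledDataset` holds an ``N x D`` matrix of real-valued features
(rows are samples, columns are features such as genes), integer class labels,
and feature names.  A :class:`FeatureWeights` holds the per-feature importance
vector ``w`` together with its square-root parameterization ``v`` (``w = v**2``
elementwise), which is how nonnegativity is maintained during learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ValidationError

__all__ = ["LabeledDataset", "FeatureWeights"]


@dataclass(frozen=True)
class LabeledDataset:
    """N samples by D features with integer class labels.

    Parameters
    ----------
    features : ndarray of shape (N, D)
        Real-valued feature matrix; rows are samples.
    labels : ndarray of shape (N,)
        Integer class labels; every distinct value forms a class.
    feature_names : tuple of str, length D
        Column names. Generated automatically when omitted.
    label_names : tuple or None
        Optional original (pre-integer-mapping) label values, indexed by the
        position of each class in :attr:`class_labels`. Used by the I/O layer
        so written predictions carry the user's original labels.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple = ()
    label_names: tuple | None = None

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise DimensionError(f"features must be 2-D, got shape {X.shape}")
        n, d = X.shape
        if n < 2 or d < 1:
            raise ValidationError(f"need N >= 2 and D >= 1, got N={n}, D={d}")
        if y.shape != (n,):
            raise DimensionError(
                f"labels length {y.shape} does not match N={n}"
            )
        if not np.issubdtype(y.dtype, np.integer):
            if not np.all(y == y.astype(int)):
                raise ValidationError("labels must be integers")
            y = y.astype(int)
        names = self.feature_names
        if not names:
            width = len(str(d))
            names = tuple(f"f{j + 1:0{width}d}" for j in range(d))
        else:
            names = tuple(str(s) for s in names)
            if len(names) != d:
                raise DimensionError(
                    f"feature_names length {len(names)} does not match D={d}"
                )
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def class_labels(self) -> np.ndarray:
        """Sorted distinct label values."""
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.class_labels.size

    def class_indices(self, class_label: int) -> np.ndarray:
        """Ascending sample indices belonging to ``class_label``."""
        idx = np.flatnonzero(self.labels == class_label)
        if idx.size == 0:
            raise ValidationError(f"no samples with label {class_label}")
        return idx

    def subset(self, sample_indices) -> "LabeledDataset":
        """Row-restricted copy (keeps all features and names)."""
        sample_indices = np.asarray(sample_indices)
        return LabeledDataset(
            self.features[sample_indices],
            self.labels[sample_indices],
            self.feature_names,
            self.label_names,
        )

    def drop_sample(self, index: int) -> "LabeledDataset":
        keep = np.arange(self.n_samples) != index
        return self.subset(np.flatnonzero(keep))

    def restrict_features(self, feature_indices) -> "LabeledDataset":
        """Column-restricted copy, preserving original column order."""
        feature_indices = np.asarray(feature_indices)
        return LabeledDataset(
            self.features[:, feature_indices],
            self.labels,
            tuple(self.feature_names[j] for j in feature_indices),
            self.label_names,
        )


@dataclass(frozen=True)
class FeatureWeights:
    """Nonnegative per-feature weights ``w`` with square-root form ``v``.

    ``w = v * v`` holds exactly; nonnegativity of ``w`` is structural rather
    than enforced by clipping.  An all-zero vector is rejected because it
    yields a degenerate (identically zero) distance.
    """

    v: np.ndarray
    w: np.ndarray = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        if v.ndim != 1:
            raise DimensionError("v must be a 1-D vector")
        w = v * v
        if not np.any(w > 0):
            raise ValidationError("all-zero feature weights are invalid")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", w)

    @classmethod
    def from_w(cls, w) -> "FeatureWeights":
        """Build from a nonnegative weight vector (takes elementwise sqrt)."""
        w = np.asarray(w, dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be nonnegative")
        return cls(np.sqrt(w))

    @classmethod
    def uniform(cls, n_features: int) -> "FeatureWeights":
        """Uniform weights summing to one: ``w_j = 1/D``, ``v_j = 1/sqrt(D)``."""
        if n_features < 1:
            raise ValidationError("n_features must be >= 1")
        return cls(np.full(n_features, 1.0 / np.sqrt(n_features)))

    @property
    def n_features(self) -> int:
        return self.w.size

    def normalized(self) -> "FeatureWeights":
        """Rescale so the weights sum to one (for interpretation only)."""
        total = self.w.sum()
        return FeatureWeights(self.v / np.sqrt(total))
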