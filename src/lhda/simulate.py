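"""Synthetic benchmarks: the Fermat's Spiral two-class problem and Gaussian blobs.

The spiral benchmark stresses feature weighting: class labels are fully
determined by the first two features (two point-symmetric spiral arms,
``r = sqrt(theta)``), while an arbitrary number of irrelevant features drawn
i.i.d. from a zero-mean unit-variance Gaussian are appended.  A good feature
weighter should concentrate nearly all weight on the two informative
coordinates regardless of how many noise dimensions are added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset
from .exceptions import ValidationError

__all__ = ["SpiralConfig", "generate_fermat_spiral", "generate_blobs"]


@dataclass(frozen=True)
class SpiralConfig:
    """Parameters of the Fermat's Spiral generator.

    ``theta_range`` is the interval the spiral angle is drawn from
    (uniformly); the default ``[0.25, 4*pi]`` gives two full interleaved
    windings per arm while avoiding the degenerate origin.  When
    ``standardize`` is set the two informative features are rescaled to zero
    mean and unit variance so signal and noise columns share scale.
    """

    n_per_class: int = 200
    noise_dim: int = 0
    theta_range: tuple = (0.25, 4.0 * np.pi)
    seed: int | None = None
    standardize: bool = True

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.noise_dim < 0:
            raise ValidationError("noise_dim must be >= 0")
        lo, hi = self.theta_range
        if not hi > lo:
            raise ValidationError(f"empty theta_range {self.theta_range}")


def generate_fermat_spiral(config: SpiralConfig) -> LabeledDataset:
    """Two interleaved Fermat spiral arms plus Gaussian noise features.

    Class 1 points are ``(r cos(theta), r sin(theta))`` with
    ``r = sqrt(theta)`` and ``theta ~ U(theta_range)``; class 2 is the
    point-reflected arm ``(-x1, -x2)`` with independently drawn angles.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_class
    lo, hi = config.theta_range

    theta1 = rng.uniform(lo, hi, size=n)
    theta2 = rng.uniform(lo, hi, size=n)
    r1, r2 = np.sqrt(theta1), np.sqrt(theta2)
    arm1 = np.column_stack([r1 * np.cos(theta1), r1 * np.sin(theta1)])
    arm2 = -np.column_stack([r2 * np.cos(theta2), r2 * np.sin(theta2)])

    informative = np.vstack([arm1, arm2])
    if config.standardize:
        informative = (informative - informative.mean(axis=0)) / informative.std(
            axis=0
        )
    noise = rng.standard_normal(size=(2 * n, config.noise_dim))
    X = np.hstack([informative, noise])

    labels = np.concatenate([np.ones(n, dtype=int), np.full(n, 2, dtype=int)])
    names = ("spiral_1", "spiral_2") + tuple(
        f"noise_{j + 1:04d}" for j in range(config.noise_dim)
    )
    return LabeledDataset(X, labels, names)


def generate_blobs(
    n_per_class: int,
    n_classes: int = 2,
    informative_dims: int = 1,
    noise_dim: int = 0,
    separation: float = 5.0,
    seed: int | None = None,
) -> LabeledDataset:
    """Unit-variance Gaussian classes separated only along informative axes.

    Class ``c`` (``c = 0..n_classes-1``, labeled ``c + 1``) has mean
    ``c * separation`` on each of the first ``informative_dims`` coordinates
    and mean zero on the ``noise_dim`` remaining ones.  A plain fixture
    generator for unit tests; deterministic given ``seed``.
    """
    if n_per_class < 1 or n_classes < 2 or informative_dims < 1:
        raise ValidationError(
            "n_per_class >= 1, n_classes >= 2, informative_dims >= 1 required"
        )
    if noise_dim < 0:
        raise ValidationError("noise_dim must be >= 0")
    if separation <= 0:
        raise ValidationError("separation must be > 0")
    rng = np.random.default_rng(seed)
    d = informative_dims + noise_dim
    blocks, labels = [], []
    for c in range(n_classes):
        block = rng.standard_normal(size=(n_per_class, d))
        block[:, :informative_dims] += c * separation
        blocks.append(block)
        labels.append(np.full(n_per_class, c + 1, dtype=int))
    names = tuple(f"inf_{j + 1}" for j in range(informative_dims)) + tuple(
        f"noise_{j + 1:04d}" for j in range(noise_dim)
    )
    return LabeledDataset(np.vstack(blocks), np.concatenate(labels), names)
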