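"""Margin-based feature-weight learning.

The weight vector is learned by minimizing the sigmoid-smoothed leave-one-out
margin error of the hyperplane nearest-neighbor rule, with an l1 sparsity
penalty:

    J(w) = (1/N) sum_i S_beta(R(x_i)) + lam * ||w||_1,      w > 0

where ``R(x) = d(x, NH) / d(x, NM)`` is the ratio of the distances to the
nearest-hit hyperplane (built from the sample's own class, self excluded) and
the nearest-miss hyperplane (the closest foreign-class hyperplane), and
``S_beta(z) = 1 / (1 + exp(beta (1 - z)))`` smooths the 0/1 error step.

Nonnegativity is kept structural through the substitution ``w = v**2``, which
turns the l1 penalty into a smooth squared-l2 penalty on ``v``.  Learning
alternates, EM-style, between (a) re-estimating every sample's nearest-hit /
nearest-miss hyperplanes and their spanning coefficients under the current
weights and (b) a backtracking gradient step on ``v`` with the hyperplanes
frozen, using the closed-form gradient

    dJ/dv = (2 lam 1 + (2/N) Upsilon^T G) (*) v

with ``gamma_i = S'_beta(R_i) R_i`` and
``g_i = |x_i - s_NH| / d(x_i, NH) - |x_i - s_NM| / d(x_i, NM)``
(``(*)`` is the elementwise Hadamard product, ``s`` the hyperplane projection
points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import LHDAConfig
from .data import FeatureWeights, LabeledDataset
from .exceptions import ConfigurationError, ValidationError
from .hyperplane import LocalHyperplane, hyperplane_distance

__all__ = [
    "MarginTerms",
    "TrainingTrace",
    "sigmoid_step",
    "sigmoid_step_derivative",
    "margin_ratio",
    "compute_margin_terms",
    "frozen_objective",
    "penalized_objective",
    "objective_gradient",
    "univariate_screening_scores",
    "screening_init",
    "fit_weights",
]

logger = logging.getLogger(__name__)

_MAX_BACKTRACKS = 30


def sigmoid_step(z, beta: float):
    """Sigmoid surrogate of the unit-step error indicator.

    ``S_beta(z) = 1 / (1 + exp(beta (1 - z)))``; increasing in ``z`` with
    ``S_beta(1) = 0.5``.  Evaluated through :func:`scipy.special.expit` for
    numerical stability at large ``|beta (1 - z)|``.
    """
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    return expit(beta * (np.asarray(z, dtype=float) - 1.0))


def sigmoid_step_derivative(z, beta: float):
    """``S'_beta(z) = beta e^{beta(1-z)} / (1 + e^{beta(1-z)})^2``."""
    s = sigmoid_step(z, beta)
    return beta * s * (1.0 - s)


@dataclass
class MarginTerms:
    """Per-sample margin quantities at a fixed weight vector.

    Holds, for every training sample, the margin ratio ``R_i``, the gradient
    weights ``gamma_i = S'_beta(R_i) R_i``, the direction vectors ``g_i``
    (rows of ``G``), the fitted nearest-hit / nearest-miss hyperplanes, and
    the frozen absolute residuals ``|x_i - s|`` needed to re-evaluate the
    objective at new weights without re-fitting the hyperplanes.
    """

    R: np.ndarray                    # (N,) margin ratios
    gamma: np.ndarray                # (N,) S'(R) * R
    G: np.ndarray                    # (N, D) rows are g_i
    nh: list                         # LocalHyperplane per sample
    nm: list                         # LocalHyperplane per sample
    abs_nh: np.ndarray               # (N, D) |x_i - s_NH_i|
    abs_nm: np.ndarray               # (N, D) |x_i - s_NM_i|


@dataclass
class TrainingTrace:
    """Convergence diagnostics of one weight-learning run."""

    objective_values: list = field(default_factory=list)
    weight_snapshots: list | None = None
    converged: bool = False
    iterations_run: int = 0


def _nearest_hyperplanes(
    x, dataset: LabeledDataset, own_label: int, w, config: LHDAConfig,
    exclude_index: int | None,
) -> tuple[LocalHyperplane, LocalHyperplane]:
    """Nearest-hit and nearest-miss hyperplanes for one query.

    The hit comes from the query's own class (optionally excluding the query
    itself); the miss is the minimum-distance hyperplane over all foreign
    classes, ties resolved toward the smaller class label.
    """
    nh = hyperplane_distance(
        x, dataset, own_label, config.k, w,
        mode=config.solver_mode, exclude_index=exclude_index,
    )
    nm = None
    for label in dataset.class_labels:
        if label == own_label:
            continue
        cand = hyperplane_distance(
            x, dataset, int(label), config.k, w, mode=config.solver_mode
        )
        if nm is None or cand.distance < nm.distance:
            nm = cand
    if nm is None:
        raise ConfigurationError("dataset has a single class; no nearest miss")
    return nh, nm


def _ratio(d_nh: float, d_nm: float, cap: float) -> float:
    if d_nm == 0.0:
        return 1.0 if d_nh == 0.0 else cap
    return d_nh / d_nm


def margin_ratio(
    sample_index: int, dataset: LabeledDataset, w, config: LHDAConfig
) -> tuple[float, LocalHyperplane, LocalHyperplane]:
    """Leave-one-out margin ratio ``R = d(x, NH) / d(x, NM)`` of one sample.

    Degenerate cases: a zero nearest-miss distance with a positive hit
    distance returns ``config.ratio_cap``; both distances zero returns 1.
    """
    x = dataset.features[sample_index]
    nh, nm = _nearest_hyperplanes(
        x, dataset, int(dataset.labels[sample_index]), w, config,
        exclude_index=sample_index,
    )
    return _ratio(nh.distance, nm.distance, config.ratio_cap), nh, nm


def compute_margin_terms(
    dataset: LabeledDataset, v, config: LHDAConfig
) -> MarginTerms:
    """Fit all nearest-hit / nearest-miss hyperplanes at ``w = v**2``."""
    v = np.asarray(v, dtype=float)
    w = v * v
    N, D = dataset.features.shape
    R = np.empty(N)
    abs_nh = np.empty((N, D))
    abs_nm = np.empty((N, D))
    d_nh = np.empty(N)
    d_nm = np.empty(N)
    nh_list, nm_list = [], []
    for i in range(N):
        x = dataset.features[i]
        nh, nm = _nearest_hyperplanes(
            x, dataset, int(dataset.labels[i]), w, config, exclude_index=i
        )
        nh_list.append(nh)
        nm_list.append(nm)
        abs_nh[i] = np.abs(x - nh.projection)
        abs_nm[i] = np.abs(x - nm.projection)
        d_nh[i] = nh.distance
        d_nm[i] = nm.distance
        R[i] = _ratio(nh.distance, nm.distance, config.ratio_cap)
    gamma = sigmoid_step_derivative(R, config.beta) * R
    # g_i rows; a zero hyperplane distance removes that ratio term entirely
    with np.errstate(invalid="ignore", divide="ignore"):
        term_nh = np.where(d_nh[:, None] > 0, abs_nh / d_nh[:, None], 0.0)
        term_nm = np.where(d_nm[:, None] > 0, abs_nm / d_nm[:, None], 0.0)
    n_zero = int((d_nh == 0).sum() + (d_nm == 0).sum())
    if n_zero:
        logger.debug(
            "%d zero hyperplane distance(s); their gradient terms were dropped",
            n_zero,
        )
    G = term_nh - term_nm
    return MarginTerms(
        R=R, gamma=gamma, G=G, nh=nh_list, nm=nm_list,
        abs_nh=abs_nh, abs_nm=abs_nm,
    )


def frozen_objective(terms: MarginTerms, v, config: LHDAConfig) -> float:
    """Penalized objective at ``w = v**2`` with hyperplanes/alphas frozen.

    This is the surface the backtracking line search descends within one
    alternation round; at the ``v`` used to fit ``terms`` it equals the full
    objective.
    """
    v = np.asarray(v, dtype=float)
    w = v * v
    d_nh = terms.abs_nh @ w
    d_nm = terms.abs_nm @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(
            d_nm > 0, d_nh / np.where(d_nm > 0, d_nm, 1.0),
            np.where(d_nh > 0, config.ratio_cap, 1.0),
        )
    return float(np.mean(sigmoid_step(R, config.beta)) + config.lam * w.sum())


def penalized_objective(dataset: LabeledDataset, v, config: LHDAConfig) -> float:
    """Full objective ``(1/N) sum_i S_beta(R_i) + lam ||w||_1`` at ``w = v**2``.

    All margin ratios use leave-one-out nearest-hit semantics.  The value lies
    in ``[lam ||w||_1, 1 + lam ||w||_1]``.
    """
    v = np.asarray(v, dtype=float)
    if not np.any(v != 0):
        raise ValidationError("v must not be the zero vector")
    terms = compute_margin_terms(dataset, v, config)
    return frozen_objective(terms, v, config)


def objective_gradient(
    dataset: LabeledDataset, v, config: LHDAConfig, terms: MarginTerms
) -> np.ndarray:
    """Analytic gradient of the frozen-hyperplane objective with respect to v.

    ``dJ/dv = (2 lam 1 + (2/N) sum_i gamma_i g_i) (*) v``; coordinates with
    ``v_j = 0`` receive an exactly zero gradient (the Hadamard factor).
    """
    v = np.asarray(v, dtype=float)
    N = dataset.n_samples
    margin_part = terms.gamma @ terms.G  # length D
    return (2.0 * config.lam + (2.0 / N) * margin_part) * v


_SCREEN_FLOOR = 0.02


def univariate_screening_scores(dataset: LabeledDataset) -> np.ndarray:
    """Per-feature univariate 1-NN leave-one-out accuracy.

    Each feature is scored on its own: every sample is assigned the label of
    its nearest neighbor along that single coordinate (left/right gap after
    sorting).  Noise features score near the majority-class frequency;
    features carrying local class structure score above it.  Scale-invariant
    and deterministic.
    """
    X, y = dataset.features, dataset.labels
    n, d = X.shape
    scores = np.empty(d)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        ys = y[order]
        gaps = np.diff(X[order, j])
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        neighbor = np.where(left <= right, np.roll(ys, 1), np.roll(ys, -1))
        scores[j] = float(np.mean(neighbor == ys))
    return scores


def screening_init(dataset: LabeledDataset, floor: float = _SCREEN_FLOOR) -> np.ndarray:
    """Initial ``v`` from univariate screening (sure-screening style).

    Weights start at ``w_j = ((a_j - a_0)_+ + floor)^2`` normalized to sum
    one, where ``a_j`` is the feature's univariate 1-NN LOO accuracy and
    ``a_0`` the majority-class frequency (the chance level).  The floor keeps
    every feature weakly alive so multivariate-only signal can still be
    picked up during descent; when no feature beats chance this reduces to a
    uniform start.
    """
    scores = univariate_screening_scores(dataset)
    counts = np.array([(dataset.labels == c).sum() for c in dataset.class_labels])
    chance = counts.max() / dataset.n_samples
    w0 = (np.maximum(scores - chance, 0.0) + floor) ** 2
    w0 = w0 / w0.sum()
    return np.sqrt(w0)


def _check_class_sizes(dataset: LabeledDataset, k: int) -> None:
    for label in dataset.class_labels:
        size = int((dataset.labels == label).sum())
        if size < k + 1:
            raise ConfigurationError(
                f"class {label} has {size} samples; weight learning with "
                f"k={k} needs at least {k + 1} per class (leave-one-out "
                "nearest-hit hyperplanes must exist)"
            )


def fit_weights(
    dataset: LabeledDataset,
    config: LHDAConfig | None = None,
    record_weights: bool = False,
    v0: np.ndarray | None = None,
) -> tuple[FeatureWeights, TrainingTrace]:
    """Learn the feature weights by alternating minimization.

    Each round re-estimates every sample's nearest-hit / nearest-miss
    hyperplanes under the current weights, then takes one gradient step on
    ``v`` with backtracking: the step is halved (up to 30 times) until the
    objective does not increase.  Candidate steps are pre-screened on the
    frozen-hyperplane surface (cheap — no refitting) and then accepted
    against the full objective with hyperplanes re-estimated at the
    candidate, whose fit is reused as the next round's estimation step.
    Where the nearest hyperplanes are unique, the frozen-hyperplane gradient
    equals the gradient of the full objective (the hyperplane distances are
    minima over the spanning coefficients, so their derivatives pass through
    the minimizers), which makes this a plain monotone descent: the recorded
    objective sequence never increases.  The run stops when no acceptable
    step remains (a descent stall at a local minimum), when the l1 change of
    ``w`` falls below ``config.tol``, or at ``max_iter``.

    The start point (``config.init``) defaults to univariate screening
    (:func:`screening_init`): margin descent from a fully uniform start is
    reliable when few features are noise, but with hundreds of irrelevant
    dimensions the initial metric is noise-dominated and the multiplicative
    updates can lock onto chance structure; seeding from each feature's own
    univariate 1-NN accuracy starts the search inside the informative basin.
    ``init="uniform"`` gives ``v_j = 1/sqrt(D)``, so ``w`` starts on the
    probability simplex.  Either way the weights are normalized at the start
    only; descent itself only constrains ``w > 0``, which the squared
    parameterization guarantees.
    """
    if config is None:
        config = LHDAConfig()
    _check_class_sizes(dataset, config.k)
    D = dataset.n_features
    if v0 is not None:
        v = np.asarray(v0, dtype=float).copy()
        if v.shape != (D,) or not np.any(v != 0):
            raise ValidationError("v0 must be a nonzero vector of length D")
    elif config.init == "screening":
        v = screening_init(dataset)
    else:
        v = np.full(D, 1.0 / np.sqrt(D))
    trace = TrainingTrace(weight_snapshots=[] if record_weights else None)

    terms = compute_margin_terms(dataset, v, config)
    j_cur = frozen_objective(terms, v, config)  # full objective at v
    trace.objective_values.append(j_cur)
    if record_weights:
        trace.weight_snapshots.append(v * v)

    for _ in range(config.max_iter):
        grad = objective_gradient(dataset, v, config, terms)
        step = config.eta
        accepted = False
        for _halving in range(_MAX_BACKTRACKS + 1):
            cand = v - step * grad
            if np.any(cand != 0):
                # cheap pre-screen on the frozen surface
                if frozen_objective(terms, cand, config) <= j_cur + 1e-12:
                    cand_terms = compute_margin_terms(dataset, cand, config)
                    f_cand = frozen_objective(cand_terms, cand, config)
                    if f_cand <= j_cur + 1e-12:
                        accepted = True
                        break
            step *= 0.5
        if not accepted:
            logger.info("no descent step found; stopping at a local minimum")
            break
        delta_w = float(np.abs(cand * cand - v * v).sum())
        v = cand
        terms = cand_terms
        j_cur = min(f_cand, j_cur)
        trace.objective_values.append(j_cur)
        trace.iterations_run += 1
        if record_weights:
            trace.weight_snapshots.append(v * v)
        logger.debug(
            "iter %d: J=%.6g |dw|_1=%.3g step=%.3g",
            trace.iterations_run, j_cur, delta_w, step,
        )
        if delta_w < config.tol:
            trace.converged = True
            break

    return FeatureWeights(v), trace
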