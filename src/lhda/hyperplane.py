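"""Local-hyperplane geometry in a feature-weighted Manhattan space.

A sample's *local hyperplane* for class ``j`` is the convex hull of its ``k``
nearest same-class neighbors; the distance from a query to that hull, under
the weighted Manhattan metric ``d(p, q) = sum_j w_j |p_j - q_j|``, is the
classification statistic of the hyperplane nearest-neighbor rule.

The hull-projection ("spanning coefficient") problem

    min_alpha  w^T |x - H alpha|   s.t.  sum(alpha) = 1, alpha >= 0

is a linear program.  ``exact`` mode solves it through its dual,

    max  u^T x - s   s.t.  H^T u <= s 1,  -w <= u <= w,

which has only ``k`` general constraints regardless of the feature dimension;
the simplex multipliers of those constraints recover alpha.  ``surrogate``
mode instead minimizes the linear upper bound ``alpha^T z`` with
``z_i = w^T |x - h_i|``, whose optimum is the vertex at the single nearest
neighbor (ties split uniformly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from ._simplex import STATUS_OPTIMAL, dual_simplex_alpha
from .data import LabeledDataset
from .exceptions import (
    DimensionError,
    InsufficientNeighborsError,
    OptimizationError,
    ValidationError,
)

__all__ = [
    "AlphaProblem",
    "LocalHyperplane",
    "weighted_manhattan_distance",
    "find_class_neighbors",
    "solve_spanning_coefficients",
    "hyperplane_distance",
]

logger = logging.getLogger(__name__)

SIMPLEX_TOL = 1e-9


def weighted_manhattan_distance(p, q, w) -> float:
    """``sum_j w_j |p_j - q_j|`` — the feature-weighted Manhattan metric.

    Symmetric in ``p`` and ``q``; zero iff the points agree on every feature
    carrying positive weight.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (p.shape == q.shape == w.shape) or p.ndim != 1:
        raise DimensionError(
            f"p, q, w must be 1-D of equal length, got {p.shape}, {q.shape}, {w.shape}"
        )
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    return float(w @ np.abs(p - q))


@dataclass(frozen=True)
class AlphaProblem:
    """Inputs of the spanning-coefficient solve for one (query, class) pair."""

    x: np.ndarray            # query point, length D
    neighbor_matrix: np.ndarray  # H, D x k, columns are neighbors
    w: np.ndarray            # nonnegative weights, length D
    z: np.ndarray            # z_i = w^T |x - h_i|, length k

    @classmethod
    def build(cls, x, H, w) -> "AlphaProblem":
        x = np.asarray(x, dtype=float)
        H = np.asarray(H, dtype=float)
        w = np.asarray(w, dtype=float)
        if H.ndim != 2 or H.shape[0] != x.size or w.size != x.size:
            raise DimensionError(
                f"incompatible shapes: x {x.shape}, H {H.shape}, w {w.shape}"
            )
        z = np.abs(x[:, None] - H).T @ w
        return cls(x=x, neighbor_matrix=H, w=w, z=z)


@dataclass(frozen=True)
class LocalHyperplane:
    """A fitted class-local hyperplane and the query's distance to it.

    ``projection`` is ``H @ alpha`` (the closest hull point found) and
    ``distance`` the weighted Manhattan distance from the query to it.
    """

    neighbor_matrix: np.ndarray      # D x k
    neighbor_indices: np.ndarray     # length k, indices into source dataset
    class_label: int
    alpha: np.ndarray                # length k, on the probability simplex
    projection: np.ndarray           # length D, H @ alpha
    distance: float


def find_class_neighbors(
    x,
    dataset: LabeledDataset,
    class_label: int,
    k: int,
    w,
    exclude_index: int | None = None,
) -> np.ndarray:
    """Indices of the ``k`` nearest samples of one class, weighted-L1 metric.

    Ties in distance are broken by ascending sample index, making the result
    deterministic.  ``exclude_index`` removes one sample from the candidate
    pool (the leave-one-out device used during training).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    idx = dataset.class_indices(class_label)
    if exclude_index is not None:
        idx = idx[idx != exclude_index]
    if idx.size < k:
        raise InsufficientNeighborsError(class_label, int(idx.size), k)
    dists = np.abs(dataset.features[idx] - x) @ w
    order = np.lexsort((idx, dists))  # distance first, then ascending index
    return idx[order[:k]]


def _project_simplex(alpha: np.ndarray) -> np.ndarray | None:
    """Clip to [0, 1] and renormalize, absorbing solver round-off."""
    alpha = np.clip(alpha, 0.0, 1.0)
    total = alpha.sum()
    if total <= 0:
        return None
    return alpha / total


def _solve_alpha_scipy(problem: AlphaProblem) -> np.ndarray:
    """Reference LP solve of the dual via scipy's HiGHS interface."""
    H, x, w = problem.neighbor_matrix, problem.x, problem.w
    k = H.shape[1]
    c = np.concatenate([-x, [1.0]])
    A = np.hstack([H.T, -np.ones((k, 1))])
    lb = np.concatenate([-w, [-np.inf]])
    ub = np.concatenate([w, [np.inf]])
    res = linprog(
        c,
        A_ub=A,
        b_ub=np.zeros(k),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"presolve": False},
    )
    if not res.success:
        raise OptimizationError(
            f"spanning-coefficient LP failed: {res.message}", status=res.status
        )
    alpha = _project_simplex(-res.ineqlin.marginals)  # duals of the k constraints
    if alpha is None:
        raise OptimizationError(
            "degenerate dual multipliers in spanning-coefficient LP",
            status=res.status,
        )
    return alpha


def _solve_alpha_exact(problem: AlphaProblem) -> np.ndarray:
    """Exact solve of the weighted-L1 simplex projection.

    Uses the specialized bounded-variable simplex on the dual (tiny k x k
    basis); every solve is verified by strong duality — the primal value
    recomputed from alpha must meet the dual objective — and falls back to
    scipy's general LP solver if the certificate fails.
    """
    H = problem.neighbor_matrix
    x, w, z = problem.x, problem.w, problem.z
    k = H.shape[1]
    if z.min() == 0.0:
        # the query coincides (on all weighted coordinates) with a neighbor
        alpha = np.zeros(k)
        alpha[int(np.argmin(z))] = 1.0
        return alpha
    alpha_raw, dual_obj, status = dual_simplex_alpha(
        np.ascontiguousarray(x), np.ascontiguousarray(H), np.ascontiguousarray(w)
    )
    if status == STATUS_OPTIMAL:
        alpha = _project_simplex(alpha_raw)
        if alpha is not None:
            primal = float(w @ np.abs(x - H @ alpha))
            if abs(primal - dual_obj) <= 1e-7 * (1.0 + abs(primal)):
                return alpha
    logger.debug("fast simplex certificate failed (status=%d); using scipy", status)
    return _solve_alpha_scipy(problem)


def _solve_alpha_surrogate(problem: AlphaProblem) -> np.ndarray:
    """Vertex minimizer of the linear bound alpha^T z; ties split uniformly."""
    z = problem.z
    tied = np.flatnonzero(z <= z.min() + 1e-12)
    alpha = np.zeros(z.size)
    alpha[tied] = 1.0 / tied.size
    return alpha


def solve_spanning_coefficients(problem: AlphaProblem, mode: str = "exact") -> np.ndarray:
    """Simplex coefficients combining the neighbors into the closest hull point.

    ``exact`` minimizes the true objective ``w^T |x - H alpha|``; ``surrogate``
    minimizes its linear upper bound ``alpha^T z``.  The returned vector
    satisfies the simplex constraints to within ``1e-9``.
    """
    k = problem.neighbor_matrix.shape[1]
    if k == 1:
        return np.ones(1)
    if mode == "exact":
        return _solve_alpha_exact(problem)
    if mode == "surrogate":
        return _solve_alpha_surrogate(problem)
    raise ValidationError(f"unknown solver mode {mode!r}")


def hyperplane_distance(
    x,
    dataset: LabeledDataset,
    class_label: int,
    k: int,
    w,
    mode: str = "exact",
    exclude_index: int | None = None,
) -> LocalHyperplane:
    """Build one class-local hyperplane for a query and measure the distance.

    Composes the neighbor search with the spanning-coefficient solve; the
    reported distance is recomputed as ``w^T |x - H alpha|`` from the returned
    alpha, so it is consistent with the stored projection point.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    nbr = find_class_neighbors(x, dataset, class_label, k, w, exclude_index)
    H = dataset.features[nbr].T
    problem = AlphaProblem.build(x, H, w)
    alpha = solve_spanning_coefficients(problem, mode=mode)
    s = H @ alpha
    return LocalHyperplane(
        neighbor_matrix=H,
        neighbor_indices=nbr,
        class_label=int(class_label),
        alpha=alpha,
        projection=s,
        distance=float(w @ np.abs(x - s)),
    )
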