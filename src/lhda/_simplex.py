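"""Specialized solver for the weighted-L1 simplex-projection linear program.

The spanning-coefficient problem

    min_alpha  w^T |x - H alpha|,   alpha on the probability simplex,

is solved through its dual

    max  u^T x - s   s.t.  h_i^T u <= s  (i = 1..k),  -w <= u <= w,

whose constraint matrix has only ``k`` rows, so a bounded-variable revised
simplex keeps a tiny ``k x k`` basis no matter how many features there are.
The optimal multipliers of the ``k`` constraints are exactly ``alpha``.

The caller (:mod:`lhda.hyperplane`) verifies every solve with a strong-duality
certificate — the primal value recomputed from alpha must meet the dual
objective — and falls back to :func:`scipy.optimize.linprog` when the
certificate fails, so speed never trades against exactness.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OPTIMAL = 0
STATUS_ITERATION_LIMIT = 1
STATUS_NUMERICAL = 2

_TOL = 1e-9


@njit(cache=True)
def dual_simplex_alpha(x, H, w):  # pragma: no cover - exercised via wrapper
    """Solve the dual LP; return (alpha, dual_objective, status).

    Variables are ``y = (u_1..u_D, s, sigma_1..sigma_k)`` with slack rows
    ``h_i^T u - s + sigma_i = 0``.  ``s`` is free and enters the basis at the
    start (with the row attaining ``max_i h_i^T u``), giving a feasible basis
    whose remaining columns are unit slack columns.
    """
    D, k = H.shape
    n = D + 1 + k

    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    for j in range(D):
        lb[j] = -w[j]
        ub[j] = w[j]
        c[j] = x[j]
    lb[D] = -np.inf
    ub[D] = np.inf
    c[D] = -1.0
    for i in range(k):
        lb[D + 1 + i] = 0.0
        ub[D + 1 + i] = np.inf

    # initial point: u_j at the bound matching sign(x_j); s = max_i h_i^T u
    xval = np.zeros(n)
    at_upper = np.zeros(n, dtype=np.bool_)
    for j in range(D):
        if x[j] >= 0.0:
            xval[j] = w[j]
            at_upper[j] = True
        else:
            xval[j] = -w[j]
    q = np.zeros(k)
    for i in range(k):
        acc = 0.0
        for j in range(D):
            acc += H[j, i] * xval[j]
        q[i] = acc
    istar = 0
    for i in range(1, k):
        if q[i] > q[istar]:
            istar = i
    xval[D] = q[istar]
    for i in range(k):
        xval[D + 1 + i] = q[istar] - q[i]

    basics = np.empty(k, dtype=np.int64)
    in_basis = np.zeros(n, dtype=np.bool_)
    basics[0] = D
    in_basis[D] = True
    pos = 1
    for i in range(k):
        if i != istar:
            basics[pos] = D + 1 + i
            in_basis[D + 1 + i] = True
            pos += 1

    col = np.empty(k)  # scratch: column of one variable
    B = np.empty((k, k))
    cB = np.empty(k)
    max_pivots = 200 + 20 * (D + k)
    bland_after = 50 + 5 * (D + k)
    z = np.zeros(k)

    for pivot in range(max_pivots):
        # factor current basis
        for m in range(k):
            b = basics[m]
            if b < D:
                for i in range(k):
                    B[i, m] = H[b, i]
            elif b == D:
                for i in range(k):
                    B[i, m] = -1.0
            else:
                for i in range(k):
                    B[i, m] = 0.0
                B[b - D - 1, m] = 1.0
            cB[m] = c[b]
        z = np.linalg.solve(B.T.copy(), cB)

        # pricing: entering variable (Dantzig; Bland when pivot count grows)
        enter = -1
        enter_dir = 0.0
        best = _TOL
        use_bland = pivot >= bland_after
        for j in range(n):
            if in_basis[j]:
                continue
            if lb[j] == ub[j]:
                continue  # fixed variable (w_j = 0)
            if j < D:
                d = c[j]
                for i in range(k):
                    d -= z[i] * H[j, i]
            elif j == D:
                d = c[j]
                for i in range(k):
                    d += z[i]
            else:
                d = -z[j - D - 1]
            if at_upper[j]:
                improve = -d
                direction = -1.0
            else:
                improve = d
                direction = 1.0
            if improve > best:
                enter = j
                enter_dir = direction
                if use_bland:
                    break
                best = improve
        if enter == -1:
            alpha = np.zeros(k)
            for i in range(k):
                alpha[i] = z[i]
            obj = 0.0
            for j in range(n):
                obj += c[j] * xval[j]
            return alpha, obj, STATUS_OPTIMAL

        # direction of basic variables: x_B(t) = x_B - dir * t * B^{-1} A_e
        if enter < D:
            for i in range(k):
                col[i] = H[enter, i]
        elif enter == D:
            for i in range(k):
                col[i] = -1.0
        else:
            for i in range(k):
                col[i] = 0.0
            col[enter - D - 1] = 1.0
        ycol = np.linalg.solve(B.copy(), col.copy())

        t_limit = ub[enter] - lb[enter]  # bound flip distance (may be inf)
        leave_m = -1
        leave_to_upper = False
        for m in range(k):
            delta = -enter_dir * ycol[m]
            b = basics[m]
            if delta > _TOL:
                if ub[b] == np.inf:
                    continue
                t_m = (ub[b] - xval[b]) / delta
                if t_m < t_limit - _TOL or (t_m < t_limit + _TOL and leave_m == -1):
                    t_limit = t_m if t_m > 0.0 else 0.0
                    leave_m = m
                    leave_to_upper = True
            elif delta < -_TOL:
                if lb[b] == -np.inf:
                    continue
                t_m = (lb[b] - xval[b]) / delta
                if t_m < t_limit - _TOL or (t_m < t_limit + _TOL and leave_m == -1):
                    t_limit = t_m if t_m > 0.0 else 0.0
                    leave_m = m
                    leave_to_upper = False
        if t_limit == np.inf:
            return np.zeros(k), 0.0, STATUS_NUMERICAL  # dual unbounded: bad input

        # move
        for m in range(k):
            xval[basics[m]] -= enter_dir * t_limit * ycol[m]
        xval[enter] += enter_dir * t_limit

        if leave_m == -1:
            at_upper[enter] = not at_upper[enter]  # bound flip
            xval[enter] = ub[enter] if at_upper[enter] else lb[enter]
        else:
            leave = basics[leave_m]
            in_basis[leave] = False
            at_upper[leave] = leave_to_upper
            xval[leave] = ub[leave] if leave_to_upper else lb[leave]
            basics[leave_m] = enter
            in_basis[enter] = True

    return np.zeros(k), 0.0, STATUS_ITERATION_LIMIT
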