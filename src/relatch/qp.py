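"""Convex quadratic programming layer on top of scipy.

All core computations — reference-state estimation, relative-change flux
prediction, MOMA — are convex QPs with linear constraints; flux-variability
analysis at a fixed optimal objective adds one convex quadratic constraint.
Problems are solved with ``scipy.optimize.minimize`` (trust-constr, SLSQP
fallback) and then *polished*: the active constraints at the approximate
optimum are resolved as an equality-constrained KKT system, which yields
machine-precision solutions for the non-degenerate instances the package
produces and makes results reproducible across runs.

The canonical form is::

    minimize    0.5 x' P x + q' x + const
    subject to  A_eq x = b_eq
                A_ub x <= b_ub
                lb <= x <= ub

with P symmetric positive semidefinite.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
from scipy.optimize import (
    LinearConstraint,
    NonlinearConstraint,
    linprog,
    minimize,
)

FEASIBILITY_TOL = 1e-8
ACTIVE_TOL = 1e-6


@contextmanager
def _quiet_solver():
    # trust-constr warns about singular KKT Jacobians on degenerate
    # instances; it falls back to SVD internally, which is exactly what we
    # want, so the warning is noise here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        yield


@dataclass
class QPResult:
    x: np.ndarray
    objective: float
    status: str  # "optimal" | "infeasible" | "failed"
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub):
    A_eq = np.zeros((0, n)) if A_eq is None else np.atleast_2d(np.asarray(A_eq, float))
    b_eq = np.zeros(0) if b_eq is None else np.atleast_1d(np.asarray(b_eq, float))
    A_ub = np.zeros((0, n)) if A_ub is None else np.atleast_2d(np.asarray(A_ub, float))
    b_ub = np.zeros(0) if b_ub is None else np.atleast_1d(np.asarray(b_ub, float))
    lb = np.full(n, -np.inf) if lb is None else np.asarray(lb, float)
    ub = np.full(n, np.inf) if ub is None else np.asarray(ub, float)
    return A_eq, b_eq, A_ub, b_ub, lb, ub


def find_feasible_point(n, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
                        lb=None, ub=None):
    """Phase-1 LP: return a feasible point or None if the set is empty."""
    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    res = linprog(
        c=np.zeros(n),
        A_eq=A_eq if A_eq.size else None,
        b_eq=b_eq if b_eq.size else None,
        A_ub=A_ub if A_ub.size else None,
        b_ub=b_ub if b_ub.size else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.x if res.status == 0 else None


def _stacked_inequalities(A_ub, b_ub, lb, ub):
    """All inequalities as G x <= h, including finite bounds."""
    n = lb.shape[0]
    rows = [A_ub]
    rhs = [b_ub]
    eye = np.eye(n)
    fin_ub = np.isfinite(ub)
    fin_lb = np.isfinite(lb)
    rows.append(eye[fin_ub])
    rhs.append(ub[fin_ub])
    rows.append(-eye[fin_lb])
    rhs.append(-lb[fin_lb])
    return np.vstack(rows), np.concatenate(rhs)


def _kkt_solve(P, q, E, f, G_act, h_act):
    """Solve the equality-constrained KKT system by least squares."""
    n = P.shape[0]
    ne, na = E.shape[0], G_act.shape[0]
    K = np.zeros((n + ne + na, n + ne + na))
    K[:n, :n] = P
    K[:n, n:n + ne] = E.T
    K[:n, n + ne:] = G_act.T
    K[n:n + ne, :n] = E
    K[n + ne:, :n] = G_act
    rhs = np.concatenate([-q, f, h_act])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:n], sol[n + ne:]


def _polish(x, P, q, const, A_eq, b_eq, G, h, max_iter=40):
    """Active-set refinement seeded from an approximate optimum.

    Returns a polished point, or None when refinement fails to produce a
    feasible improvement (degenerate active sets, rank-deficient KKT).
    """
    scale = 1.0 + np.abs(h) if h.size else np.ones(0)
    resid = h - G @ x if G.size else np.zeros(0)
    active = set(np.nonzero(resid / scale < ACTIVE_TOL)[0]) if G.size else set()
    best = None
    for _ in range(max_iter):
        idx = sorted(active)
        try:
            x_new, lam = _kkt_solve(P, q, A_eq, b_eq, G[idx], h[idx])
        except np.linalg.LinAlgError:
            return best
        if not np.all(np.isfinite(x_new)):
            return best
        viol = (G @ x_new - h) / scale if G.size else np.zeros(0)
        eq_viol = np.max(np.abs(A_eq @ x_new - b_eq)) if A_eq.size else 0.0
        if eq_viol > 1e-7:
            return best
        worst = int(np.argmax(viol)) if viol.size else -1
        if viol.size and viol[worst] > FEASIBILITY_TOL:
            if worst in active:  # numerically stuck
                return best
            active.add(worst)
            continue
        best = x_new
        # drop a constraint with a clearly negative multiplier, if any
        neg = [i for i, l in zip(idx, lam) if l < -1e-9]
        if not neg:
            return best
        active.remove(min(neg, key=lambda i: lam[idx.index(i)]))
    return best


def qp_objective(P, q, const, x):
    return float(0.5 * x @ P @ x + q @ x + const)


def solve_qp(P, q, const=0.0, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
             lb=None, ub=None, x0=None) -> QPResult:
    """Solve a convex QP to high accuracy; deterministic for a fixed input."""
    P = np.asarray(P, float)
    q = np.asarray(q, float)
    n = q.shape[0]
    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)

    feas = find_feasible_point(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    if feas is None:
        return QPResult(np.full(n, np.nan), np.nan, "infeasible",
                        "constraint set is empty")
    start = feas if x0 is None else np.clip(np.asarray(x0, float), lb, ub)

    constraints = []
    if A_eq.size:
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub.size:
        constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))

    def fun(x):
        return 0.5 * x @ P @ x + q @ x + const

    def jac(x):
        return P @ x + q

    with _quiet_solver():
        res = minimize(
            fun, start, jac=jac, hess=lambda x: P,
            bounds=list(zip(lb, ub)), constraints=constraints,
            method="trust-constr",
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000, "verbose": 0},
        )
    x = np.asarray(res.x, float)
    if not _is_feasible(x, A_eq, b_eq, A_ub, b_ub, lb, ub):
        with _quiet_solver():
            slsqp = minimize(
                fun, start, jac=jac, bounds=list(zip(lb, ub)),
                constraints=_slsqp_constraints(A_eq, b_eq, A_ub, b_ub),
                method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
            )
        if _is_feasible(slsqp.x, A_eq, b_eq, A_ub, b_ub, lb, ub):
            x = np.asarray(slsqp.x, float)
        else:
            x = np.asarray(feas, float)

    G, h = _stacked_inequalities(A_ub, b_ub, lb, ub)
    polished = _polish(x, P, q, const, A_eq, b_eq, G, h)
    if polished is not None and qp_objective(P, q, const, polished) <= \
            qp_objective(P, q, const, x) + 1e-12 * (1 + abs(qp_objective(P, q, const, x))):
        x = polished
    return QPResult(x, qp_objective(P, q, const, x), "optimal", res.message)


def _slsqp_constraints(A_eq, b_eq, A_ub, b_ub):
    cons = []
    if A_eq.size:
        cons.append({"type": "eq", "fun": lambda x: A_eq @ x - b_eq,
                     "jac": lambda x: A_eq})
    if A_ub.size:
        cons.append({"type": "ineq", "fun": lambda x: b_ub - A_ub @ x,
                     "jac": lambda x: -A_ub})
    return cons


def _is_feasible(x, A_eq, b_eq, A_ub, b_ub, lb, ub, tol=1e-6):
    if x is None or not np.all(np.isfinite(x)):
        return False
    if A_eq.size and np.max(np.abs(A_eq @ x - b_eq)) > tol * (1 + np.max(np.abs(b_eq), initial=0)):
        return False
    if A_ub.size and np.max(A_ub @ x - b_ub) > tol * (1 + np.max(np.abs(b_ub), initial=0)):
        return False
    pad = tol * (1 + np.max(np.abs(x)))
    return bool(np.all(x >= lb - pad) and np.all(x <= ub + pad))


def solve_lp(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, lb=None, ub=None,
             maximize=False) -> QPResult:
    """Solve an LP via HiGHS; objective reported in the requested sense."""
    c = np.asarray(c, float)
    n = c.shape[0]
    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    res = linprog(
        c=-c if maximize else c,
        A_eq=A_eq if A_eq.size else None, b_eq=b_eq if b_eq.size else None,
        A_ub=A_ub if A_ub.size else None, b_ub=b_ub if b_ub.size else None,
        bounds=list(zip(lb, ub)), method="highs",
    )
    if res.status == 2:
        return QPResult(np.full(n, np.nan), np.nan, "infeasible", res.message)
    if res.status != 0:
        return QPResult(np.full(n, np.nan), np.nan, "failed", res.message)
    obj = -res.fun if maximize else res.fun
    return QPResult(np.asarray(res.x, float), float(obj), "optimal", res.message)


def optimize_linear_under_quadratic_cap(
    c, P, q, const, cap, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
    lb=None, ub=None, x0=None, maximize=False,
) -> QPResult:
    """min/max c'x subject to the QP objective staying at or below ``cap``.

    This is the flux-variability subproblem at a fixed optimal objective:
    linear target, one convex quadratic constraint, linear constraints.
    """
    c = np.asarray(c, float)
    P = np.asarray(P, float)
    q = np.asarray(q, float)
    n = c.shape[0]
    A_eq, b_eq, A_ub, b_ub, lb, ub = _as_arrays(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    sign = -1.0 if maximize else 1.0

    constraints = [
        NonlinearConstraint(
            lambda x: 0.5 * x @ P @ x + q @ x + const,
            -np.inf, cap,
            jac=lambda x: P @ x + q,
            hess=lambda x, v: v[0] * P,
        )
    ]
    if A_eq.size:
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub.size:
        constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))

    start = x0 if x0 is not None else find_feasible_point(n, A_eq, b_eq, A_ub, b_ub, lb, ub)
    if start is None:
        return QPResult(np.full(n, np.nan), np.nan, "infeasible", "no feasible point")

    with _quiet_solver():
        res = minimize(
            lambda x: sign * (c @ x), np.asarray(start, float),
            jac=lambda x: sign * c, hess=lambda x: np.zeros((n, n)),
            bounds=list(zip(lb, ub)), constraints=constraints,
            method="trust-constr",
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
        )
    def _acceptable(x):
        if x is None:
            return False
        quad = 0.5 * x @ P @ x + q @ x + const
        return (quad <= cap + 1e-6 * (1 + abs(cap))
                and _is_feasible(x, A_eq, b_eq, A_ub, b_ub, lb, ub))

    # judge by actual feasibility, not the solver's status flag: a point
    # that satisfies all constraints carries a valid objective value
    x = np.asarray(res.x, float)
    if _acceptable(x):
        return QPResult(x, float(c @ x), "optimal", res.message)
    with _quiet_solver():
        slsqp = minimize(
            lambda x: sign * (c @ x), np.asarray(start, float),
            jac=lambda x: sign * c, bounds=list(zip(lb, ub)),
            constraints=_slsqp_constraints(A_eq, b_eq, A_ub, b_ub) + [
                {"type": "ineq",
                 "fun": lambda x: cap - (0.5 * x @ P @ x + q @ x + const),
                 "jac": lambda x: -(P @ x + q)}],
            method="SLSQP", options={"ftol": 1e-12, "maxiter": 500},
        )
    if _acceptable(np.asarray(slsqp.x, float)):
        return QPResult(np.asarray(slsqp.x, float), float(c @ slsqp.x),
                        "optimal", slsqp.message)
    if x0 is not None and _acceptable(np.asarray(x0, float)):
        # the incumbent optimum itself is feasible for the cap; reporting
        # its value is a conservative (zero-width) bound
        x0 = np.asarray(x0, float)
        return QPResult(x0, float(c @ x0), "optimal", "fell back to incumbent")
    return QPResult(x, float(c @ x), "failed", res.message)
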