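"""Pluggable LP backends.

A backend receives a :class:`LinearProgram` (sparse constraint data,
variable bounds, maximization objective) and returns a
:class:`RawSolution` with primal values and duals normalized to one
convention, independent of the solver library:

* equality duals ``y_eq[k] = d z* / d b_eq[k]`` (free sign),
* inequality duals ``y_ub[k] = d z* / d b_ub[k] >= 0`` for ``A_ub x <= b_ub``,
* ``mu_ub[i] = d z* / d ub[i] >= 0`` and ``mu_lb[i] = -d z* / d lb[i] >= 0``
  for variable bounds, exactly 0 where a bound is absent (infinite).

Backends are resolved by name through :func:`get_backend`; core code
never references a solver library directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import SolverError

__all__ = ["LinearProgram", "RawSolution", "get_backend", "available_backends"]


@dataclass
class LinearProgram:
    """A maximization LP: max c.x s.t. A_eq x = b_eq, A_ub x <= b_ub,
    lb <= x <= ub (entries of ub may be +inf)."""

    c: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    col_names: list[str] = field(default_factory=list)
    eq_names: list[str] = field(default_factory=list)
    ub_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.c)


@dataclass
class RawSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    objective: float
    x: np.ndarray
    y_eq: np.ndarray
    y_ub: np.ndarray
    mu_lb: np.ndarray
    mu_ub: np.ndarray
    backend: str
    message: str = ""


def _zero_absent_bounds(lp: LinearProgram, sol: RawSolution) -> RawSolution:
    sol.mu_ub = np.where(np.isfinite(lp.ub), sol.mu_ub, 0.0)
    sol.mu_lb = np.where(np.isfinite(lp.lb), sol.mu_lb, 0.0)
    return sol


def solve_scipy_highs(lp: LinearProgram, tol: float = 1e-9) -> RawSolution:
    """HiGHS dual simplex via scipy.  Vertex solutions with exact
    complementary slackness; duals read from the marginals and
    sign-flipped from scipy's minimization convention."""
    res = linprog(
        -lp.c,
        A_eq=lp.A_eq if lp.A_eq.shape[0] else None,
        b_eq=lp.b_eq if lp.A_eq.shape[0] else None,
        A_ub=lp.A_ub if lp.A_ub.shape[0] else None,
        b_ub=lp.b_ub if lp.A_ub.shape[0] else None,
        bounds=np.column_stack([lp.lb, lp.ub]),
        method="highs-ds",
        options={"primal_feasibility_tolerance": tol,
                 "dual_feasibility_tolerance": tol},
    )
    n_eq, n_ub = lp.A_eq.shape[0], lp.A_ub.shape[0]
    if res.status == 2:
        return RawSolution("infeasible", np.nan, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0),
                           "scipy-highs", res.message)
    if res.status == 3:
        return RawSolution("unbounded", np.inf, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0),
                           "scipy-highs", res.message)
    if res.status != 0:
        return RawSolution("error", np.nan, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0),
                           "scipy-highs", res.message)
    sol = RawSolution(
        status="optimal",
        objective=-res.fun,
        x=np.asarray(res.x, dtype=float),
        # scipy reports d(min)/d rhs; our convention is d(max)/d rhs
        y_eq=-np.asarray(res.eqlin.marginals) if n_eq else np.empty(0),
        y_ub=-np.asarray(res.ineqlin.marginals) if n_ub else np.empty(0),
        mu_lb=np.asarray(res.lower.marginals, dtype=float),
        mu_ub=-np.asarray(res.upper.marginals, dtype=float),
        backend="scipy-highs",
        message=res.message,
    )
    return _zero_absent_bounds(lp, sol)


def solve_glpk(lp: LinearProgram, tol: float = 1e-9) -> RawSolution:
    """GLPK simplex through optlang; used as an independent cross-check
    of the primary backend."""
    try:
        from optlang import glpk_interface as gi
    except ImportError as exc:  # pragma: no cover
        raise SolverError("GLPK backend unavailable (optlang/glpk missing)") from exc

    def _b(v: float) -> float | None:
        return None if not np.isfinite(v) else float(v)

    variables = [
        gi.Variable(name, lb=_b(lo), ub=_b(hi))
        for name, lo, hi in zip(lp.col_names, lp.lb, lp.ub)
    ]
    m = gi.Model()
    m.add(variables)
    m.update()
    constraints = []
    for A, names, rhs, is_eq in (
        (lp.A_eq, lp.eq_names, lp.b_eq, True),
        (lp.A_ub, lp.ub_names, lp.b_ub, False),
    ):
        A = A.tocsr()
        for k in range(A.shape[0]):
            row = A.getrow(k)
            expr = sum(
                float(val) * variables[j]
                for j, val in zip(row.indices, row.data)
            )
            kw = {"lb": float(rhs[k]), "ub": float(rhs[k])} if is_eq else {
                "ub": float(rhs[k])
            }
            constraints.append(gi.Constraint(expr, name=names[k], **kw))
    m.add(constraints)
    m.objective = gi.Objective(
        sum(float(c) * v for c, v in zip(lp.c, variables) if c != 0),
        direction="max",
    )
    status = m.optimize()
    if status == "infeasible":
        return RawSolution("infeasible", np.nan, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0), "glpk")
    if status == "unbounded":
        return RawSolution("unbounded", np.inf, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0), "glpk")
    if status != "optimal":
        return RawSolution("error", np.nan, np.empty(0), np.empty(0),
                           np.empty(0), np.empty(0), np.empty(0),
                           "glpk", str(status))
    x = np.array([v.primal for v in variables], dtype=float)
    # constraint.dual is already d(max objective)/d rhs
    duals = {c.name: float(c.dual) for c in m.constraints}
    y_eq = np.array([duals[nm] for nm in lp.eq_names], dtype=float)
    y_ub = np.array([duals[nm] for nm in lp.ub_names], dtype=float)
    # reduced costs split into bound duals by the active side
    rc = np.array([v.dual for v in variables], dtype=float)
    at_ub = np.isfinite(lp.ub) & (x >= lp.ub - 1e-7)
    at_lb = np.isfinite(lp.lb) & (x <= lp.lb + 1e-7)
    mu_ub = np.where(at_ub, np.maximum(rc, 0.0), 0.0)
    mu_lb = np.where(at_lb, np.maximum(-rc, 0.0), 0.0)
    sol = RawSolution("optimal", float(m.objective.value), x, y_eq, y_ub,
                      mu_lb, mu_ub, "glpk")
    return _zero_absent_bounds(lp, sol)


_BACKENDS = {
    "scipy-highs": solve_scipy_highs,
    "glpk": solve_glpk,
}


def available_backends() -> list[str]:
    return list(_BACKENDS)


def get_backend(name: str):
    try:
        return _BACKENDS[name]
    except KeyError:
        raise SolverError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
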