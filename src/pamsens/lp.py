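"""LP assembly, solution and duality checks for PAMs.

The primal program maximizes the objective flux subject to mass
balances ``S v = 0``, enzyme coupling ``sum_i v_i / kcat_{i,j} - e_j <=
0``, the proteome budget ``w.v + m.e <= phi_0`` and variable bounds.
One solve yields both the primal optimum and every shadow price needed
for sensitivity analysis; the explicit dual program is constructed
separately (:func:`build_dual`) purely as a verification oracle.

Shadow-price sign convention (all as sensitivities of the *maximal*
objective to the constraint right-hand side):

========  ==========================================  ======
dual      constraint                                  sign
========  ==========================================  ======
lambda    mass balance of a metabolite                free
xi        enzyme coupling row                         >= 0
pi        proteome budget row                         >= 0
mu_max    flux upper bound (0 where unbounded)        >= 0
mu_min    flux lower bound (as -d z*/d lb)            >= 0
eps_max   enzyme upper bound (0 where unbounded)      >= 0
eps_min   enzyme lower bound (as -d z*/d emin)        >= 0
========  ==========================================  ======
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .backends import LinearProgram, get_backend
from .errors import (
    InfeasibleProblemError,
    NonOptimalSolutionError,
    SolverError,
    UnboundedProblemError,
)
from .model import PamModel, compute_phi0

__all__ = [
    "PrimalDualSolution",
    "build_primal",
    "solve",
    "build_dual",
    "solve_dual",
    "verify_strong_duality",
    "verify_complementary_slackness",
    "solve_count",
    "DEFAULT_BACKEND",
]

DEFAULT_BACKEND = "scipy-highs"

#: Feasibility/optimality tolerance requested from backends.
SOLVER_TOL = 1e-9

#: Tolerance used by identity and slackness checks.
CHECK_TOL = 1e-6

_solves_so_far = 0


def solve_count() -> int:
    """Total number of LP solves performed in this process (bookkeeping
    for solve-economy comparisons between exact and finite-difference
    sensitivities)."""
    return _solves_so_far


@dataclass
class PrimalDualSolution:
    """Optimal primal and dual values of a PAM linear program."""

    objective: float
    fluxes: pd.Series
    enzymes: pd.Series
    lam: pd.Series          # mass-balance duals, free sign
    xi: pd.Series           # enzyme-coupling duals, >= 0
    mu_max: pd.Series       # flux upper-bound duals, >= 0
    mu_min: pd.Series       # flux lower-bound duals, >= 0
    eps_max: pd.Series      # enzyme upper-bound duals, >= 0
    eps_min: pd.Series      # enzyme lower-bound duals, >= 0
    pi: float | None        # proteome dual (None when model has no sectors)
    status: str = "optimal"
    backend: str = DEFAULT_BACKEND
    tolerance: float = SOLVER_TOL
    degenerate: bool = False

    @property
    def pi_value(self) -> float:
        return 0.0 if self.pi is None else self.pi


def _column_layout(pam: PamModel) -> tuple[list[str], list[str]]:
    flux_ids = list(pam.network.reactions)
    enz_ids = [e.enzyme_id for e in pam.enzymes]
    return flux_ids, enz_ids


def build_primal(pam: PamModel) -> LinearProgram:
    """Assemble the PAM linear program (maximization form).

    Columns are fluxes followed by enzyme concentrations; equality rows
    are the metabolite mass balances; inequality rows are one coupling
    row per catalytic enzyme plus, when sectors are configured, the
    proteome budget row.
    """
    net = pam.network
    flux_ids, enz_ids = _column_layout(pam)
    n_v, n_e = len(flux_ids), len(enz_ids)
    ri = {r: j for j, r in enumerate(flux_ids)}
    ei = {e: j for j, e in enumerate(enz_ids)}

    S = net.s_matrix()
    A_eq = sparse.hstack(
        [S, sparse.csr_matrix((S.shape[0], n_e))], format="csr"
    ) if n_e else S.tocsr()
    b_eq = np.zeros(S.shape[0])

    rows, cols, vals = [], [], []
    ub_names: list[str] = []
    b_ub: list[float] = []
    k = 0
    for enz in pam.enzymes:
        if not enz.catalytic:
            continue
        for rid, kcat in enz.kcats.items():
            rows.append(k)
            cols.append(ri[rid])
            vals.append(1.0 / kcat)
        rows.append(k)
        cols.append(n_v + ei[enz.enzyme_id])
        vals.append(-1.0)
        ub_names.append(f"coupling[{enz.enzyme_id}]")
        b_ub.append(0.0)
        k += 1
    if pam.sectors is not None:
        w = pam.sector_weights()
        for j, wj in enumerate(w):
            if wj != 0.0:
                rows.append(k)
                cols.append(j)
                vals.append(wj)
        for enz in pam.enzymes:
            rows.append(k)
            cols.append(n_v + ei[enz.enzyme_id])
            vals.append(enz.molar_mass)
        ub_names.append("proteome")
        b_ub.append(compute_phi0(pam.sectors))
        k += 1
    A_ub = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(k, n_v + n_e)
    )

    c = np.zeros(n_v + n_e)
    if net.objective is not None:
        c[ri[net.objective]] = 1.0
    lb = np.array([net.lb(r) for r in flux_ids] + [e.emin for e in pam.enzymes])
    ub = np.array([net.ub(r) for r in flux_ids] + [e.emax for e in pam.enzymes])
    return LinearProgram(
        c=c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=np.asarray(b_ub),
        lb=lb, ub=ub,
        col_names=[f"v[{r}]" for r in flux_ids] + [f"e[{e}]" for e in enz_ids],
        eq_names=[f"balance[{m}]" for m in net.metabolites],
        ub_names=ub_names,
    )


def _clean(a: np.ndarray, eps: float = 1e-11) -> np.ndarray:
    """Suppress solver noise below eps (keeps exact zeros exact)."""
    a = np.asarray(a, dtype=float).copy()
    a[np.abs(a) < eps] = 0.0
    return a


def solve(
    pam: PamModel,
    backend: str = DEFAULT_BACKEND,
    tol: float = SOLVER_TOL,
) -> PrimalDualSolution:
    """Solve a PAM to optimality and extract all shadow prices.

    Raises :class:`InfeasibleProblemError` or
    :class:`UnboundedProblemError` with context on non-optimal statuses.
    """
    global _solves_so_far
    net = pam.network
    for rid in net.reactions:
        if net.lb(rid) > net.ub(rid):
            raise InfeasibleProblemError(
                "model infeasible before solving",
                hint=f"reaction {rid!r} has lb > ub",
            )
    lp = build_primal(pam)
    raw = get_backend(backend)(lp, tol=tol)
    _solves_so_far += 1
    if raw.status == "infeasible":
        raise InfeasibleProblemError(
            "PAM linear program is infeasible",
            hint=_infeasibility_hint(pam),
        )
    if raw.status == "unbounded":
        raise UnboundedProblemError(
            "PAM objective is unbounded; add an uptake or proteome limit"
        )
    if raw.status != "optimal":
        raise SolverError(f"backend {backend} failed: {raw.message}")

    flux_ids, enz_ids = _column_layout(pam)
    n_v = len(flux_ids)
    cat_ids = [e.enzyme_id for e in pam.enzymes if e.catalytic]
    xi = pd.Series(_clean(raw.y_ub[: len(cat_ids)]), index=cat_ids, dtype=float)
    pi = None
    if pam.sectors is not None:
        pi = float(_clean(raw.y_ub[-1:])[0])
    sol = PrimalDualSolution(
        objective=float(raw.objective),
        fluxes=pd.Series(_clean(raw.x[:n_v]), index=flux_ids),
        enzymes=pd.Series(_clean(raw.x[n_v:]), index=enz_ids),
        lam=pd.Series(_clean(raw.y_eq), index=net.metabolites),
        xi=xi,
        mu_max=pd.Series(_clean(raw.mu_ub[:n_v]), index=flux_ids),
        mu_min=pd.Series(_clean(raw.mu_lb[:n_v]), index=flux_ids),
        eps_max=pd.Series(_clean(raw.mu_ub[n_v:]), index=enz_ids),
        eps_min=pd.Series(_clean(raw.mu_lb[n_v:]), index=enz_ids),
        pi=pi,
        status="optimal",
        backend=raw.backend,
        tolerance=tol,
    )
    sol.degenerate = _diagnose_degeneracy(sol, pam, lp)
    return sol


def _infeasibility_hint(pam: PamModel) -> str | None:
    net = pam.network
    forced = [r for r in net.reactions if net.lb(r) > 0]
    if forced:
        return (
            "reactions with positive lower bounds may exceed available "
            f"capacity: {forced}"
        )
    return None


def _diagnose_degeneracy(
    sol: PrimalDualSolution, pam: PamModel, lp: LinearProgram, tol: float = 1e-7
) -> bool:
    """Heuristic degeneracy flag.

    Shadow prices are non-unique at degenerate optima; the reported
    coefficients are then one valid subgradient choice.  We flag (a)
    variables sitting at a bound with zero reduced cost (alternative
    optima) and (b) more active constraints than variables (primal
    degeneracy).
    """
    x = np.concatenate([sol.fluxes.to_numpy(), sol.enzymes.to_numpy()])
    n_v = len(sol.fluxes)
    # reduced costs from the dual solution
    y_ub = np.concatenate(
        [sol.xi.to_numpy(), [] if sol.pi is None else [sol.pi_value]]
    )
    aty = lp.A_eq.T @ sol.lam.to_numpy() + lp.A_ub.T @ y_ub
    rc = lp.c - aty
    at_lb = np.isfinite(lp.lb) & (x <= lp.lb + tol)
    at_ub = np.isfinite(lp.ub) & (x >= lp.ub - tol)
    nonbasic_zero_rc = ((at_lb | at_ub) & (np.abs(rc) < tol)).sum()
    n_active = int(
        lp.A_eq.shape[0]
        + ((lp.b_ub - lp.A_ub @ x) < tol).sum()
        + (at_lb | at_ub).sum()
    )
    return bool(nonbasic_zero_rc > 0 or n_active > lp.n)


# ---------------------------------------------------------------------------
# explicit dual (verification oracle)


def build_dual(pam: PamModel) -> LinearProgram:
    """Construct the explicit dual program of the PAM.

    Minimize ``vmax.mu_max - vmin.mu_min + emax.eps_max - emin.eps_min +
    phi0 pi`` subject to dual feasibility

    * per flux i:  ``(S^T lambda)_i + (Kinv^T xi)_i + mu_max_i -
      mu_min_i + pi w_i >= c_i``
    * per enzyme j: ``-xi_j + eps_max_j - eps_min_j + pi m_j >= 0``

    with every dual nonnegative except lambda.  Variables for absent
    (infinite) primal bounds are omitted, so their implied duals are
    identically zero.  Returned as a maximization of the negated
    objective to fit the backend contract; :func:`solve_dual` undoes the
    negation.
    """
    net = pam.network
    flux_ids, enz_ids = _column_layout(pam)
    cat = [e for e in pam.enzymes if e.catalytic]
    has_pi = pam.sectors is not None
    w = pam.sector_weights()

    cols: list[str] = [f"lambda[{m}]" for m in net.metabolites]
    lb = [-np.inf] * len(net.metabolites)
    obj = [0.0] * len(net.metabolites)
    col_of = {name: i for i, name in enumerate(cols)}

    def add(name: str, cost: float) -> int:
        col_of[name] = len(cols)
        cols.append(name)
        lb.append(0.0)
        obj.append(cost)
        return col_of[name]

    for e in cat:
        add(f"xi[{e.enzyme_id}]", 0.0)
    for r in flux_ids:
        if np.isfinite(net.ub(r)):
            add(f"mu_max[{r}]", net.ub(r))
        add(f"mu_min[{r}]", -net.lb(r))
    for e in pam.enzymes:
        if np.isfinite(e.emax):
            add(f"eps_max[{e.enzyme_id}]", e.emax)
        add(f"eps_min[{e.enzyme_id}]", -e.emin)
    if has_pi:
        add("pi", compute_phi0(pam.sectors))

    # dual feasibility rows, written as <= for the backend:
    # -( ... ) <= -c_i
    rows, colidx, vals, rhs, names = [], [], [], [], []
    S = net.s_matrix().tocsc()
    kcat_of: dict[str, tuple[str, float]] = {}
    for e in cat:
        for rid, kc in e.kcats.items():
            kcat_of[rid] = (e.enzyme_id, kc)
    r_index = {r: j for j, r in enumerate(flux_ids)}
    k = 0
    for i, r in enumerate(flux_ids):
        col = S.getcol(r_index[r])
        for mrow, coef in zip(col.indices, col.data):
            rows.append(k); colidx.append(mrow); vals.append(-float(coef))
        if r in kcat_of:
            enz_id, kc = kcat_of[r]
            rows.append(k); colidx.append(col_of[f"xi[{enz_id}]"])
            vals.append(-1.0 / kc)
        if f"mu_max[{r}]" in col_of:
            rows.append(k); colidx.append(col_of[f"mu_max[{r}]"]); vals.append(-1.0)
        rows.append(k); colidx.append(col_of[f"mu_min[{r}]"]); vals.append(1.0)
        if has_pi and w[i] != 0.0:
            rows.append(k); colidx.append(col_of["pi"]); vals.append(-w[i])
        rhs.append(-(1.0 if r == net.objective else 0.0))
        names.append(f"dualfeas_v[{r}]")
        k += 1
    for e in pam.enzymes:
        if e.catalytic:
            rows.append(k); colidx.append(col_of[f"xi[{e.enzyme_id}]"]); vals.append(1.0)
        if f"eps_max[{e.enzyme_id}]" in col_of:
            rows.append(k); colidx.append(col_of[f"eps_max[{e.enzyme_id}]"])
            vals.append(-1.0)
        rows.append(k); colidx.append(col_of[f"eps_min[{e.enzyme_id}]"]); vals.append(1.0)
        if has_pi:
            rows.append(k); colidx.append(col_of["pi"]); vals.append(-e.molar_mass)
        rhs.append(0.0)
        names.append(f"dualfeas_e[{e.enzyme_id}]")
        k += 1

    n = len(cols)
    return LinearProgram(
        c=-np.asarray(obj),  # maximize the negated min-objective
        A_eq=sparse.csr_matrix((0, n)),
        b_eq=np.zeros(0),
        A_ub=sparse.csr_matrix((vals, (rows, colidx)), shape=(k, n)),
        b_ub=np.asarray(rhs),
        lb=np.asarray(lb),
        ub=np.full(n, np.inf),
        col_names=cols,
        eq_names=[],
        ub_names=names,
    )


def solve_dual(pam: PamModel, backend: str = DEFAULT_BACKEND) -> float:
    """Solve the explicit dual program and return its optimal value.

    By strong duality this equals the primal optimum whenever both are
    feasible and finite.
    """
    global _solves_so_far
    lp = build_dual(pam)
    raw = get_backend(backend)(lp, tol=SOLVER_TOL)
    _solves_so_far += 1
    if raw.status != "optimal":
        raise SolverError(f"dual solve returned status {raw.status!r}")
    return -float(raw.objective)


def verify_strong_duality(sol: PrimalDualSolution, pam: PamModel) -> float:
    """Residual of the strong-duality identity.

    ``|vz - (vmax.mu_max - vmin.mu_min + emax.eps_max - emin.eps_min +
    phi0 pi)|`` with terms for absent (unbounded) bounds treated as 0.
    """
    if sol.status != "optimal":
        raise NonOptimalSolutionError(
            f"strong duality requires an optimal solution, got {sol.status!r}"
        )
    net = pam.network
    total = 0.0
    for r in net.reactions:
        if np.isfinite(net.ub(r)):
            total += net.ub(r) * sol.mu_max[r]
        total -= net.lb(r) * sol.mu_min[r]
    for e in pam.enzymes:
        if np.isfinite(e.emax):
            total += e.emax * sol.eps_max[e.enzyme_id]
        total -= e.emin * sol.eps_min[e.enzyme_id]
    if pam.sectors is not None:
        total += compute_phi0(pam.sectors) * sol.pi_value
    return abs(sol.objective - total)


def verify_complementary_slackness(
    sol: PrimalDualSolution, pam: PamModel, tol: float = CHECK_TOL
) -> float:
    """Maximal complementary-slackness violation over all bound duals.

    For every finite bound, ``dual * slack`` must vanish at the optimum;
    returns the largest |dual * slack| found.
    """
    if sol.status != "optimal":
        raise NonOptimalSolutionError("need an optimal solution")
    net = pam.network
    worst = 0.0
    for r in net.reactions:
        if np.isfinite(net.ub(r)):
            worst = max(worst, sol.mu_max[r] * abs(net.ub(r) - sol.fluxes[r]))
        worst = max(worst, sol.mu_min[r] * abs(sol.fluxes[r] - net.lb(r)))
    for e in pam.enzymes:
        ej = sol.enzymes[e.enzyme_id]
        if np.isfinite(e.emax):
            worst = max(worst, sol.eps_max[e.enzyme_id] * abs(e.emax - ej))
        worst = max(worst, sol.eps_min[e.enzyme_id] * abs(ej - e.emin))
    return worst
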