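"""LP solution, shadow-price extraction and duality checks."""

import numpy as np
import pytest

import pamsens as ps
from pamsens.errors import (
    InfeasibleProblemError,
    NonOptimalSolutionError,
    UnboundedProblemError,
)
from pamsens.lp import verify_complementary_slackness
from conftest import random_cases


class TestChain3ClosedForm:
    """Hand-derived primal/dual solution of the three-reaction chain:
    vz = 2, pi = 2, xi = 2, lambda = (0, -1), all bound duals zero."""

    def test_primal(self, chain3_pam):
        sol = ps.solve(chain3_pam)
        assert sol.objective == pytest.approx(2.0, abs=1e-9)
        assert sol.fluxes.to_numpy() == pytest.approx([2, 2, 2], abs=1e-9)
        assert sol.enzymes["E1"] == pytest.approx(1.0, abs=1e-9)

    def test_duals(self, chain3_pam):
        sol = ps.solve(chain3_pam)
        assert sol.pi == pytest.approx(2.0, abs=1e-9)
        assert sol.xi["E1"] == pytest.approx(2.0, abs=1e-9)
        assert sol.lam["A"] == pytest.approx(0.0, abs=1e-9)
        assert sol.lam["B"] == pytest.approx(-1.0, abs=1e-9)
        for series in (sol.mu_max, sol.mu_min, sol.eps_max, sol.eps_min):
            assert np.all(np.abs(series.to_numpy()) < 1e-9)

    def test_flux_limited_variant(self, chain3_pam):
        limited = ps.set_flux_bounds(chain3_pam, "R1", ub=1.0)
        sol = ps.solve(limited)
        assert sol.objective == pytest.approx(1.0, abs=1e-9)
        assert sol.pi == pytest.approx(0.0, abs=1e-9)
        assert sol.mu_max["R1"] == pytest.approx(1.0, abs=1e-9)

    def test_strong_duality_residual_exact(self, chain3_pam):
        sol = ps.solve(chain3_pam)
        assert ps.verify_strong_duality(sol, chain3_pam) < 1e-9


def test_inverted_bounds_raise_infeasible(chain3_pam):
    broken = chain3_pam.copy()
    broken.network.lower_bounds["R1"] = 5.0
    broken.network.upper_bounds["R1"] = 1.0
    with pytest.raises(InfeasibleProblemError):
        ps.solve(broken)


def test_forced_flux_beyond_capacity_is_infeasible(chain3_pam):
    # proteome caps the chain at 2; forcing 5 through is impossible
    forced = ps.set_flux_bounds(chain3_pam, "R3", lb=5.0)
    with pytest.raises(InfeasibleProblemError):
        ps.solve(forced)


def test_unbounded_objective_detected(chain3_pam):
    free = ps.build_pam(chain3_pam.network)  # no enzymes, no sectors
    free.network.upper_bounds.pop("R1")
    with pytest.raises(UnboundedProblemError):
        ps.solve(free)


def test_duals_of_absent_bounds_are_exact_zero(chain3_pam):
    sol = ps.solve(chain3_pam)
    assert sol.mu_max["R3"] == 0.0      # R3 has no upper bound
    assert sol.eps_max["E1"] == 0.0     # E1 has no concentration cap


class TestExplicitDual:
    def test_chain3_dual_optimum_matches_primal(self, chain3_pam):
        assert ps.solve_dual(chain3_pam) == pytest.approx(2.0, abs=1e-9)

    def test_enzyme_free_dual_reduces_to_fba_dual(self, chain3_pam):
        fba = ps.build_pam(chain3_pam.network)
        lp = ps.build_dual(fba)
        assert not any(n.startswith(("xi[", "eps_", "pi")) for n in lp.col_names)
        assert ps.solve_dual(fba) == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("seed,n_rxns,n_enz", random_cases(10))
    def test_strong_duality_on_random_instances(self, seed, n_rxns, n_enz):
        pam = ps.random_pam(seed, n_rxns, n_enz)
        primal = ps.solve(pam).objective
        dual = ps.solve_dual(pam)
        assert abs(primal - dual) <= 1e-6 * max(1.0, abs(primal))


def test_strong_duality_requires_optimal_status(chain3_pam):
    sol = ps.solve(chain3_pam)
    sol.status = "interrupted"
    with pytest.raises(NonOptimalSolutionError):
        ps.verify_strong_duality(sol, chain3_pam)


@pytest.mark.parametrize("seed,n_rxns,n_enz", random_cases(25))
def test_duality_and_slackness_on_random_instances(seed, n_rxns, n_enz):
    """Strong duality and complementary slackness at every optimum."""
    pam = ps.random_pam(seed, n_rxns, n_enz)
    sol = ps.solve(pam)
    rel = max(1.0, abs(sol.objective))
    assert ps.verify_strong_duality(sol, pam) <= 1e-6 * rel
    assert verify_complementary_slackness(sol, pam) <= 1e-6 * rel
    # sign conventions: every inequality dual nonnegative
    for series in (sol.xi, sol.mu_max, sol.mu_min, sol.eps_max, sol.eps_min):
        assert np.all(series.to_numpy() >= 0.0)
    assert sol.pi_value >= 0.0


class TestBackendIndependence:
    def test_same_objective_and_duals_on_chain3(self, chain3_pam):
        a = ps.solve(chain3_pam, backend="scipy-highs")
        b = ps.solve(chain3_pam, backend="glpk")
        assert a.objective == pytest.approx(b.objective, abs=1e-6)
        assert a.pi == pytest.approx(b.pi, abs=1e-6)
        assert a.xi["E1"] == pytest.approx(b.xi["E1"], abs=1e-6)

    @pytest.mark.parametrize("seed,n_rxns,n_enz", random_cases(5, start=40))
    def test_matching_coefficients_on_random_instances(
        self, seed, n_rxns, n_enz
    ):
        pam = ps.random_pam(seed, n_rxns, n_enz)
        ra = ps.analyze(pam, backend="scipy-highs")
        rb = ps.analyze(pam, backend="glpk")
        assert ra.objective == pytest.approx(rb.objective, abs=1e-6)
        if not (ra.degenerate or rb.degenerate):
            assert np.allclose(
                ra.flux_csc.to_numpy(), rb.flux_csc.to_numpy(), atol=1e-4
            )
            assert np.allclose(ra.esc.to_numpy(), rb.esc.to_numpy(), atol=1e-4)


def test_fba_optimum_matches_cobra_oracle(chain3_pam):
    """The enzyme-free model must agree with an independent FBA solver."""
    import cobra

    model = cobra.Model("chain3")
    mets = {m: cobra.Metabolite(m) for m in ("A", "B")}
    defs = {
        "R1": ({"A": 1.0}, 0.0, 10.0),
        "R2": ({"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        "R3": ({"B": -1.0}, 0.0, 1000.0),
    }
    for rid, (st, lb, ub) in defs.items():
        rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({mets[m]: c for m, c in st.items()})
        model.add_reactions([rxn])
    model.objective = "R3"
    oracle = model.optimize().objective_value
    ours = ps.solve(ps.build_pam(chain3_pam.network)).objective
    assert ours == pytest.approx(oracle, abs=1e-6)
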