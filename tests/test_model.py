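"""Model assembly: sector budget, irreversibilization, edits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pamsens as ps
from pamsens.errors import (
    InvalidBoundsError,
    InvalidSectorConfigError,
    IsozymeError,
    ModelBuildError,
)
from pamsens.model import StoichiometricNetwork, split_reversible


@pytest.mark.parametrize(
    "phi_total, phi_T0, phi_UE0, expected",
    [(100, 10, 20, 70), (100, 0, 0, 100), (1.0, 0.25, 0.25, 0.5)],
)
def test_protein_budget_is_total_minus_intercepts(
    phi_total, phi_T0, phi_UE0, expected
):
    cfg = ps.SectorConfig(phi_total=phi_total, phi_T0=phi_T0, phi_UE0=phi_UE0)
    assert ps.compute_phi0(cfg) == pytest.approx(expected)


def test_negative_protein_budget_rejected():
    with pytest.raises(InvalidSectorConfigError):
        ps.SectorConfig(phi_total=10, phi_T0=8, phi_UE0=5)


def _net(lb, ub):
    return StoichiometricNetwork(
        metabolites=["A"],
        reactions=["R", "SINK"],
        stoichiometry={"R": {"A": 1.0}, "SINK": {"A": -1.0}},
        lower_bounds={"R": lb},
        upper_bounds={"R": ub},
        objective="SINK",
    )


@pytest.mark.parametrize(
    "lb, ub, fwd, rev",
    [
        (-5, 10, (0, 10), (0, 5)),
        (-5, -1, (0, 0), (1, 5)),
        (-3, math.inf, (0, math.inf), (0, 3)),
    ],
)
def test_split_reversible_bounds(lb, ub, fwd, rev):
    out = split_reversible(_net(lb, ub))
    assert (out.lb("R"), out.ub("R")) == fwd
    assert (out.lb("R__rev"), out.ub("R__rev")) == rev
    # reverse column is the exact negation of the forward column
    assert out.stoichiometry["R__rev"] == {"A": -1.0}


def test_split_leaves_irreversible_reactions_alone():
    out = split_reversible(_net(0, 10))
    assert "R__rev" not in out.reactions
    assert (out.lb("R"), out.ub("R")) == (0, 10)


def test_split_rejects_inverted_bounds():
    with pytest.raises(InvalidBoundsError):
        split_reversible(_net(5, 1))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    lb=st.floats(-20, 5),
    ub=st.floats(-20, 20),
    flux=st.floats(-20, 20),
)
def test_split_round_trip_preserves_feasible_flux(lb, ub, flux):
    """Any flux in [lb, ub] decomposes as v_fwd - v_rev with both parts
    feasible in the split network."""
    if lb > ub:
        lb, ub = ub, lb
    flux = min(max(flux, lb), ub)
    out = split_reversible(_net(lb, ub))
    if lb >= 0:
        assert out.lb("R") <= flux <= out.ub("R")
        return
    v_fwd, v_rev = max(flux, 0.0), max(-flux, 0.0)
    # shift into the split bounds if a direction is forced
    v_fwd = min(max(v_fwd, out.lb("R")), out.ub("R"))
    v_rev = min(max(v_rev, out.lb("R__rev")), out.ub("R__rev"))
    assert v_fwd - v_rev == pytest.approx(flux, abs=1e-9)


def test_build_counts_rows_for_chain3(chain3_pam):
    lp = ps.build_primal(chain3_pam)
    assert lp.A_eq.shape[0] == 2          # two metabolite balances
    assert lp.ub_names == ["coupling[E1]", "proteome"]


def test_enzyme_free_model_reduces_to_fba(chain3_pam):
    fba = ps.build_pam(chain3_pam.network)
    sol = ps.solve(fba)
    assert sol.objective == pytest.approx(10.0)  # only the uptake bound
    assert sol.pi is None and len(sol.xi) == 0


def test_unknown_catalyzed_reaction_rejected(chain3_pam):
    bad = ps.EnzymeEntry("EX", molar_mass=1.0, kcats={"NOPE": 1.0})
    with pytest.raises(ModelBuildError, match="NOPE"):
        ps.build_pam(chain3_pam.network, [bad])


def test_isozymes_rejected(chain3_pam):
    extra = ps.EnzymeEntry("E2", molar_mass=1.0, kcats={"R2": 3.0})
    with pytest.raises(IsozymeError):
        ps.build_pam(chain3_pam.network, [*chain3_pam.enzymes, extra])


def test_nonpositive_kcat_rejected():
    with pytest.raises(ModelBuildError):
        ps.EnzymeEntry("E", molar_mass=1.0, kcats={"R": 0.0})


class TestGeckoReduction:
    def test_flux_terms_dropped(self, toy):
        gecko = ps.derive_gecko(toy, pool=100.0)
        assert np.all(gecko.sector_weights() == 0.0)
        assert gecko.phi0 == pytest.approx(100.0)

    def test_pool_equal_to_phi0_preserves_chain3_optimum(self, chain3_pam):
        gecko = ps.derive_gecko(chain3_pam, pool=1.0)
        assert ps.solve(gecko).objective == pytest.approx(2.0)

    def test_halving_the_pool_halves_the_optimum(self, chain3_pam):
        gecko = ps.derive_gecko(chain3_pam, pool=0.5)
        assert ps.solve(gecko).objective == pytest.approx(1.0)

    def test_nonpositive_pool_rejected(self, chain3_pam):
        with pytest.raises(ModelBuildError):
            ps.derive_gecko(chain3_pam, pool=0.0)


class TestInertProtein:
    def test_zero_concentration_is_free(self, chain3_pam):
        edited = ps.add_inert_protein(chain3_pam, "GFP", 1.0, 0.0)
        assert ps.solve(edited).objective == pytest.approx(2.0)

    def test_burden_shrinks_enzyme_budget(self, chain3_pam):
        edited = ps.add_inert_protein(chain3_pam, "GFP", 1.0, 0.5)
        assert ps.solve(edited).objective == pytest.approx(1.0)

    def test_objective_non_increasing_in_concentration(self, chain3_pam):
        previous = math.inf
        for conc in [0.0, 0.2, 0.5, 0.9]:
            vz = ps.solve(
                ps.add_inert_protein(chain3_pam, "GFP", 1.0, conc)
            ).objective
            assert vz <= previous + 1e-9
            previous = vz

    def test_negative_concentration_rejected(self, chain3_pam):
        with pytest.raises(ModelBuildError):
            ps.add_inert_protein(chain3_pam, "GFP", 1.0, -0.1)

    def test_drain_consumes_metabolite(self, chain3_pam):
        edited = ps.add_inert_protein(
            chain3_pam, "GFP", 1.0, 0.2, drain={"A": 1.0}
        )
        sol = ps.solve(edited)
        assert sol.fluxes["GFP__drain"] == pytest.approx(0.2)
        # drained A must come through the uptake on top of chain flux
        assert sol.fluxes["R1"] == pytest.approx(sol.fluxes["R2"] + 0.2)


class TestKcatUpdate:
    def test_identity_factor(self, chain3_pam):
        same = ps.update_kcat(chain3_pam, "E1", "R2", 1.0)
        assert ps.solve(same).objective == pytest.approx(2.0)

    def test_doubling_kcat_doubles_proteome_limited_optimum(self, chain3_pam):
        fast = ps.update_kcat(chain3_pam, "E1", "R2", 2.0)
        assert ps.solve(fast).objective == pytest.approx(4.0)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_nonpositive_factor_rejected(self, chain3_pam, factor):
        with pytest.raises(ModelBuildError):
            ps.update_kcat(chain3_pam, "E1", "R2", factor)

    def test_unknown_pair_rejected(self, chain3_pam):
        with pytest.raises(ModelBuildError):
            ps.update_kcat(chain3_pam, "E1", "R3", 2.0)


def test_knockout_fixes_bounds_to_zero(chain3_pam):
    ko = ps.knock_out(chain3_pam, "R2")
    assert ko.network.lb("R2") == ko.network.ub("R2") == 0.0
    assert ps.solve(ko).objective == pytest.approx(0.0)


def test_proteome_row_units_bounded_by_phi0(toy):
    sol = ps.solve(toy)
    mass = {e.enzyme_id: e.molar_mass for e in toy.enzymes}
    burden = sum(mass[k] * v for k, v in sol.enzymes.items())
    burden += float(np.dot(toy.sector_weights(),
                           sol.fluxes.to_numpy()))
    assert burden <= ps.compute_phi0(toy.sectors) + 1e-6
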