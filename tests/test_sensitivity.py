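"""Capacity/enzyme sensitivity coefficients and theorem identities."""

import numpy as np
import pandas as pd
import pytest

import pamsens as ps
from pamsens.errors import NonOptimalSolutionError, ZeroObjectiveError
from pamsens.sensitivity import summation_report, top_sensitivities
from conftest import random_cases


class TestChain3Coefficients:
    def test_proteome_limited_report(self, chain3_pam):
        rep = ps.analyze(chain3_pam)
        assert rep.proteome_csc == pytest.approx(1.0, abs=1e-9)
        assert np.all(rep.flux_csc.to_numpy() == 0.0)
        assert rep.esc["E1"] == pytest.approx(1.0, abs=1e-9)
        assert rep.alpha == pytest.approx(1.0, abs=1e-9)
        assert max(
            rep.residual_capacity,
            rep.residual_connectivity_flux,
            rep.residual_connectivity_enzyme,
        ) < 1e-9

    def test_flux_limited_variant(self, chain3_pam):
        limited = ps.set_flux_bounds(chain3_pam, "R1", ub=1.0)
        rep = ps.analyze(limited)
        assert rep.flux_csc["R1"] == pytest.approx(1.0, abs=1e-9)
        assert rep.proteome_csc == 0.0
        # no capacity limit on enzymes -> every ESC vanishes
        assert np.all(rep.esc.to_numpy() == 0.0)

    def test_enzyme_bound_limited_variant(self, chain3_pam):
        capped = chain3_pam.copy()
        capped.enzyme("E1").emax = 0.4
        rep = ps.analyze(capped)
        assert rep.objective == pytest.approx(0.8, abs=1e-9)
        assert rep.enzyme_csc["E1"] == pytest.approx(1.0, abs=1e-9)
        assert rep.esc["E1"] == pytest.approx(1.0, abs=1e-9)
        assert rep.proteome_csc == 0.0
        assert rep.alpha == pytest.approx(0.4, abs=1e-9)

    def test_active_lower_bound_gives_negative_flux_csc(self, chain3_pam):
        """A maintenance-style forced flux drains capacity: its CSC is
        negative (relaxing the requirement would raise the optimum)."""
        pam = chain3_pam.copy()
        pam.network.reactions.append("MAINT")
        pam.network.stoichiometry["MAINT"] = {"B": -1.0}
        pam.network.lower_bounds["MAINT"] = 1.0
        rep = ps.analyze(pam)
        assert rep.objective == pytest.approx(1.0, abs=1e-9)
        assert rep.flux_csc["MAINT"] == pytest.approx(-1.0, abs=1e-9)
        assert rep.residual_capacity < 1e-9


def test_zero_objective_raises(chain3_pam):
    blocked = ps.set_flux_bounds(chain3_pam, "R1", ub=0.0)
    with pytest.raises(ZeroObjectiveError):
        ps.analyze(blocked)


def test_non_optimal_solution_rejected(chain3_pam):
    sol = ps.solve(chain3_pam)
    sol.status = "interrupted"
    with pytest.raises(NonOptimalSolutionError):
        ps.compute_csc(sol, chain3_pam)


@pytest.mark.parametrize("seed,n_rxns,n_enz", random_cases(30))
def test_identities_hold_on_random_instances(seed, n_rxns, n_enz):
    """Capacity summation and both connectivity relations at 1e-6."""
    pam = ps.random_pam(seed, n_rxns, n_enz)
    rep = ps.analyze(pam)
    r_cap, r_flux, r_enz = summation_report(rep)
    assert r_cap <= 1e-6
    assert r_flux <= 1e-6
    assert r_enz <= 1e-6
    assert np.all(rep.esc.to_numpy() >= 0.0)
    assert 0.0 <= rep.alpha <= 1.0 + 1e-9


def test_corrupted_coefficient_breaks_the_identity(chain3_pam):
    rep = ps.analyze(chain3_pam)
    rep.flux_csc["R1"] = 0.3
    r_cap, _, _ = summation_report(rep)
    assert r_cap == pytest.approx(0.3, abs=1e-9)


def test_esc_sum_zero_when_no_capacity_active(chain3_pam):
    """If the proteome and all enzyme CSCs vanish, so does every ESC."""
    limited = ps.set_flux_bounds(chain3_pam, "R1", ub=1.0)
    rep = ps.analyze(limited)
    assert rep.proteome_csc == 0.0
    assert float(rep.enzyme_csc.abs().sum()) == 0.0
    assert float(rep.esc.sum()) == 0.0


def test_gsmm_limit_flux_cscs_alone_sum_to_one():
    """Without enzymes and sectors the model is a conventional GSMM:
    flux CSCs carry all the control."""
    pam = ps.random_pam(seed=2, n_rxns=10, n_enz=0)
    assert pam.sectors is None and not pam.enzymes
    rep = ps.analyze(pam)
    assert float(rep.esc.sum()) == 0.0
    assert float(rep.flux_csc.sum()) == pytest.approx(1.0, abs=1e-6)


class TestTopSensitivities:
    def test_chain3_ranking(self, chain3_pam):
        table = top_sensitivities(ps.analyze(chain3_pam))
        assert set(zip(table["kind"], table["id"])) == {
            ("proteome_csc", "proteome"),
            ("esc", "E1"),
        }
        assert table["coefficient"].tolist() == pytest.approx([1.0, 1.0])

    def test_high_threshold_empties_table(self, chain3_pam):
        assert len(top_sensitivities(ps.analyze(chain3_pam), threshold=2)) == 0

    def test_ties_break_by_kind_then_id(self, chain3_pam):
        table = top_sensitivities(ps.analyze(chain3_pam))
        # both coefficients are exactly 1; 'esc' sorts before 'proteome_csc'
        assert table["kind"].tolist() == ["esc", "proteome_csc"]

    def test_inert_proteins_hidden_by_default(self, chain3_pam):
        pam = ps.add_inert_protein(chain3_pam, "GFP", 1.0, 0.5)
        rep = ps.analyze(pam)
        shown = top_sensitivities(rep, threshold=0.0)
        assert "GFP" not in set(shown["id"])
        with_inert = top_sensitivities(rep, threshold=0.0, include_inert=True)
        assert "GFP" in set(with_inert["id"])


def test_report_writer_schema(tmp_path, chain3_pam):
    rep = ps.analyze(chain3_pam)
    csv_path, json_path = ps.write_report(rep, tmp_path)
    df = pd.read_csv(csv_path)
    assert list(df.columns) == ["kind", "id", "coefficient", "normalized_by"]
    assert (df["kind"] == "proteome_csc").sum() == 1
    assert json_path.exists()


def test_report_writer_deterministic(tmp_path, chain3_pam):
    rep = ps.analyze(chain3_pam)
    a, _ = ps.write_report(rep, tmp_path / "a")
    b, _ = ps.write_report(rep, tmp_path / "b")
    assert a.read_bytes() == b.read_bytes()
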