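"""Synthetic model generators.

Three families of fully self-contained models make the package testable
without any downloads:

* :func:`chain3` — a three-reaction chain whose optimum and every
  shadow price are known in closed form (the worked example used
  throughout the test suite);
* :func:`toy_pam` — a small network with a protein-efficient,
  low-ATP-yield fermentation route and a protein-hungry, high-yield
  respiration route, built to exhibit the classic three-phase
  flux-limited / co-limited / proteome-limited transition (and hence
  overflow metabolism) along a substrate-uptake sweep;
* :func:`random_pam` — randomized chain/branch networks, feasible and
  bounded by construction, for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelBuildError
from .model import (
    EnzymeEntry,
    PamModel,
    SectorConfig,
    StoichiometricNetwork,
    build_pam,
    compute_phi0,
)

__all__ = ["chain3", "ToyParams", "toy_pam", "random_pam"]


def chain3() -> PamModel:
    """Hand-solvable three-reaction chain.

    ``R1: -> A`` (uptake, vmax 10), ``R2: A -> B`` catalyzed by enzyme
    E1 (kcat 2/h, mass 1 g/mol), ``R3: B ->`` (objective).  Protein
    budget phi0 = 1 mg/gCDW with zero sector slopes.

    Closed form: the proteome row forces e1 <= 1, the coupling row
    v2 <= kcat e1 <= 2, so vz = 2 with duals pi = 2, xi = 2,
    lambda_A = 0, lambda_B = -1 and all bound duals zero.  Hence
    proteome CSC = 1, ESC(E1) = 1, alpha = 1.
    """
    net = StoichiometricNetwork(
        metabolites=["A", "B"],
        reactions=["R1", "R2", "R3"],
        stoichiometry={
            "R1": {"A": 1.0},
            "R2": {"A": -1.0, "B": 1.0},
            "R3": {"B": -1.0},
        },
        lower_bounds={"R1": 0.0, "R2": 0.0, "R3": 0.0},
        upper_bounds={"R1": 10.0},
        objective="R3",
        substrate="R1",
        biomass="R3",
    )
    enzymes = [EnzymeEntry("E1", molar_mass=1.0, kcats={"R2": 2.0})]
    sectors = SectorConfig(phi_total=1.0, biomass_rxn="R3", substrate_rxn="R1")
    return build_pam(net, enzymes, sectors)


@dataclass
class ToyParams:
    """Parameters of the toy overflow model.

    The network routes substrate through glycolysis into either a
    fermentation-like pathway (protein-efficient, low ATP yield, with a
    secreted byproduct) or a respiration-like pathway (protein-hungry,
    high ATP yield).  Biomass consumes precursor and ATP.  Protein
    makes up 60% of cell dry weight, split between the metabolic
    (active-enzyme), translational and unused-enzyme sectors.

    kcats in 1/h, masses in g/mol, phi in mg/gCDW; the dict keys are the
    enzyme ids E1 (uptake), E2 (glycolysis), E3 (fermentation), E4/E5
    (respiration, two steps).
    """

    kcat: dict[str, float] = field(
        default_factory=lambda: {
            "E1": 1.0, "E2": 5.0, "E3": 10.0, "E4": 2.0, "E5": 2.0,
        }
    )
    mass: dict[str, float] = field(
        default_factory=lambda: {
            "E1": 10.0, "E2": 10.0, "E3": 10.0, "E4": 20.0, "E5": 20.0,
        }
    )
    #: ATP produced per unit flux: glycolysis, fermentation, respiration
    atp_yield_glycolysis: float = 1.0
    atp_yield_fermentation: float = 1.0
    atp_yield_respiration: float = 4.0
    #: biomass stoichiometry: precursor and ATP consumed per unit growth
    biomass_precursor: float = 1.0
    biomass_atp: float = 5.0
    #: protein sectors (mg/gCDW); total protein is 60% of dry weight
    phi_total: float = 600.0
    phi_T0: float = 275.0
    w_T: float = 10.0
    phi_UE0: float = 275.0
    w_UE: float = 1.0
    uptake_max: float = 10.0

    def protein_cost(self, enzyme_id: str) -> float:
        """Protein burden per unit flux, m/kcat (mg h/gCDW per flux)."""
        return self.mass[enzyme_id] / self.kcat[enzyme_id]

    def validate(self) -> None:
        """The structural premise: fermentation is the protein-cheaper
        but lower-yield ATP route."""
        ferm_cost = self.protein_cost("E3") / self.atp_yield_fermentation
        resp_cost = (
            self.protein_cost("E4") + self.protein_cost("E5")
        ) / self.atp_yield_respiration
        if not ferm_cost < resp_cost:
            raise ModelBuildError(
                "fermentation must be more protein-efficient per ATP than "
                f"respiration (got {ferm_cost:g} vs {resp_cost:g})"
            )
        if not self.atp_yield_fermentation < self.atp_yield_respiration:
            raise ModelBuildError(
                "respiration must have the higher ATP yield (got "
                f"{self.atp_yield_fermentation:g} vs "
                f"{self.atp_yield_respiration:g})"
            )


def toy_pam(params: ToyParams | None = None) -> PamModel:
    """Toy PAM with substrate uptake (R1), glycolysis (R2),
    fermentation (R3) with byproduct excretion (R6), a two-step
    respiration route (R4, R5) and a biomass reaction (R7).

    With default parameters, sweeping the uptake bound produces three
    phases: uptake-limited growth on pure respiration, a co-limited
    overflow regime where fermentation engages, and a fully
    proteome-limited plateau.
    """
    p = params or ToyParams()
    p.validate()
    net = StoichiometricNetwork(
        metabolites=["glc", "prec", "inter", "atp", "byp"],
        reactions=["R1", "R2", "R3", "R4", "R5", "R6", "R7"],
        stoichiometry={
            "R1": {"glc": 1.0},
            "R2": {"glc": -1.0, "prec": 1.0, "atp": p.atp_yield_glycolysis},
            "R3": {"prec": -1.0, "byp": 1.0, "atp": p.atp_yield_fermentation},
            "R4": {"prec": -1.0, "inter": 1.0},
            "R5": {"inter": -1.0, "atp": p.atp_yield_respiration},
            "R6": {"byp": -1.0},
            "R7": {"prec": -p.biomass_precursor, "atp": -p.biomass_atp},
        },
        upper_bounds={"R1": p.uptake_max},
        objective="R7",
        substrate="R1",
        biomass="R7",
    )
    enzymes = [
        EnzymeEntry("E1", p.mass["E1"], {"R1": p.kcat["E1"]}),
        EnzymeEntry("E2", p.mass["E2"], {"R2": p.kcat["E2"]}),
        EnzymeEntry("E3", p.mass["E3"], {"R3": p.kcat["E3"]}),
        EnzymeEntry("E4", p.mass["E4"], {"R4": p.kcat["E4"]}),
        EnzymeEntry("E5", p.mass["E5"], {"R5": p.kcat["E5"]}),
    ]
    sectors = SectorConfig(
        phi_total=p.phi_total,
        phi_T0=p.phi_T0,
        w_T=p.w_T,
        phi_UE0=p.phi_UE0,
        w_UE=p.w_UE,
        biomass_rxn="R7",
        substrate_rxn="R1",
    )
    return build_pam(net, enzymes, sectors)


def random_pam(
    seed: int,
    n_rxns: int = 12,
    n_enz: int = 4,
    max_retries: int = 25,
) -> PamModel:
    """Random feasible, bounded PAM (deterministic given ``seed``).

    The network is a linear chain from one uptake reaction to one
    objective sink, decorated with forward branch reactions between
    chain metabolites; this motif structure guarantees mass balance and
    boundedness (the uptake bound caps every flux).  kcats are drawn
    log-uniformly from [1, 1e4] 1/h and masses from [1e3, 1e6] g/mol;
    the protein budget is scaled to the enzyme cost of carrying a
    substantial fraction of the uptake bound, so that instances land on
    either side of the flux/proteome-limited boundary.  Occasional
    finite flux and enzyme upper bounds exercise every dual term.

    Draws whose optimum is zero or non-finite are rejected and
    resampled (still deterministically) up to ``max_retries`` times.
    """
    if n_rxns < 3:
        raise ModelBuildError("need at least uptake, conversion and sink")
    if n_enz < 0 or n_enz > n_rxns - 2:
        raise ModelBuildError(
            f"n_enz must be in [0, n_rxns - 2], got {n_enz}"
        )
    from .errors import PamError
    from .lp import solve

    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(attempt,))
        )
        pam = _draw_random_pam(rng, n_rxns, n_enz)
        try:
            sol = solve(pam)
        except PamError:
            continue
        if sol.objective <= 1e-6:
            continue
        if pam.sectors is not None:
            # physically coherent sector draw: metabolic enzymes must fit
            # inside the nominal budget (active-enzyme fraction <= 1);
            # otherwise the unused-sector relief dominates, which the
            # generator treats as an invalid parameterization
            burden = sum(
                e.molar_mass * sol.enzymes[e.enzyme_id] for e in pam.enzymes
            )
            if burden > compute_phi0(pam.sectors) * (1 + 1e-9):
                continue
        return pam
    raise ModelBuildError(
        f"random_pam(seed={seed}) failed to draw a solvable instance "
        f"in {max_retries} attempts"
    )


def _draw_random_pam(
    rng: np.random.Generator, n_rxns: int, n_enz: int
) -> PamModel:
    n_branch = int(rng.integers(0, max((n_rxns - 3) // 3, 0) + 1))
    n_chain = n_rxns - n_branch  # includes uptake + sink
    n_mets = n_chain - 1
    mets = [f"M{i}" for i in range(n_mets)]
    reactions: dict[str, dict[str, float]] = {"UPT": {"M0": 1.0}}
    for i in range(n_mets - 1):
        reactions[f"C{i}"] = {f"M{i}": -1.0, f"M{i+1}": 1.0}
    reactions["SINK"] = {f"M{n_mets-1}": -1.0}
    for b in range(n_branch):
        i = int(rng.integers(0, n_mets - 1))
        j = int(rng.integers(i + 1, n_mets))
        yield_ = float(rng.uniform(0.5, 1.5))
        reactions[f"B{b}"] = {f"M{i}": -1.0, f"M{j}": yield_}

    uptake_max = float(rng.uniform(1.0, 10.0))
    upper = {"UPT": uptake_max}
    rids = list(reactions)
    net = StoichiometricNetwork(
        metabolites=mets,
        reactions=rids,
        stoichiometry=reactions,
        upper_bounds=upper,
        objective="SINK",
        substrate="UPT",
        biomass="SINK",
    )

    candidates = [r for r in rids if r not in ("UPT", "SINK")]
    rng.shuffle(candidates)
    enzymes = []
    unit_cost = 0.0  # protein per unit of chain flux, mg h/gCDW
    for k in range(n_enz):
        rid = candidates[k]
        kcat = float(np.exp(rng.uniform(np.log(1.0), np.log(1e4))))
        mass = float(np.exp(rng.uniform(np.log(1e3), np.log(1e6))))
        emax = np.inf
        if rng.uniform() < 0.25:
            emax = uptake_max / kcat * float(rng.uniform(0.3, 1.5))
        enzymes.append(
            EnzymeEntry(f"E_{rid}", molar_mass=mass, kcats={rid: kcat},
                        emax=emax)
        )
        unit_cost += mass / kcat
    # a finite flux cap on one interior reaction now and then
    if len(candidates) > n_enz and rng.uniform() < 0.4:
        rid = candidates[n_enz]
        net.upper_bounds[rid] = uptake_max * float(rng.uniform(0.3, 1.2))

    sectors = None
    if enzymes:
        phi0 = unit_cost * uptake_max * float(rng.uniform(0.25, 1.5))
        w_T = 0.0
        w_UE = 0.0
        if rng.uniform() < 0.5:
            w_T = phi0 / uptake_max * float(rng.uniform(0.0, 0.3))
        if rng.uniform() < 0.3:
            w_UE = phi0 / uptake_max * float(rng.uniform(0.0, 0.1))
        sectors = SectorConfig(
            phi_total=phi0,
            w_T=w_T,
            w_UE=w_UE,
            biomass_rxn="SINK",
            substrate_rxn="UPT",
        )
    return build_pam(net, enzymes, sectors)
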