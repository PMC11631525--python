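"""Protein allocation models (PAMs).

A PAM extends a stoichiometric (flux balance) model with two kinds of
protein constraints:

* **enzyme coupling** — each catalyzed flux consumes its enzyme in
  proportion to the reciprocal turnover number, ``sum_i v_i / kcat_{i,j}
  <= e_j`` for enzyme *j* over the irreversible reactions it catalyzes;

* **proteome budget** — metabolic enzymes plus coarse-grained protein
  sectors (translation, unused enzymes) share a finite protein pool,
  ``w . v + sum_j m_j e_j <= phi_0`` where ``m_j`` is the enzyme molar
  mass (g/mol), ``e_j`` its concentration (mmol/gCDW), ``phi_0`` the
  condition-independent budget (mg/gCDW) and ``w`` carries the sector
  slopes on the biomass and substrate-uptake fluxes.

Units are fixed at the API boundary: kcat in 1/h, masses in g/mol,
enzyme concentrations in mmol/gCDW, protein fractions in mg/gCDW and
fluxes in mmol/gCDW/h, so the product ``m_j * e_j`` lands in mg/gCDW
without hidden conversion factors.

All model-editing operations return a new :class:`PamModel`; inputs are
never mutated.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import (
    InvalidBoundsError,
    InvalidSectorConfigError,
    IsozymeError,
    ModelBuildError,
)

__all__ = [
    "StoichiometricNetwork",
    "EnzymeEntry",
    "SectorConfig",
    "PamModel",
    "compute_phi0",
    "split_reversible",
    "build_pam",
    "derive_gecko",
    "add_inert_protein",
    "update_kcat",
    "scale_enzyme_kcats",
    "set_flux_bounds",
    "knock_out",
]

#: Sentinel for an absent (unbounded) upper bound.  Represented as
#: ``inf`` rather than a big-M number so that its dual variable is
#: identically zero.
UNBOUNDED = math.inf


@dataclass
class StoichiometricNetwork:
    """An irreversible (or to-be-split) metabolic network.

    Parameters
    ----------
    metabolites
        Metabolite ids, defining the row order of the stoichiometric
        matrix.
    reactions
        Reaction ids, defining the column order.
    stoichiometry
        ``{reaction_id: {metabolite_id: coefficient}}``; negative
        coefficients consume, positive produce.
    lower_bounds, upper_bounds
        Flux bounds per reaction (mmol/gCDW/h).  Missing entries default
        to 0 and unbounded respectively.
    objective
        Id of the objective reaction (the flux to maximize).
    substrate, biomass
        Optional ids of the substrate-uptake and biomass reactions, used
        to attach sector slopes and to drive uptake sweeps.
    """

    metabolites: list[str]
    reactions: list[str]
    stoichiometry: dict[str, dict[str, float]]
    lower_bounds: dict[str, float] = field(default_factory=dict)
    upper_bounds: dict[str, float] = field(default_factory=dict)
    objective: str | None = None
    substrate: str | None = None
    biomass: str | None = None

    def __post_init__(self) -> None:
        known = set(self.reactions)
        for rid in list(self.lower_bounds) + list(self.upper_bounds):
            if rid not in known:
                raise ModelBuildError(f"bound refers to unknown reaction {rid!r}")
        for rid, mets in self.stoichiometry.items():
            if rid not in known:
                raise ModelBuildError(
                    f"stoichiometry refers to unknown reaction {rid!r}"
                )
            for mid in mets:
                if mid not in self.metabolites:
                    raise ModelBuildError(
                        f"reaction {rid!r} refers to unknown metabolite {mid!r}"
                    )
        if self.objective is not None and self.objective not in known:
            raise ModelBuildError(f"objective reaction {self.objective!r} not found")

    # -- bounds ---------------------------------------------------------
    def lb(self, rid: str) -> float:
        return self.lower_bounds.get(rid, 0.0)

    def ub(self, rid: str) -> float:
        return self.upper_bounds.get(rid, UNBOUNDED)

    def is_irreversible(self) -> bool:
        return all(self.lb(r) >= 0 for r in self.reactions)

    # -- matrix view ----------------------------------------------------
    def s_matrix(self) -> sparse.csr_matrix:
        """Stoichiometric matrix S (metabolites x reactions)."""
        mi = {m: i for i, m in enumerate(self.metabolites)}
        ri = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for rid, mets in self.stoichiometry.items():
            for mid, coef in mets.items():
                if coef != 0:
                    rows.append(mi[mid])
                    cols.append(ri[rid])
                    vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def copy(self) -> "StoichiometricNetwork":
        return copy.deepcopy(self)


@dataclass
class EnzymeEntry:
    """One enzyme: molar mass, per-reaction turnover numbers and bounds.

    ``kcats`` maps each catalyzed irreversible reaction id to its kcat in
    1/h; one enzyme may cover both split directions of a reversible
    reaction.  Non-catalytic (inert) proteins carry ``catalytic=False``
    and an empty ``kcats`` map; they occupy the proteome but have no
    coupling constraint.
    """

    enzyme_id: str
    molar_mass: float  # g/mol
    kcats: dict[str, float] = field(default_factory=dict)
    emin: float = 0.0
    emax: float = UNBOUNDED
    catalytic: bool = True

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ModelBuildError(
                f"enzyme {self.enzyme_id!r}: molar mass must be > 0"
            )
        for rid, k in self.kcats.items():
            if k <= 0:
                raise ModelBuildError(
                    f"enzyme {self.enzyme_id!r}: kcat for {rid!r} must be > 0"
                )
        if not (0 <= self.emin <= self.emax):
            raise ModelBuildError(
                f"enzyme {self.enzyme_id!r}: need 0 <= emin <= emax"
            )
        if self.catalytic and not self.kcats:
            raise ModelBuildError(
                f"enzyme {self.enzyme_id!r}: catalytic enzyme needs >= 1 kcat"
            )


@dataclass
class SectorConfig:
    """Coarse-grained protein sectors sharing the total proteome.

    The translational sector grows linearly with the growth rate
    (intercept ``phi_T0``, slope ``w_T`` attached to the biomass
    reaction); the unused-enzyme sector shrinks linearly with substrate
    uptake (intercept ``phi_UE0``, slope ``w_UE`` entering the proteome
    row with a negative sign on the uptake flux).  The pure linear form
    is kept — the unused sector is not clipped at zero for large uptake
    rates.  All phi in mg/gCDW, slopes in mg*h/gCDW per flux unit.
    """

    phi_total: float
    phi_T0: float = 0.0
    w_T: float = 0.0
    phi_UE0: float = 0.0
    w_UE: float = 0.0
    biomass_rxn: str | None = None
    substrate_rxn: str | None = None

    def __post_init__(self) -> None:
        if self.phi_T0 < 0 or self.phi_UE0 < 0:
            raise InvalidSectorConfigError("sector intercepts must be >= 0")
        compute_phi0(self)  # validates non-negative budget


def compute_phi0(config: SectorConfig) -> float:
    """Condition-independent protein budget phi_0 (mg/gCDW).

    ``phi_0 = phi_total - phi_T0 - phi_UE0``: the total proteome minus
    the zero-growth intercepts of the translational and unused sectors.
    """
    phi0 = config.phi_total - config.phi_T0 - config.phi_UE0
    if phi0 < 0:
        raise InvalidSectorConfigError(
            f"sector intercepts ({config.phi_T0} + {config.phi_UE0}) exceed "
            f"phi_total ({config.phi_total}): negative protein budget"
        )
    return phi0


@dataclass
class PamModel:
    """A fully assembled protein allocation model.

    ``sectors is None`` means a plain FBA model (no proteome row);
    an empty ``enzymes`` list additionally removes all coupling rows.
    ``reversible_map`` records reactions split during irreversibilization
    as ``{original_id: (forward_id, reverse_id)}``.
    """

    network: StoichiometricNetwork
    enzymes: list[EnzymeEntry] = field(default_factory=list)
    sectors: SectorConfig | None = None
    reversible_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def phi0(self) -> float | None:
        return None if self.sectors is None else compute_phi0(self.sectors)

    @property
    def catalytic_enzymes(self) -> list[EnzymeEntry]:
        return [e for e in self.enzymes if e.catalytic]

    def enzyme(self, enzyme_id: str) -> EnzymeEntry:
        for e in self.enzymes:
            if e.enzyme_id == enzyme_id:
                return e
        raise KeyError(f"no enzyme {enzyme_id!r} in model")

    def sector_weights(self) -> np.ndarray:
        """Flux weight vector w of the proteome row (0 without sectors)."""
        w = np.zeros(len(self.network.reactions))
        if self.sectors is None:
            return w
        ri = {r: j for j, r in enumerate(self.network.reactions)}
        s = self.sectors
        if s.w_T:
            w[ri[s.biomass_rxn]] += s.w_T
        if s.w_UE:
            w[ri[s.substrate_rxn]] -= s.w_UE
        return w

    def copy(self) -> "PamModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# construction


def split_reversible(network: StoichiometricNetwork) -> StoichiometricNetwork:
    """Split every reversible reaction into two irreversible ones.

    A reaction with bounds ``[lb, ub]`` and ``lb < 0`` becomes a forward
    copy bounded ``[max(0, lb), max(0, ub)]`` and a reverse copy (negated
    stoichiometry, id suffixed ``__rev``) bounded ``[max(0, -ub), -lb]``.
    Mass balances are preserved because the reverse column is the exact
    negation of the forward column.  The split is recorded on the
    returned network's ``reversible_pairs`` attribute for bookkeeping by
    :func:`build_pam`.
    """
    out = network.copy()
    pairs: dict[str, tuple[str, str]] = {}
    for rid in list(network.reactions):
        lb, ub = network.lb(rid), network.ub(rid)
        if lb > ub:
            raise InvalidBoundsError(f"reaction {rid!r}: lb {lb} > ub {ub}")
        if lb >= 0:
            continue
        rev = f"{rid}__rev"
        if rev in out.reactions:
            raise ModelBuildError(f"reverse id {rev!r} already taken")
        out.reactions.append(rev)
        out.stoichiometry[rev] = {
            m: -c for m, c in network.stoichiometry.get(rid, {}).items()
        }
        out.lower_bounds[rid] = max(0.0, lb)
        out.upper_bounds[rid] = max(0.0, ub)
        out.lower_bounds[rev] = max(0.0, -ub)
        out.upper_bounds[rev] = -lb
        pairs[rid] = (rid, rev)
    out.reversible_pairs = pairs  # type: ignore[attr-defined]
    return out


def build_pam(
    network: StoichiometricNetwork,
    enzymes: list[EnzymeEntry] | None = None,
    sectors: SectorConfig | None = None,
) -> PamModel:
    """Assemble and validate a :class:`PamModel`.

    The network is irreversibilized if needed.  Validation enforces the
    diagonal enzyme-coupling structure (at most one enzyme per catalyzed
    reaction), existence of every referenced reaction, and that sector
    slopes attach to reactions present in the network.
    """
    enzymes = list(enzymes or [])
    rev_map: dict[str, tuple[str, str]] = {}
    if not network.is_irreversible():
        network = split_reversible(network)
        rev_map = getattr(network, "reversible_pairs", {})
    else:
        network = network.copy()
    for rid in network.reactions:
        if network.lb(rid) > network.ub(rid):
            raise InvalidBoundsError(
                f"reaction {rid!r}: lb {network.lb(rid)} > ub {network.ub(rid)}"
            )

    known = set(network.reactions)
    claimed: dict[str, str] = {}
    for enz in enzymes:
        for rid in enz.kcats:
            if rid not in known:
                raise ModelBuildError(
                    f"enzyme {enz.enzyme_id!r} references unknown reaction {rid!r}"
                )
            if rid in claimed:
                raise IsozymeError(
                    f"reaction {rid!r} is claimed by both {claimed[rid]!r} and "
                    f"{enz.enzyme_id!r}; one enzyme per reaction is required"
                )
            claimed[rid] = enz.enzyme_id
    seen_ids = set()
    for enz in enzymes:
        if enz.enzyme_id in seen_ids:
            raise ModelBuildError(f"duplicate enzyme id {enz.enzyme_id!r}")
        seen_ids.add(enz.enzyme_id)

    if sectors is not None:
        compute_phi0(sectors)
        if sectors.w_T and sectors.biomass_rxn not in known:
            raise ModelBuildError(
                f"sector slope w_T attaches to unknown reaction "
                f"{sectors.biomass_rxn!r}"
            )
        if sectors.w_UE and sectors.substrate_rxn not in known:
            raise ModelBuildError(
                f"sector slope w_UE attaches to unknown reaction "
                f"{sectors.substrate_rxn!r}"
            )
    return PamModel(
        network=network,
        enzymes=enzymes,
        sectors=copy.deepcopy(sectors),
        reversible_map=rev_map,
    )


# ---------------------------------------------------------------------------
# model edits


def derive_gecko(pam: PamModel, pool: float) -> PamModel:
    """Reduce a PAM to a GECKO-style enzyme-constrained model.

    Drops the flux-dependent sectors (translation, unused enzymes) while
    keeping enzyme coupling: the proteome row becomes ``sum m_j e_j <=
    pool`` with no flux terms.
    """
    if pam.sectors is None:
        raise ModelBuildError("model has no sectors to reduce")
    if pool <= 0:
        raise ModelBuildError(f"enzyme pool must be > 0, got {pool}")
    out = pam.copy()
    out.sectors = SectorConfig(phi_total=pool)
    return out


def add_inert_protein(
    pam: PamModel,
    enzyme_id: str,
    molar_mass: float,
    concentration: float,
    drain: dict[str, float] | None = None,
) -> PamModel:
    """Add a non-catalytic protein at a fixed concentration.

    The protein contributes ``molar_mass * concentration`` mg/gCDW of
    burden to the proteome row (``emin = emax = concentration``) but has
    no coupling constraint.  If ``drain`` is given, a pseudo-reaction
    consuming the listed metabolites is added with flux fixed to the
    protein concentration, modelling the precursor cost of expressing
    it; by default only the proteome burden is applied.
    """
    if concentration < 0:
        raise ModelBuildError("inert protein concentration must be >= 0")
    out = pam.copy()
    out.enzymes.append(
        EnzymeEntry(
            enzyme_id=enzyme_id,
            molar_mass=molar_mass,
            kcats={},
            emin=concentration,
            emax=concentration,
            catalytic=False,
        )
    )
    if drain:
        rid = f"{enzyme_id}__drain"
        if rid in out.network.reactions:
            raise ModelBuildError(f"drain id {rid!r} already taken")
        for mid in drain:
            if mid not in out.network.metabolites:
                raise ModelBuildError(f"drain refers to unknown metabolite {mid!r}")
        out.network.reactions.append(rid)
        out.network.stoichiometry[rid] = {m: -abs(c) for m, c in drain.items()}
        out.network.lower_bounds[rid] = concentration
        out.network.upper_bounds[rid] = concentration
    return out


def update_kcat(
    pam: PamModel, enzyme_id: str, reaction_id: str, factor: float
) -> PamModel:
    """Multiply one (enzyme, reaction) kcat by ``factor`` (> 0)."""
    if factor <= 0:
        raise ModelBuildError(f"kcat factor must be > 0, got {factor}")
    out = pam.copy()
    enz = out.enzyme(enzyme_id)
    if reaction_id not in enz.kcats:
        raise ModelBuildError(
            f"enzyme {enzyme_id!r} does not catalyze reaction {reaction_id!r}"
        )
    enz.kcats[reaction_id] *= factor
    return out


def scale_enzyme_kcats(pam: PamModel, enzyme_id: str, factor: float) -> PamModel:
    """Multiply all kcats of one enzyme jointly by ``factor`` (> 0)."""
    if factor <= 0:
        raise ModelBuildError(f"kcat factor must be > 0, got {factor}")
    out = pam.copy()
    enz = out.enzyme(enzyme_id)
    if not enz.kcats:
        raise ModelBuildError(f"enzyme {enzyme_id!r} has no kcats to scale")
    for rid in enz.kcats:
        enz.kcats[rid] *= factor
    return out


def set_flux_bounds(
    pam: PamModel, reaction_id: str, lb: float | None = None, ub: float | None = None
) -> PamModel:
    """Return a copy with updated bounds on one reaction."""
    if reaction_id not in pam.network.reactions:
        raise ModelBuildError(f"unknown reaction {reaction_id!r}")
    out = pam.copy()
    if lb is not None:
        out.network.lower_bounds[reaction_id] = lb
    if ub is not None:
        out.network.upper_bounds[reaction_id] = ub
    new_lb = out.network.lb(reaction_id)
    new_ub = out.network.ub(reaction_id)
    if new_lb > new_ub:
        raise InvalidBoundsError(
            f"reaction {reaction_id!r}: lb {new_lb} > ub {new_ub}"
        )
    return out


def knock_out(pam: PamModel, reaction_id: str) -> PamModel:
    """Inactivate a reaction by fixing its bounds to [0, 0]."""
    return set_flux_bounds(pam, reaction_id, lb=0.0, ub=0.0)
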