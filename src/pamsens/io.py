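"""Readers and writers for the model exchange formats.

Networks are read from SBML Level 3 (FBC) via COBRApy or from a small
JSON dialect documented in the README::

    {
      "metabolites": ["A", "B"],
      "reactions": [
        {"id": "R1", "metabolites": {"A": 1.0},
         "lower_bound": 0.0, "upper_bound": 10.0}
      ],
      "objective": "R3", "substrate": "R1", "biomass": "R3"
    }

A missing or ``null`` upper bound means unbounded.  Enzyme parameters
come from a TSV with header columns ``enzyme_id, reaction_id,
kcat_per_h, molar_mass_g_per_mol, emin, emax`` (one row per catalyzed
reaction; an empty reaction/kcat pair marks an inert protein), and
sector parameters from YAML/JSON with keys ``phi_total, phi_T0, w_T,
phi_UE0, w_UE, biomass_rxn, substrate_rxn``.

Sign convention at the SBML boundary: exchange reactions follow the
FBC habit of negative flux for uptake; reversible reactions (negative
lower bounds) are split into non-negative forward/reverse pairs during
model assembly and the applied conversions are listed in the manifest.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ModelBuildError
from .model import (
    EnzymeEntry,
    PamModel,
    SectorConfig,
    StoichiometricNetwork,
    build_pam,
)

__all__ = [
    "RunConfig",
    "read_network",
    "write_network_json",
    "read_enzyme_table",
    "write_enzyme_table",
    "read_sector_config",
    "write_sector_config",
    "read_pam_inputs",
    "write_pam",
    "read_pam",
]

log = logging.getLogger("pamsens")

SECTOR_KEYS = (
    "phi_total", "phi_T0", "w_T", "phi_UE0", "w_UE",
    "biomass_rxn", "substrate_rxn",
)


@dataclass
class RunConfig:
    """Paths and settings for one reproducible run."""

    model_path: str
    enzyme_path: str | None = None
    sector_path: str | None = None
    objective: str | None = None
    backend: str = "scipy-highs"
    tolerance: float = 1e-9
    kcat_unit: str = "1/h"      # or "1/s" (converted by x3600)
    mass_unit: str = "g/mol"    # or "kDa" (converted by x1000)
    outdir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.model_path, self.enzyme_path, self.sector_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.kcat_unit not in ("1/h", "1/s"):
            raise ValueError(f"unknown kcat unit {self.kcat_unit!r}")
        if self.mass_unit not in ("g/mol", "kDa"):
            raise ValueError(f"unknown mass unit {self.mass_unit!r}")


# ---------------------------------------------------------------------------
# networks


def read_network(path: str | Path) -> StoichiometricNetwork:
    """Read a network from SBML (.xml/.sbml) or the JSON dialect."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return _read_sbml(path)
    if path.suffix.lower() == ".json":
        return _read_network_json(path)
    raise ModelBuildError(
        f"unrecognized network format {path.suffix!r} (expect .json/.xml/.sbml)"
    )


def _read_network_json(path: Path) -> StoichiometricNetwork:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelBuildError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise ModelBuildError(f"{path}: missing {key!r} section")
    stoich, lbs, ubs, rids = {}, {}, {}, []
    for k, rxn in enumerate(data["reactions"]):
        if "id" not in rxn:
            raise ModelBuildError(f"{path}: reaction #{k} has no id")
        rid = rxn["id"]
        rids.append(rid)
        stoich[rid] = {m: float(c) for m, c in rxn.get("metabolites", {}).items()}
        lbs[rid] = float(rxn.get("lower_bound", 0.0))
        ub = rxn.get("upper_bound", None)
        ubs[rid] = math.inf if ub is None else float(ub)
    return StoichiometricNetwork(
        metabolites=list(data["metabolites"]),
        reactions=rids,
        stoichiometry=stoich,
        lower_bounds=lbs,
        upper_bounds=ubs,
        objective=data.get("objective"),
        substrate=data.get("substrate"),
        biomass=data.get("biomass"),
    )


def write_network_json(net: StoichiometricNetwork, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "metabolites": list(net.metabolites),
        "reactions": [
            {
                "id": rid,
                "metabolites": dict(sorted(net.stoichiometry.get(rid, {}).items())),
                "lower_bound": net.lb(rid),
                "upper_bound": None if math.isinf(net.ub(rid)) else net.ub(rid),
            }
            for rid in net.reactions
        ],
        "objective": net.objective,
        "substrate": net.substrate,
        "biomass": net.biomass,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _read_sbml(path: Path) -> StoichiometricNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    stoich = {
        rxn.id: {m.id: float(c) for m, c in rxn.metabolites.items()}
        for rxn in model.reactions
    }
    objective = None
    for rxn in model.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    return StoichiometricNetwork(
        metabolites=[m.id for m in model.metabolites],
        reactions=[r.id for r in model.reactions],
        stoichiometry=stoich,
        lower_bounds={r.id: float(r.lower_bound) for r in model.reactions},
        upper_bounds={
            r.id: (math.inf if r.upper_bound >= 1e30 else float(r.upper_bound))
            for r in model.reactions
        },
        objective=objective,
    )


# ---------------------------------------------------------------------------
# enzyme table


def read_enzyme_table(
    path: str | Path,
    kcat_unit: str = "1/h",
    mass_unit: str = "g/mol",
) -> list[EnzymeEntry]:
    """Read the enzyme TSV, applying unit conversions at the boundary.

    ``kcat_unit="1/s"`` multiplies by 3600; ``mass_unit="kDa"``
    multiplies by 1000.  Errors name the offending row.
    """
    kcat_factor = {"1/h": 1.0, "1/s": 3600.0}[kcat_unit]
    mass_factor = {"g/mol": 1.0, "kDa": 1000.0}[mass_unit]
    rows = list(csv.DictReader(Path(path).open(), delimiter="\t"))
    required = {"enzyme_id", "reaction_id", "kcat_per_h", "molar_mass_g_per_mol"}
    if rows and not required <= set(rows[0]):
        raise ModelBuildError(
            f"{path}: enzyme table must have columns {sorted(required)}"
        )
    grouped: dict[str, dict] = {}
    for k, row in enumerate(rows, start=2):  # header is line 1
        eid = (row.get("enzyme_id") or "").strip()
        if not eid:
            raise ModelBuildError(f"{path}: line {k}: empty enzyme_id")
        g = grouped.setdefault(
            eid,
            {"kcats": {}, "mass": None, "emin": 0.0, "emax": math.inf},
        )
        try:
            g["mass"] = float(row["molar_mass_g_per_mol"]) * mass_factor
            rid = (row.get("reaction_id") or "").strip()
            kc = (row.get("kcat_per_h") or "").strip()
            if rid or kc:
                if not (rid and kc):
                    raise ValueError("reaction_id and kcat must come together")
                g["kcats"][rid] = float(kc) * kcat_factor
            if (row.get("emin") or "").strip():
                g["emin"] = float(row["emin"])
            if (row.get("emax") or "").strip():
                g["emax"] = float(row["emax"])
        except ValueError as exc:
            raise ModelBuildError(f"{path}: line {k}: {exc}") from exc
    return [
        EnzymeEntry(
            enzyme_id=eid,
            molar_mass=g["mass"],
            kcats=g["kcats"],
            emin=g["emin"],
            emax=g["emax"],
            catalytic=bool(g["kcats"]),
        )
        for eid, g in grouped.items()
    ]


def write_enzyme_table(enzymes: list[EnzymeEntry], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["enzyme_id", "reaction_id", "kcat_per_h",
             "molar_mass_g_per_mol", "emin", "emax"]
        )
        for enz in enzymes:
            emax = "" if math.isinf(enz.emax) else repr(enz.emax)
            if enz.kcats:
                for rid in sorted(enz.kcats):
                    writer.writerow(
                        [enz.enzyme_id, rid, repr(enz.kcats[rid]),
                         repr(enz.molar_mass), repr(enz.emin), emax]
                    )
            else:
                writer.writerow(
                    [enz.enzyme_id, "", "", repr(enz.molar_mass),
                     repr(enz.emin), emax]
                )
    return path


# ---------------------------------------------------------------------------
# sector config


def read_sector_config(path: str | Path) -> SectorConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "phi_total" not in data:
        raise ModelBuildError(f"{path}: sector config needs a phi_total key")
    unknown = set(data) - set(SECTOR_KEYS)
    if unknown:
        raise ModelBuildError(f"{path}: unknown sector keys {sorted(unknown)}")
    return SectorConfig(
        phi_total=float(data["phi_total"]),
        phi_T0=float(data.get("phi_T0", 0.0)),
        w_T=float(data.get("w_T", 0.0)),
        phi_UE0=float(data.get("phi_UE0", 0.0)),
        w_UE=float(data.get("w_UE", 0.0)),
        biomass_rxn=data.get("biomass_rxn"),
        substrate_rxn=data.get("substrate_rxn"),
    )


def write_sector_config(sectors: SectorConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = {k: getattr(sectors, k) for k in SECTOR_KEYS}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# assembled models


def read_pam_inputs(config: RunConfig) -> tuple[PamModel, dict]:
    """Assemble a validated PAM from the configured input files.

    Returns the model and a manifest of applied conversions (unit
    factors, reversible splits, objective overrides), also logged at
    INFO level.
    """
    config.validate()
    net = read_network(config.model_path)
    if config.objective is not None:
        net.objective = config.objective
        if config.objective not in net.reactions:
            raise ModelBuildError(
                f"objective override {config.objective!r} not in network"
            )
    enzymes = (
        read_enzyme_table(
            config.enzyme_path, kcat_unit=config.kcat_unit,
            mass_unit=config.mass_unit,
        )
        if config.enzyme_path
        else []
    )
    sectors = read_sector_config(config.sector_path) if config.sector_path else None
    pam = build_pam(net, enzymes, sectors)
    manifest = {
        "model_path": str(config.model_path),
        "kcat_unit": config.kcat_unit,
        "mass_unit": config.mass_unit,
        "reversible_splits": {
            orig: list(pair) for orig, pair in pam.reversible_map.items()
        },
        "objective": pam.network.objective,
        "n_reactions": len(pam.network.reactions),
        "n_enzymes": len(pam.enzymes),
        "has_sectors": pam.sectors is not None,
    }
    log.info("assembled PAM: %s", manifest)
    return pam, manifest


def write_pam(pam: PamModel, directory: str | Path) -> dict[str, Path]:
    """Serialize a PAM to ``model.json`` + ``enzymes.tsv`` (+
    ``sectors.yaml``) in ``directory``; byte-deterministic."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {
        "model": write_network_json(pam.network, directory / "model.json"),
        "enzymes": write_enzyme_table(pam.enzymes, directory / "enzymes.tsv"),
    }
    if pam.sectors is not None:
        out["sectors"] = write_sector_config(
            pam.sectors, directory / "sectors.yaml"
        )
    return out


def read_pam(directory: str | Path) -> PamModel:
    """Load a PAM serialized by :func:`write_pam`."""
    directory = Path(directory)
    sector_path = directory / "sectors.yaml"
    config = RunConfig(
        model_path=str(directory / "model.json"),
        enzyme_path=str(directory / "enzymes.tsv"),
        sector_path=str(sector_path) if sector_path.exists() else None,
    )
    pam, _ = read_pam_inputs(config)
    return pam
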