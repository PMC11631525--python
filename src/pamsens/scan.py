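"""Substrate-uptake sweeps, metabolic-phase detection and overflow onset.

Sweeping the upper bound of a substrate uptake reaction while
maximizing the objective (typically biomass) traces the transition
between metabolic regimes: while substrate is scarce the uptake bound
carries all the control (flux-limited), past a threshold the protein
budget starts to bind alongside it (co-limited, where byproduct
excretion — overflow metabolism — typically begins), and once protein
alone limits growth the proteome CSC reaches 1 and additional
substrate is useless (proteome-limited plateau)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleProblemError, PamError, ZeroObjectiveError
from .lp import solve
from .model import PamModel, set_flux_bounds
from .sensitivity import SensitivityReport, analyze

__all__ = ["SweepResult", "sweep_substrate", "detect_phases", "overflow_onset"]

#: Default coefficient threshold below which a constraint is "not limiting".
PHASE_TOL = 1e-3


@dataclass
class SweepResult:
    """Per-grid-point trajectories of one uptake sweep.

    ``feasible[k]`` is False where the solve failed or the objective was
    zero (no sensitivity normalization); such gaps carry NaN rows and
    are excluded from phase segments.
    """

    reaction_id: str
    grid: np.ndarray
    objective: np.ndarray
    fluxes: pd.DataFrame            # grid points x tracked reactions
    proteome_csc: np.ndarray
    alpha: np.ndarray
    feasible: np.ndarray
    reports: list[SensitivityReport | None]
    byproducts: tuple[str, ...] = ()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "bound": self.grid,
                "objective": self.objective,
                "proteome_csc": self.proteome_csc,
                "alpha": self.alpha,
                "feasible": self.feasible,
            }
        )
        for rid in self.fluxes.columns:
            df[f"flux[{rid}]"] = self.fluxes[rid].to_numpy()
        df.to_csv(path, index=False, float_format="%.12g")
        return path


def sweep_substrate(
    pam: PamModel,
    reaction_id: str,
    grid,
    byproducts: tuple[str, ...] = (),
    track: tuple[str, ...] = (),
) -> SweepResult:
    """Solve the PAM for each value of the swept upper bound.

    ``grid`` must be strictly increasing.  Tracked fluxes default to
    the objective, the swept reaction and any declared byproducts.
    Infeasible points (and points with zero objective, where
    sensitivities are undefined) are recorded as gaps rather than
    aborting; an error is raised only if *every* point fails.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if reaction_id not in pam.network.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    for rid in byproducts + tuple(track):
        if rid not in pam.network.reactions:
            raise KeyError(f"unknown reaction {rid!r}")

    tracked = [pam.network.objective, reaction_id, *byproducts, *track]
    tracked = list(dict.fromkeys(r for r in tracked if r is not None))

    n = grid.size
    objective = np.full(n, np.nan)
    pcsc = np.full(n, np.nan)
    alpha = np.full(n, np.nan)
    feasible = np.zeros(n, dtype=bool)
    flux_rows = np.full((n, len(tracked)), np.nan)
    reports: list[SensitivityReport | None] = [None] * n
    for k, g in enumerate(grid):
        model = set_flux_bounds(pam, reaction_id, ub=float(g))
        try:
            sol = solve(model)
            report = analyze(model, sol)
        except (InfeasibleProblemError, ZeroObjectiveError):
            continue
        except PamError:
            continue
        objective[k] = sol.objective
        pcsc[k] = report.proteome_csc
        alpha[k] = report.alpha
        feasible[k] = True
        flux_rows[k] = [sol.fluxes[r] for r in tracked]
        reports[k] = report
    if not feasible.any():
        raise InfeasibleProblemError(
            "every sweep point was infeasible or had zero objective"
        )
    return SweepResult(
        reaction_id=reaction_id,
        grid=grid,
        objective=objective,
        fluxes=pd.DataFrame(flux_rows, columns=tracked),
        proteome_csc=pcsc,
        alpha=alpha,
        feasible=feasible,
        reports=reports,
        byproducts=tuple(byproducts),
    )


def _label(report: SensitivityReport, tol: float) -> str:
    pcsc = report.proteome_csc
    max_flux_csc = float(report.flux_csc.abs().max()) if len(report.flux_csc) else 0.0
    if pcsc >= 1.0 - tol:
        return "proteome-limited"
    if pcsc > tol and max_flux_csc > tol:
        return "co-limited"
    if pcsc <= tol and max_flux_csc > tol:
        return "flux-limited"
    if pcsc > tol:
        return "co-limited"
    return "other"


def detect_phases(
    sweep: SweepResult, tol: float = PHASE_TOL
) -> list[dict]:
    """Label every feasible sweep point and merge contiguous segments.

    Labels: ``flux-limited`` (proteome CSC ~ 0 but some flux bound
    limiting), ``co-limited`` (proteome and a flux bound both
    limiting), ``proteome-limited`` (proteome CSC ~ 1).  Returns a list
    of ``{"phase", "start", "end", "indices"}`` dicts with grid-value
    boundaries, skipping infeasible gaps.
    """
    segments: list[dict] = []
    for k in range(sweep.grid.size):
        if not sweep.feasible[k]:
            continue
        label = _label(sweep.reports[k], tol)
        if segments and segments[-1]["phase"] == label \
                and segments[-1]["indices"][-1] == k - 1:
            segments[-1]["end"] = float(sweep.grid[k])
            segments[-1]["indices"].append(k)
        else:
            segments.append(
                {
                    "phase": label,
                    "start": float(sweep.grid[k]),
                    "end": float(sweep.grid[k]),
                    "indices": [k],
                }
            )
    return segments


def overflow_onset(
    sweep: SweepResult, byproduct_id: str, tol: float = 1e-6
) -> float | None:
    """Smallest swept bound at which the byproduct flux exceeds ``tol``
    (the predicted onset of overflow metabolism), or None if the
    byproduct is never excreted."""
    if byproduct_id not in sweep.fluxes.columns:
        raise KeyError(
            f"reaction {byproduct_id!r} was not recorded in the sweep"
        )
    flux = sweep.fluxes[byproduct_id].to_numpy()
    for k in range(sweep.grid.size):
        if sweep.feasible[k] and flux[k] > tol:
            return float(sweep.grid[k])
    return None


def write_phase_summary(
    sweep: SweepResult, segments: list[dict], path: str | Path
) -> Path:
    path = Path(path)
    payload = {
        "reaction": sweep.reaction_id,
        "segments": [
            {k: v for k, v in seg.items() if k != "indices"}
            for seg in segments
        ],
        "overflow_onset": {
            b: overflow_onset(sweep, b) for b in sweep.byproducts
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
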