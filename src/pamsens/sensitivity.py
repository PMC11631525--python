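"""Capacity and enzyme sensitivity coefficients from the dual solution.

All coefficients are normalized shadow prices (per-unit effects on the
optimal objective flux ``vz``):

* flux CSC_i   = (vmax_i mu_max_i - vmin_i mu_min_i) / vz
* enzyme CSC_j = (emax_j eps_max_j - emin_j eps_min_j) / vz
* proteome CSC = phi0 pi / vz
* ESC_j        = e_j xi_j / vz  (>= 0 by construction)

The capacity coefficients sum to exactly 1 at any optimum (a direct
consequence of strong duality), and two connectivity identities link
the ESCs to the capacity coefficients through the active-enzyme
fraction ``alpha = (sum_j m_j e_j) / phi0`` — the mass-weighted share
of the protein budget occupied by enzymes at the optimum.  These three
residuals are computed for every report and serve as built-in numerical
self-checks.

Note on alpha: the dimensionally consistent mass-weighted form is used
(molar concentrations carry mmol/gCDW while the budget is in mg/gCDW),
matching the proteome-row identity ``w.v + m.e = phi0`` at an active
budget.  Inert proteins count toward alpha (they occupy the budget) but
are excluded from ESC rankings by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NonOptimalSolutionError, ZeroObjectiveError
from .lp import PrimalDualSolution, solve
from .model import PamModel, compute_phi0

__all__ = [
    "SensitivityReport",
    "compute_csc",
    "compute_esc",
    "summation_report",
    "top_sensitivities",
    "analyze",
    "write_report",
]

#: Coefficients smaller than this in magnitude are reported as exact 0.
CLAMP_TOL = 1e-9


def _clamp(s: pd.Series) -> pd.Series:
    out = s.copy()
    out[out.abs() < CLAMP_TOL] = 0.0
    return out


@dataclass
class SensitivityReport:
    """All sensitivity coefficients of one optimal PAM solution."""

    flux_csc: pd.Series
    enzyme_csc: pd.Series
    proteome_csc: float
    esc: pd.Series
    alpha: float
    objective: float
    residual_capacity: float = np.nan       # |sum CSC - 1|
    residual_connectivity_flux: float = np.nan
    residual_connectivity_enzyme: float = np.nan
    degenerate: bool = False
    inert_ids: list[str] = field(default_factory=list)
    raw: dict[str, pd.Series] = field(default_factory=dict, repr=False)


def _require_optimal(sol: PrimalDualSolution) -> float:
    if sol.status != "optimal":
        raise NonOptimalSolutionError(
            f"sensitivities need an optimal solution, got {sol.status!r}"
        )
    if sol.objective <= CLAMP_TOL:
        raise ZeroObjectiveError(
            "objective value is zero; sensitivity normalization undefined"
        )
    return sol.objective


def compute_csc(
    sol: PrimalDualSolution, pam: PamModel
) -> tuple[pd.Series, pd.Series, float]:
    """Flux, enzyme and proteome capacity sensitivity coefficients.

    Terms belonging to absent (unbounded) bounds are identically zero;
    a model without sectors has proteome CSC 0.
    """
    vz = _require_optimal(sol)
    net = pam.network
    ub = pd.Series({r: net.ub(r) for r in net.reactions})
    lb = pd.Series({r: net.lb(r) for r in net.reactions})
    up = (ub * sol.mu_max).where(np.isfinite(ub), 0.0)
    flux_csc = (up - lb * sol.mu_min) / vz

    emax = pd.Series({e.enzyme_id: e.emax for e in pam.enzymes}, dtype=float)
    emin = pd.Series({e.enzyme_id: e.emin for e in pam.enzymes}, dtype=float)
    if len(pam.enzymes):
        eup = (emax * sol.eps_max).where(np.isfinite(emax), 0.0)
        enzyme_csc = (eup - emin * sol.eps_min) / vz
    else:
        enzyme_csc = pd.Series(dtype=float)

    proteome_csc = 0.0
    if pam.sectors is not None:
        proteome_csc = compute_phi0(pam.sectors) * sol.pi_value / vz
    return flux_csc, enzyme_csc, proteome_csc


def compute_esc(
    sol: PrimalDualSolution, pam: PamModel
) -> tuple[pd.Series, float]:
    """Enzyme sensitivity coefficients and the active-enzyme fraction.

    ESC_j = e_j xi_j / vz for every catalytic enzyme (non-negative by
    construction).  alpha is the mass-weighted enzyme share of the
    protein budget, including inert proteins; it is 0 for models
    without sectors or enzymes.
    """
    vz = _require_optimal(sol)
    cat_ids = [e.enzyme_id for e in pam.catalytic_enzymes]
    esc = (sol.enzymes.loc[cat_ids] * sol.xi.loc[cat_ids]) / vz \
        if cat_ids else pd.Series(dtype=float)
    alpha = 0.0
    if pam.sectors is not None and pam.enzymes:
        mass = pd.Series({e.enzyme_id: e.molar_mass for e in pam.enzymes})
        alpha = float((mass * sol.enzymes).sum() / compute_phi0(pam.sectors))
    return esc, alpha


def summation_report(report: SensitivityReport) -> tuple[float, float, float]:
    """Residuals of the three theorem identities, recomputed from the
    report's stored coefficients.

    Returns ``(|sum CSC - 1|, |sum ESC + sum flux CSC + (1 - alpha)
    proteome CSC - 1|, |-sum ESC + sum enzyme CSC + alpha proteome
    CSC|)``.  Nonzero residuals beyond solver tolerance indicate a
    corrupted report or a numerically unreliable solve.
    """
    csc_sum = (
        float(report.flux_csc.sum())
        + float(report.enzyme_csc.sum())
        + report.proteome_csc
    )
    r_cap = abs(csc_sum - 1.0)
    r_flux = abs(
        float(report.esc.sum())
        + float(report.flux_csc.sum())
        + (1.0 - report.alpha) * report.proteome_csc
        - 1.0
    )
    r_enz = abs(
        -float(report.esc.sum())
        + float(report.enzyme_csc.sum())
        + report.alpha * report.proteome_csc
    )
    return r_cap, r_flux, r_enz


def analyze(
    pam: PamModel,
    sol: PrimalDualSolution | None = None,
    backend: str | None = None,
) -> SensitivityReport:
    """Solve (if needed) and compute the full sensitivity report."""
    if sol is None:
        sol = solve(pam, **({"backend": backend} if backend else {}))
    flux_csc, enzyme_csc, proteome_csc = compute_csc(sol, pam)
    esc, alpha = compute_esc(sol, pam)
    report = SensitivityReport(
        flux_csc=_clamp(flux_csc),
        enzyme_csc=_clamp(enzyme_csc),
        proteome_csc=0.0 if abs(proteome_csc) < CLAMP_TOL else proteome_csc,
        esc=_clamp(esc),
        alpha=alpha,
        objective=sol.objective,
        degenerate=sol.degenerate,
        inert_ids=[e.enzyme_id for e in pam.enzymes if not e.catalytic],
        raw={"flux_csc": flux_csc, "enzyme_csc": enzyme_csc, "esc": esc},
    )
    (
        report.residual_capacity,
        report.residual_connectivity_flux,
        report.residual_connectivity_enzyme,
    ) = summation_report(report)
    return report


def top_sensitivities(
    report: SensitivityReport,
    threshold: float = 0.05,
    include_inert: bool = False,
) -> pd.DataFrame:
    """Coefficients with |value| > threshold, ranked by magnitude.

    Ties in magnitude are broken by (kind, id) lexicographic order.
    Inert proteins never carry an ESC; they can only appear through an
    enzyme CSC row and are hidden unless ``include_inert`` is set.
    """
    rows = []
    for kind, series in (
        ("flux_csc", report.flux_csc),
        ("enzyme_csc", report.enzyme_csc),
        ("esc", report.esc),
    ):
        for ident, val in series.items():
            if kind == "enzyme_csc" and not include_inert \
                    and ident in report.inert_ids:
                continue
            rows.append((kind, ident, float(val)))
    rows.append(("proteome_csc", "proteome", report.proteome_csc))
    df = pd.DataFrame(rows, columns=["kind", "id", "coefficient"])
    df = df[df["coefficient"].abs() > threshold]
    df = df.sort_values(
        by=["coefficient", "kind", "id"],
        key=lambda c: -c.abs() if c.name == "coefficient" else c,
        ascending=True,
    ).reset_index(drop=True)
    return df


def write_report(report: SensitivityReport, directory: str | Path) -> list[Path]:
    """Write the sensitivities CSV and a JSON diagnostics block.

    The CSV has columns kind, id, coefficient, normalized_by and is
    sorted by (kind, id); floats are written at 12 significant digits so
    repeated runs are byte-identical.
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [("proteome_csc", "proteome", report.proteome_csc)]
    for kind, series in (
        ("flux_csc", report.flux_csc),
        ("enzyme_csc", report.enzyme_csc),
        ("esc", report.esc),
    ):
        rows.extend((kind, i, float(v)) for i, v in series.items())
    df = pd.DataFrame(rows, columns=["kind", "id", "coefficient"])
    df["normalized_by"] = report.objective
    df = df.sort_values(["kind", "id"]).reset_index(drop=True)
    csv_path = directory / "sensitivities.csv"
    df.to_csv(csv_path, index=False, float_format="%.12g")
    diag = {
        "residual_capacity": report.residual_capacity,
        "residual_connectivity_flux": report.residual_connectivity_flux,
        "residual_connectivity_enzyme": report.residual_connectivity_enzyme,
        "alpha": report.alpha,
        "objective": report.objective,
        "degenerate": report.degenerate,
        "package_version": __version__,
    }
    json_path = directory / "diagnostics.json"
    json_path.write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")
    return [csv_path, json_path]
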