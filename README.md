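# pamsens

Exact sensitivity analysis for **protein allocation models** (PAMs).

Constraint-based metabolic models predict fluxes from stoichiometry
alone; PAMs additionally charge each catalyzed flux for the enzyme that
carries it and force all enzymes, together with coarse-grained
translational and unused-protein sectors, to fit inside a finite
proteome budget. This reproduces phenomena plain flux balance analysis
misses — most prominently overflow metabolism, where cells excrete
fermentation byproducts under protein (not substrate) limitation. What
such a model does *not* tell you by itself is **why** a predicted
phenotype looks the way it does: which flux bound, enzyme or protein
pool actually limits growth.

`pamsens` answers that question from a *single* linear-program solve.
Because a PAM is an LP, every constraint has a shadow price, and
normalizing the shadow prices by the optimal objective flux `v_z`
yields a complete, exact sensitivity decomposition:

| coefficient | definition | meaning |
|---|---|---|
| flux CSC | `(v_max,i · μ_max,i − v_min,i · μ_min,i) / v_z` | control exerted by a flux bound |
| enzyme CSC | `(e_max,j · ε_max,j − e_min,j · ε_min,j) / v_z` | control exerted by an enzyme concentration bound |
| proteome CSC | `φ₀ · π / v_z` | control exerted by the total protein budget |
| ESC | `e_j · ξ_j / v_z` | control exerted by one enzyme's concentration (≥ 0) |

with `μ, ε, π, ξ` the duals of the flux bounds, enzyme bounds, proteome
budget and enzyme-coupling constraints, and `φ₀` the protein budget.
Strong LP duality makes the capacity coefficients sum to exactly 1, and
two connectivity identities tie the ESCs to the capacity coefficients
through the active-enzyme fraction `α = (Σ m_j e_j)/φ₀`:

```
Σ flux CSC + Σ enzyme CSC + proteome CSC                = 1
Σ ESC + Σ flux CSC + (1 − α) · proteome CSC             = 1
−Σ ESC + Σ enzyme CSC + α · proteome CSC                = 0
```

These identities are recomputed for every report and double as built-in
numerical self-checks. Finite-difference flux control coefficients
(forward and central kcat perturbations) are provided as an independent
baseline; they need `n_enz + 1` or `2·n_enz + 1` LP solves to
approximate what the dual solution gives exactly in one.

The package is aimed at systems-biology practitioners who build or use
enzyme-constrained models (PAM / GECKO style) and want to interrogate
what limits a simulated phenotype, scan overflow onset, or rank
enzymes for engineering targets.

## Worked example

`chain3` is a three-reaction chain (`R1: → A ≤ 10`, `R2: A → B`
catalyzed by enzyme E1 with kcat 2 h⁻¹ and mass 1 g/mol, `R3: B →`
maximized) under a protein budget φ₀ = 1 mg/gCDW. The budget caps
e₁ ≤ 1 mmol/gCDW, the coupling caps v₂ ≤ kcat·e₁ = 2, so the optimum is
2 with the proteome holding all the control:

```console
$ pamsens fixtures chain3 -o chain3
$ pamsens solve chain3
status=optimal objective=2 proteome_dual=2 degenerate=False
$ pamsens sens chain3 -o out
        kind       id  coefficient
         esc       E1          1.0
proteome_csc proteome          1.0
alpha=1 objective=2
```

Relaxing the budget by 1 mg/gCDW would buy 2 extra flux units
(`proteome_dual=2`); proteome CSC = φ₀·π/v_z = 1 says the protein pool
is the *only* limiting capacity, and ESC(E1) = 1 says all of that
control is channelled through enzyme E1. Tightening the uptake instead
(`vmax(R1) = 1`) moves the full control to the flux bound: flux
CSC(R1) = 1 and every ESC drops to 0.

The same machinery drives uptake sweeps with phase classification:

```console
$ pamsens fixtures toy -o toy
$ pamsens sweep toy --reaction R1 --from 0.2 --to 10 --steps 50 --byproduct R6 -o sweep
flux-limited: bound in [0.2, 1.8]
co-limited: bound in [2, 3.2]
proteome-limited: bound in [3.4, 10]
```

The bundled toy model (a protein-efficient low-yield fermentation route
versus a protein-hungry high-yield respiration route) transitions from
substrate-limited respiration through a co-limited overflow regime —
byproduct excretion starts here — to a fully proteome-limited plateau
where the proteome CSC reaches 1.

As a library:

```python
import pamsens as ps

pam = ps.chain3()                 # or ps.build_pam(network, enzymes, sectors)
report = ps.analyze(pam)          # one LP solve
report.proteome_csc, dict(report.esc), report.alpha
# (1.0, {'E1': 1.0}, 1.0)
```

## Input formats

* **Networks**: SBML Level 3 + FBC (via COBRApy), or a JSON dialect:
  `{"metabolites": [...], "reactions": [{"id", "metabolites": {met:
  coef}, "lower_bound", "upper_bound"}], "objective", "substrate",
  "biomass"}` (`upper_bound: null` = unbounded). Reversible reactions
  are split into irreversible pairs on assembly.
* **Enzymes**: TSV with columns `enzyme_id, reaction_id, kcat_per_h,
  molar_mass_g_per_mol, emin, emax`; one row per catalyzed reaction,
  `--kcat-unit 1/s` and `--mass-unit kDa` convert at the boundary.
* **Sectors**: YAML/JSON with `phi_total, phi_T0, w_T, phi_UE0, w_UE,
  biomass_rxn, substrate_rxn` (all φ in mg/gCDW).

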