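# Methods

## Model formulation

A protein allocation model (PAM) is the linear program

```
max  v_z = c·v
s.t. S v = 0                                  (mass balances)
     Σ_i v_i / kcat_{i,j} − e_j ≤ 0           (coupling, per enzyme j)
     w·v + Σ_j m_j e_j ≤ φ₀                   (proteome budget)
     v_min ≤ v ≤ v_max,  e_min ≤ e ≤ e_max,  v, e ≥ 0
```

over non-negative irreversible fluxes `v` (mmol/gCDW/h) and enzyme
concentrations `e` (mmol/gCDW). Reversible reactions are split into
forward/reverse pairs at assembly; one enzyme may cover both split
directions inside a single coupling row. The coupling matrix is
diagonal by construction — exactly one enzyme per catalyzed reaction —
and isozymes are rejected with an explicit error rather than silently
merged, because the sensitivity decomposition below assumes the
diagonal structure.

The proteome budget aggregates three protein sectors. Metabolic
enzymes enter through their mass `m_j e_j` (g/mol × mmol/gCDW =
mg/gCDW). The translational sector grows linearly with the growth rate
(slope `w_T` on the biomass flux) and the unused-enzyme sector shrinks
linearly with substrate uptake (slope `w_UE`, entering `w` with a
negative sign); their zero-growth intercepts are folded into the
condition-independent budget `φ₀ = φ_total − φ_T,0 − φ_UE,0`. The
unused sector is a pure linear term — it is *not* clipped at zero for
large uptake rates, and users parameterizing sectors should keep
`φ_UE,0 ≥ w_UE · v_s` over their operating range (the random generator
enforces the analogous coherence condition, see below).

Units are fixed at the API boundary (kcat 1/h, mass g/mol, φ mg/gCDW;
readers convert 1/s and kDa on request) so no hidden factors appear in
the proteome row. Absent bounds are represented as `inf`, never as a
big-M number, which makes their dual variables identically zero rather
than small and noisy.

## Sensitivity coefficients

All coefficients are shadow prices normalized by the optimal objective
`v̄_z > 0` (a zero optimum raises a dedicated error, as the
normalization is undefined there):

* flux CSC_i = `(v_max,i μ̄_max,i − v_min,i μ̄_min,i) / v̄_z` — the
  bound-weighted form; under complementary slackness it equals the
  flux-weighted form `(v̄_i/v̄_z)·Δμ̄_i`, but the bound-weighted form
  stays exact when a flux is at a bound within solver tolerance only.
  A binding *lower* bound (e.g. an ATP-maintenance requirement)
  produces a negative flux CSC: relaxing the requirement would raise
  the optimum.
* enzyme CSC_j analogously from the enzyme bounds, proteome CSC =
  `φ₀ π̄ / v̄_z`, and ESC_j = `ē_j ξ̄_j / v̄_z ≥ 0`.

Strong duality makes all capacity CSCs sum to exactly 1; multiplying
the two dual-feasibility blocks by the primal optimum and applying
complementary slackness yields two connectivity identities linking
ESCs and CSCs through the **active-enzyme fraction**

```
α = (Σ_j m_j ē_j) / φ₀ .
```

α is computed *mass-weighted*. An unweighted sum of molar enzyme
concentrations over a mass-unit budget is dimensionally inconsistent
and breaks the connectivity identities; the mass-weighted form is
exactly the quantity that the proteome-row identity `w·v̄ + m·ē = φ₀`
trades against the sector terms, and with it both identities hold to
solver precision on every instance. Inert proteins count toward α
(they occupy the budget) but carry no ESC and are hidden from rankings
by default. Note that α ≤ 1 is guaranteed only when the net sector
term `w·v̄` is non-negative at the optimum; a dominating unused-sector
relief would push the enzyme mass above the nominal budget. The
identities hold for any α, but such parameterizations are treated as
incoherent by the fixture generator.

The three identity residuals are recomputed for every report from the
stored coefficients, so a corrupted coefficient is flagged by a
non-zero residual; they also serve as the package-level acceptance
quantities.

## LP solution and duals

One solve suffices: the sensitivity coefficients are read from the
solver's dual values, not from re-solving an explicit dual program.
The explicit dual *is* constructed (`build_dual`) — with variables for
finite bounds only — but purely as a verification oracle: its optimum
must equal the primal optimum to 1e-6 relative.

Backends implement a small contract (sparse rows, bounds, maximize)
and return duals normalized to one sign convention: all inequality
duals are sensitivities of the maximal objective to the right-hand
side, hence non-negative. The default backend is HiGHS dual simplex
via SciPy, which returns vertex solutions with exact complementary
slackness; GLPK (via optlang) is wired in as an independent
cross-check. Feasibility/optimality tolerances of 1e-9 are requested
from the backend; identity checks assert at 1e-6; coefficients below
1e-9 in magnitude are clamped to exact 0 in reports (raw values are
retained on the report object).

Shadow prices are non-unique at degenerate optima. A heuristic
diagnostic flags degeneracy (variables at a bound with zero reduced
cost, or more active constraints than variables) and the flag is
propagated into every report; coefficients at a flagged optimum are
one valid subgradient choice, and backend-agreement tests are asserted
only on unflagged instances.

## Finite-difference baseline

Flux control coefficients are approximated by relative differences of
the re-optimized objective after multiplying all kcats of one enzyme
by `1 ± Δ` (default Δ = 1e-3): forward (first-order, `n_enz + 1`
solves) and central (second-order, `2·n_enz + 1` solves). The
denominator is `v_z` at the unperturbed optimum; midpoint
normalization would differ only at second order. At non-degenerate
optima the central scheme reproduces the exact ESC; at kinks
(vertex-changing perturbations) one-sided derivatives disagree, and
entries with `|forward − central| > 10Δ` are flagged rather than
asserted. A per-process solve counter substantiates the solve-count
economy claim without wall-clock timing, which is hardware-dependent
and out of scope.

## Synthetic fixtures

**chain3** is the worked micro-example: uptake → catalyzed conversion
→ sink, φ₀ = 1, kcat = 2, mass = 1. Its LP reduces to two effective
variables and was solved by hand together with its dual before
implementation; the suite asserts the entire closed-form
primal/dual/coefficient set at 1e-9.

**toy model.** Seven reactions: substrate uptake (R1, enzyme E1),
glycolysis (R2, E2, +1 ATP), fermentation (R3, E3, +1 ATP, secreted
byproduct via R6), two-step respiration (R4/R5, E4/E5, +4 ATP), and a
biomass reaction (R7) consuming one precursor and five ATP. Default
parameters make fermentation the protein-cheap but low-yield ATP route
(cost m/kcat per ATP: 1 vs 5 mg·h/gCDW) — the structural premise is
validated at construction and inverting it is an error. Sectors use
φ_total = 600 mg/gCDW (60% of dry weight) with symmetric intercepts
(φ₀ = 50), a translational slope of 10 and an unused-enzyme slope of 1.
Numeric values are repo-chosen to produce the canonical three-phase
sweep (flux-limited → co-limited → proteome-limited with overflow
starting at the co-limited boundary); the sweep is validated
qualitatively — phase order, overflow/proteome-CSC coincidence,
plateau — not against any external numeric trajectory, and the phase
boundaries themselves are not asserted.

**random generator.** Chain-with-branches motifs (one uptake, one
objective sink, forward branches with yields in [0.5, 1.5]) guarantee
mass balance, feasibility at zero flux and boundedness under the
finite uptake bound, keeping the rejection rate near zero — fully
random stoichiometry would mostly be infeasible or unbounded. kcats
are log-uniform in [1, 1e4] 1/h and masses in [1e3, 1e6] g/mol
(spanning realistic enzyme ranges); φ₀ is scaled to the enzyme cost of
carrying a random fraction (0.25–1.5) of the uptake bound so instances
land on both sides of the flux/proteome-limited boundary; occasional
finite flux caps, enzyme caps and sector slopes exercise every dual
term. Draws with zero optimum, infeasible status, or an optimum whose
enzyme mass exceeds the nominal budget (α > 1, an incoherent sector
draw as discussed above) are rejected and deterministically resampled.
Everything is reproducible from a single integer seed, down to
byte-identical serialization.

What the generator does *not* emulate: realistic genome-scale
topology (cofactor coupling, compartments), isozymes and enzyme
complexes, calibrated sector parameters from proteomics, or
thermodynamic constraints. Passing the property suite therefore
demonstrates the mathematical correctness of the sensitivity
machinery on the model class, not predictive accuracy for any
organism; applying the package to a calibrated organism-scale PAM
requires externally estimated kcats and sector parameters.

## Validation battery and problem sizes

The identity and duality properties are asserted on 100 random PAMs
(10–40 reactions, 3–15 enzymes — comfortably desk-scale, solving in
milliseconds each) plus both named fixtures; the finite-difference
cross-check uses a smaller non-degenerate subset with Δ = 1e-4. The
acceptance script regenerates the same battery from a base seed and
reports worst-case identity values.

## Known limitations

* Sensitivities are normalized by the objective flux only; no
  second-order effects, no sensitivities of non-objective fluxes.
* At degenerate optima coefficients are one valid choice among several
  (flagged, not resolved; no lexicographic or interior-point
  tie-break is attempted).
* The inert-protein drain couples precursor consumption to the fixed
  protein concentration, not to growth; the default edit applies the
  proteome burden only, which already captures the qualitative
  growth-vs-expression trade-off.
* No MILP, QP, or parsimonious variants; knockouts are plain `[0, 0]`
  bound edits.
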