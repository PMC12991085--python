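# Methods

`hcnfep` is the post-simulation half of an absolute binding free-energy
study of cAMP at the cyclic-nucleotide-binding domain (CNBD) of HCN1–4:
it takes per-window alchemical energy differences, per-residue
pair-interaction energies, and trajectories, and turns them into binding
free energies, per-residue interaction contributions, and replicate
quality-control verdicts. The molecular-dynamics engine itself is out of
scope; a synthetic-data module with exact ground truth stands in for it
so every computation is testable at desk scale.

## Free-energy estimation

The alchemical protocol is a 20-window annihilation (Δλ = 0.05), with
electrostatics fully decoupled by λ = 0.5 through a soft-core treatment,
10 ps of alchemical equilibration plus 115 ps of sampling per window,
and double-wide sampling giving forward (annihilation) and backward
(re-coupling) ΔU samples per window. All energies are kcal/mol; the
thermal energy defaults to RT = 0.616 kcal/mol (310 K) and is
configurable everywhere.

Per window, the free-energy difference is the root of Bennett's
self-consistency equation

    Σ_F f(M + (W_F − ΔG)/RT) = Σ_R f(−M + (W_R + ΔG)/RT),
    f(x) = 1/(1+e^x),  M = ln(n_F/n_R),

whose left-minus-right residual is strictly increasing in ΔG, so the
root is unique. It is located with an expanding bracket followed by
Brent's method (default tolerance 1e-8 kcal/mol, 500 iterations; a
non-convergent solve raises with the last bracket). Brent on a monotone
bracketed residual is at least as robust as bisection-plus-Newton and
needs no derivative. The standard error per window is Bennett's
asymptotic variance,

    Var(ΔG)/RT² = [⟨f²⟩_F/⟨f⟩_F² − 1]/n_F + [⟨f²⟩_R/⟨f⟩_R² − 1]/n_R,

evaluated at the solution. Totals sum the per-window estimates; windows
are treated as independent, so the total variance is the sum of the
per-window variances. No autocorrelation correction is applied — at 25
pair-interaction samples and ~10² ΔU samples per window, time-series
variance estimators are less reliable than the independence assumption
they would replace — and reports say so.

The one-sided Zwanzig (exponential-averaging) estimator
−RT·ln⟨e^(−ΔU/RT)⟩ is kept as a cross-check; both it and all other
exponential averages in the package are computed through log-sum-exp and
are stable to |ΔU|/RT of several hundred.

A caution learned while testing: the folklore claim that the BAR
estimate is bracketed by the forward and backward exponential estimates
in every window is false at finite sample size. Bennett's ΔG(C) curve,
whose limits C → ∓∞ are the two exponential estimates and whose
self-consistent interior point is BAR, is not monotone in C; on
well-overlapped Gaussian work (σ/RT ≈ 1.3, 1000 samples/leg) roughly
40% of windows place BAR slightly outside the interval, by about the
estimator noise. What does hold, and what the test suite asserts, is the
statistical statement: BAR's mean absolute error is no larger than
either one-sided estimate's.

Sign convention: ΔG is reported for the annihilation direction, so the
protein-leg and solvation-leg values are large positive numbers, and the
binding free energy is ΔG_solv − ΔG_protein (more negative = tighter
binding). No standard-state or restraint-release corrections are added;
the reported quantity is the raw difference of the two legs.

## Isoform aggregation

Per isoform, pose-level protein-leg values are averaged and subtracted
from the solvation-leg value ΔG_solv(cAMP) = 118.63 ± 0.39 kcal/mol.
The reported uncertainty is the sample standard deviation (ddof = 1)
across poses combined in quadrature with the solvation-leg standard
error. This is a deliberate, transparent convention: no simple rule we
tested reproduces the published final-column errors from the published
per-pose errors, so the package documents its own. Ranking sorts by
binding ΔG ascending and flags any pair whose difference is smaller
than the quadrature combination of their errors as "comparable" —
affinities the error bars cannot separate.

Homologous positions across the four differently-numbered CNBDs are
referenced by "residue offset" — sequence distance from the first
considered binding-site residue. The 27-row offset → (HCN1, HCN2, HCN3,
HCN4) residue map ships as packaged CSV data.

## Per-residue decomposition

The alchemical transformation is treated as a two-state equilibrium and
each residue's electrostatic and van der Waals interaction energies with
the transitioning ligand define a per-window equilibrium constant:

    K_i = ⟨exp(−(U_elec·0.1 + U_vdw·0.05)/RT)⟩   i = 1…10
    K_i = ⟨exp(−(U_vdw·0.05)/RT)⟩                i = 11…20
    ΔG  = −RT Σ_{i=1}^{20} ln K_i .

The scale factors 0.1 (electrostatic, first half only — electrostatics
are off past λ = 0.5) and 0.05 (van der Waals, all windows) are fixed
constants of the method, not per-window λ values; an alternative reading
with window-dependent λ weights exists, but the fixed-constant form is
the one implemented. The quantity is an approximate ranking tool for
residue importance, not a rigorous free-energy partition. NaN or
infinite energy samples are rejected outright rather than skipped:
silently dropping samples would bias the exponential average.

## Trajectory QC metrics

Five per-frame metrics feed replicate selection:

* **Ligand COM displacement** and **ligand all-atom RMSD**, both after
  Kabsch superposition of the frame onto the reference frame using the
  β-sheet Cα set (the β-jelly-roll core), so whole-domain drift is not
  counted as ligand motion. The ligand is never re-fitted. COM
  displacement without alignment is available behind a flag. Masses come
  from the topology when present, else unit masses.
* **Lid distance** — the Cα–Cα distance between a β-jelly-roll loop
  residue and a C/D-helix-turn residue (S527/I594, N596/I663, A480/I547,
  N647/I714 for HCN1–4), a proxy for C-helix closure over the bound
  nucleotide. Frame-internal; no alignment.
* **Helix B/C angle** — each helix's long axis is the smallest-moment
  eigenvector of the inertia tensor of its Cα atoms (unit masses),
  oriented first→last residue; the angle is folded to [0°, 90°] via the
  absolute dot product (a signed variant exists behind a flag). A
  degenerate inertia tensor (smallest moment not unique to 1e-9
  relative) is an error naming the frame.
* **Hydrogen-bond geometry** — a bond is present when the
  donor–acceptor distance is ≤ 3.0 Å and the D–H–A angle deviates from
  linearity by ≤ 20°; occupancy is the fraction of frames present. The
  angle cutoff is deviation-from-180°, matching the semantics of the
  common trajectory-viewer H-bond tools.

Kabsch superposition enforces a proper rotation (determinant +1 via sign
correction of the smallest singular direction) and rejects fewer than
three atoms or rank-deficient (collinear) configurations.

## Replicate selection

A replicate passes when, over the frames after `production_start`, at
least `fraction_required` (default 0.9) of frames keep each enabled
metric within bound: COM displacement < 2 Å and ligand RMSD < 3 Å
(absolute bounds), lid distance and helix angle within a bounded
excursion of their own medians (defaults 2 Å and 15°), and H-bond
occupancy above a minimum (default 0.5). The absolute COM/RMSD bounds
are established selection thresholds; the lid/helix stability bounds and
the 0.9 frame fraction are this package's operationalisation of what is
otherwise a visual judgement call, are configurable, and are flagged as
package defaults in reports. Passing replicates are ranked by
mean(COM)/COM-bound + mean(RMSD)/RMSD-bound (lower is better), ties
broken by replicate id, so reports are deterministic and byte-identical
for identical inputs.

## Synthetic data

* **Gaussian work**: forward work W ~ N(μ, σ²), backward work
  W' ~ N(−μ + σ²/RT, σ²). This pair satisfies the Crooks fluctuation
  relation exactly in distribution with per-window ground truth
  ΔG = μ − σ²/(2RT); the test suite confirms the relation by histogram
  regression (slope 1/RT). Default study conditions where nothing else
  dictates them: μ = 1.0, σ = 0.8 kcal/mol per window (σ/RT ≈ 1.3,
  healthy window overlap).
* **Pair-energy streams**: Gaussian per-window samples; zero variance
  yields a closed-form decomposition ΔG stored with the series.
* **Toy trajectories**: a rigid β-sheet Cα scaffold, two ideal-helix
  Cα rods (2.3 Å radius, 1.5 Å rise, 100° twist, 18 residues) at a
  scheduled relative tilt about an axis exactly perpendicular to the
  template's inertia axis (so the scheduled tilt is the exact expected
  angle), a rigid 5-atom ligand following a static/linear-drift/random-
  walk model, a lid Cα pair following a distance schedule, and a D–H–A
  triplet following distance/deviation schedules. Because the scaffold
  is rigid, superposition is the identity and every scheduled series is
  the exact expected metric value.

The generators emulate the statistical structure the estimators consume
— work distributions, energy streams, geometric schedules — and nothing
else: no force-field energetics, no water, no correlated protein
dynamics, no clash avoidance. Tests passing on them demonstrate that the
estimators and metrics are computed correctly, not that real CNBD
trajectories would pass QC or that published per-residue energies are
reproduced (those require the original trajectories).

## Problem sizes and numerical choices

Default analysis sizes follow the protocol: 20 windows, 25
pair-interaction samples per window (500 per double-wide process).
Synthetic validation sizes are chosen for tight statistics at desk
scale: 50 seeds × 20 windows × 1000 samples/leg for estimator recovery;
10³ random streams for the Jensen bound; 100 randomized fixtures for QC
monotonicity; bundles of 2 isoforms × 2–3 replicates/poses for
end-to-end runs. Tolerances: BAR root 1e-8 kcal/mol; closed-form
decomposition checks 1e-9; Kabsch rigid-motion residuals 1e-10 Å (1e-6 Å
against the brute-force oracle); helix tilt recovery 0.5°. Angles pass
through arccos, which halves working precision near 0° and 90°;
equality-style angle assertions therefore use ~1e-5° rather than machine
epsilon.

## Known limitations

* Window-independence in the error model ignores any correlation
  introduced by a shared seed conformation across windows.
* The per-residue decomposition inherits the printed fixed scale factors;
  it is a ranking heuristic and its values are not additive components
  of the total ΔG.
* QC stability bounds for lid distance and helix angle have no published
  numeric reference; results depending on them should report the bounds
  used.
* The binding free energies carry no standard-state correction, so they
  are comparable between isoforms but not directly to experimental
  dissociation constants.
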