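# Methods

## Model and assumptions

The model is a well-mixed (non-spatial) ODE description of acute liver
inflammation. A pro-inflammatory mediator pool *c* recruits neutrophils and
macrophages; neutrophils apoptose (rate ν, promoted by the anti-inflammatory
mediator *g* and suppressed by *c*) and their necrosis (γ_a) feeds back on
*c*; macrophages clear apoptotic material (φ, with the restorative phenotype
φ₂-fold more efficient) and switch between a pro-inflammatory phenotype
(secreting *c* at rate k_m) and a restorative one (secreting *g* at k_g) at
rates k_m1/k_m2; hepatocytes are damaged by *c* (ν₂), cleared by macrophages
(χ_h φ) and lyse (γ_h), with dead tissue replaced by hepatocytes or by
extracellular matrix depending on stellate-cell activation (r₁ c forward, r₂
(1+g) back). Saturation of the neutrophil feedbacks is Hill-type (quadratic);
the macrophage feedback k_m is unsaturated and must be small because the
macrophage pool grows to O(10²) in chronic states.

All computations use the dimensionless form, which is the single
computational core; the dimensional parameterization exists purely as a
front-end (`nondimensionalize` maps dimensional rates onto the 23
dimensionless groups and returns the variable scalings, and `rescale_for_ka`
expresses variation of the dimensional necrosis-release magnitude k_a, which
the scaling eliminates, as the corresponding joint move of ten dimensionless
groups). Two exact conservation laws (tissue h + h_a + e and stellate s + s_a
totals) are built into the equations; the reduced nine-variable system with
e and s_a eliminated is used for all equilibrium and eigenvalue work. State
ordering is fixed as (n, a, m_i, m_r, c, g, h, h_a, e, s, s_a) everywhere.

One wrinkle is documented rather than resolved: descriptions of the k_a
rescaling sometimes group γ_m2 with the inversely-scaling saturation
constants, but its defining group is proportional to k_a; `rescale_for_ka`
follows the group definition and emits a one-time warning.

## Parameters

Baseline values (the `default_parameters()` set, also shipped as
`data/table3.json`): ν = 0.1, φ = 0.1, φ₂ = 10, γ_a = 1, γ_m = 0.01,
γ_m2 = 0.01, γ_g = 1, γ_e = 0.1, γ_h = 0.1, k_n = 0.01, k_g = 0.1, k_h = 0.1,
k_m = 10⁻⁴, k_m1 = 30, k_m2 = 0.3, β_a = 0.1, β_n = 0.1, β_c = 0.12,
β_g = 0.01, ν₂ = 0.01, χ_h = 1, r₁ = r₂ = 1. All are dimensionless; rates are
per unit of the mediator-decay timescale. The slowest rate, macrophage loss
γ_m = 0.01, sets the ~100-unit relaxation scale that dictates simulation
horizons.

## Numerics

**Vector field and Jacobians.** The eleven equations are written once over
generic arithmetic; the same expressions are evaluated numerically, reduced
through the conservation laws, and differentiated symbolically (sympy) to
give exact 9×9 and 11×11 Jacobians (lambdified once per process). A
central-difference Jacobian (step 10⁻⁶·max(1, |y|)) exists solely as an
independent cross-check; the two agree to better than 10⁻⁶ in tests.

**Integration.** `solve_ivp` with LSODA, the analytic Jacobian, rtol 10⁻⁹ and
atol 10⁻¹¹ by default — tight, because outcome classification adjacent to
bifurcation boundaries is tolerance-sensitive. Default horizon 2000 time
units, doubled (to at most 16000) when the outcome is undetermined.
Conservation drift stays below 10⁻⁸ and is recorded on every trajectory.

**Outcome classification.** On the final 25 % of samples: *resolved* if every
pro-inflammatory component (n, a, m_i, c, h_a) stays below 10⁻⁵; *oscillatory*
if the peak-to-peak range of c exceeds 10⁻⁴ with at least three complete
peaks; *chronic steady* if the tail is near-constant with c above 10⁻⁵;
otherwise *undetermined*. The two thresholds sit far below the O(0.1–1)
dynamical scales and far above integrator noise. Note that the stimulus-free
initial state is not itself an equilibrium: g relaxes from 0 to its healthy
balance k_h/γ_g while every other component is stationary.

**Oscillation metrics.** After discarding the first half of the run as
transient, peaks and troughs of c are found on the dense output
(prominence-filtered) with quadratic refinement of extremum times; amplitude
is the mean peak-to-trough swing, wavelength the mean peak-to-peak interval
(standard error reported), measured over at least five cycles where the
horizon permits.

**Equilibria.** Damped Newton (step halving, up to 8 halvings, residual
∞-norm below 10⁻¹² to converge) on the reduced system. The multistart search
uses a Latin-hypercube over [0, 5] for the immune variables and mediators and
[0, 1] for (h, h_a, s) with a recorded seed; roots are deduplicated at
∞-distance 10⁻⁶ and unphysical roots (negative components, h + h_a > 1)
discarded. An equilibrium is *stable* iff max Re λ < −10⁻⁹ and *marginal*
within ±10⁻⁹, so transcritical points cannot be misclassified by round-off.
For branch seeding, the chronic state is more robustly obtained by settling a
simulation at a parameter point where it is attracting and Newton-polishing
the endpoint.

**Continuation.** Pseudo-arclength with a secant predictor and a Newton
corrector on the bordered system, corrector tolerance 10⁻¹⁰. Arclength is
measured in scaled coordinates (state components relative to their current
magnitude, the parameter relative to the range width), so the step bounds —
initial 10⁻³, range [10⁻⁷, 5·10⁻²] — are problem-independent. The step halves
on corrector failure or when a step doubles back onto the branch, and grows
by 1.3 after success. Folds are followed; stability is reported at every
accepted point, and branch residuals stay below 10⁻¹⁰.

**Event detection and location.** Along a branch, a Hopf is flagged by a sign
change of the leading complex-pair real part, and a zero real eigenvalue by a
sign change of the Jacobian determinant. Events are located by bisection on
the branch segment (corrector on the secant hyperplane, indicator tolerance
10⁻⁸; sign flips caused by a complex pair merging onto the real axis are
discarded as non-events). Near a fold the hyperplane intersects both solution
sheets and bisection stalls; saddle-nodes are then polished by Newton on the
bordered fold system (F = 0, Jv = 0, normalized null vector), which converges
to machine accuracy. A zero eigenvalue on the healthy (c = 0) branch is
labelled transcritical, elsewhere saddle-node. Every located Hopf re-verifies
against direct bisection in the bare parameter to within 10⁻⁶.

**Hopf criticality** is classified empirically rather than through the first
Lyapunov coefficient: the equilibrium is continued 1 % of the Hopf value to
the side where it is unstable and a trajectory is launched from a 2 %
perturbation along the leading eigenvector. A bounded small oscillation
around the equilibrium ⇒ supercritical; escape beyond 0.6·max(|c*|, 0.1) ⇒
subcritical (the hysteresis signature: the large attractor that trajectories
reach exists already on the stable side). Inconclusive probes enlarge the
offset and horizon up to three times and otherwise return "unclassified" —
never a guess. The probe is simple, independently checkable by simulation,
and matches all classified cases in the test suite.

**Two-parameter Hopf loci** are traced by re-locating the one-parameter Hopf
at each scan value via bracketed bisection seeded from the previous point
(bracket half-width 25 % of the previous value, widened up to 4× on failure),
rather than by bordered two-parameter continuation: this is slower but
embarrassingly verifiable, and the locus terminating out of bracket is the
natural signature of a fold–Hopf point. Region labels (bistable, monostable
resolved/chronic, oscillatory) combine the closed-form healthy verdict with
the continued chronic equilibrium's spectrum, and are verified by simulation
in tests.

**Periodic branches** are characterized by direct simulation with attractor
hand-off (the final state at one parameter seeds the next), swept in both
directions; hysteresis between sweeps flags a saddle-node-of-periodic-orbits
window, and a period exceeding 10× the branch median adjacent to the loss of
oscillation flags a homoclinic approach, with the bracketing interval
recorded. Both flags are deliberately bracket-valued, not point-located:
collocation-based orbit continuation and Floquet analysis are out of scope.

## Problem sizes

Branch continuations use 30–200 accepted points; bifurcation location costs
tens of Newton solves per event; the acceptance script (six targets,
including four full branch continuations with event location and a 128-start
multistart verification) completes in a few seconds on one core. Figure-level
Hopf-locus scenarios default to 5–9 scan points per curve; the sensitivity
scan covers all 23 parameters at four perturbation levels (93 simulations).

## What the computations do and do not show

The model's claims are qualitative regime boundaries and their organization
(bistability bounded by Hopf/saddle-node sets, a transcritical line where
macrophage and hepatocyte feedbacks jointly destabilize the healthy state,
oscillations where hepatocyte damage is strong but phagocytosis moderate).
The parameter set is an order-of-magnitude construction, not a fit to
patient data; no spatial structure, platelets, T cells or individual
cytokines are represented, so passing tests validate the dynamical-systems
machinery and the internal consistency of the model, not clinical
quantities. Known limitations: sub/supercriticality is empirical (no normal
form); SNPO, homoclinic and fold–Hopf points are flagged with brackets, not
located; periodic-orbit stability is inferred from simulation, not Floquet
multipliers.
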