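# Methods

## Scope and model family

`coshlib` models the axial evolution of hemoglobin saturation (HS, `S`) and
its heterogeneity in cylindrical capillary geometries. All continuum models
are steady-state ordinary differential equations in the axial coordinate
`x`, derived under two standing assumptions:

* **no axial diffusion** — oxygen leaving the capillary at `x` is consumed
  in the tissue slice normal to `x`, so slices decouple;
* **zero-order tissue consumption** — the metabolic rate `M0` does not
  depend on tissue Po2, which gives the Krogh solution for the radial
  Po2 profile in closed form.

A reduced discrete-RBC finite-volume solver (advection–diffusion–reaction
with individual moving cells) provides an independent validation route that
makes neither assumption; it resolves the oxygen field and produces σ_S
decay without any interaction coefficient as input.

## Canonical units and parameters

Internally everything is in μm, s, mmHg and μm³ of gaseous-equivalent O2.
Literature values in cgs convert on entry (solubilities in
ml O2·mmHg⁻¹·cm⁻³ are numerically identical in μm³O2·μm⁻³·mmHg⁻¹;
diffusivities scale by 1e8).

The shipped `mouse_cortex_baseline` preset (defaults of every dataclass):

| parameter | value | units | role |
| --- | --- | --- | --- |
| n, P50 | 2.64, 47.9 | –, mmHg | Hill curve (rodent blood) |
| α_rbc, α_p, α_w, α_t | 3.38e-5, 2.82e-5, 3.89e-5, 3.89e-5 | μm³O2 μm⁻³ mmHg⁻¹ | region solubilities |
| D_rbc, D_p, D_w, D_t | 950, 2180, 873, 2410 | μm²/s | region diffusivities |
| N_Hb·V_mol = C0 | 0.516 | μm³O2/μm³ | Hb-bound O2 capacity |
| k₋ | 44 | 1/s | Hb–O2 dissociation rate (PDE solver) |
| r_c, r_p, r_w | 1.5 (1.6), 2.0, 2.6 (2.5) | μm | RBC, lumen, endothelium radii; values in parentheses for the capillary-array geometry |
| r_t | 23 (22.6) | μm | tissue cylinder radius; the array value follows the equal-area rule r_t = d/√π for spacing d = 40 μm |
| V_rbc | 59 | μm³ | cylindrical model RBC (length V_rbc/(π r_c²)) |
| μ_LD, v_rbc | 0.3, 1000 | –, μm/s | linear density and RBC velocity |
| M0 | 1e-3 | μm³O2 μm⁻³ s⁻¹ | oxygen consumption |
| K_IV,0.5 | 5.15 | mmHg μm s/μm³O2 | intravascular resistance at μ_LD = 0.5; K_IV = 0.5·K_IV,0.5/μ_LD |
| L | 100 (300 for the RBC-interaction worked example) | μm | domain length |

The discharge hematocrit is set equal to the tube hematocrit
H_T = μ_LD (r_c/r_p)² (Fåhraeus effect neglected); attempts to set them
apart are rejected. `K_IV,0.5 = 5.15` is used for both RBC radii (1.5 and
1.6 μm) because no separate coefficient is available for the array
geometry; it is configurable.

### Adair constants

The four Adair constants shipped as defaults are a **synthetic** set,
obtained once by least-squares adjustment of the Adair form to the Hill
curve (n = 2.64, P50 = 47.9) on S ∈ [0.05, 0.95]. They reproduce the Hill
curve to ≲0.01 in S at mid saturations while showing the characteristic
Adair excess slope at low S (up to ~11% at S = 0.05). Species-specific
measured constants should be supplied through the `oxyhb.adair_coeffs`
config entry when available; the default set exists so the Adair code path
is exercised and the low-S sensitivity of τ_CI can be quantified.

## Interaction models

* **Nonlinear RBC ensemble model.** Finite weighted saturation classes
  co-integrated with the coupling term −(1/K_RI)(P_eq(S_i) − Σw P_eq(S)).
  `K_RI = ∞` switches interaction off exactly.
* **Linearized σ_S model.** Mean ODE plus
  Q_O2(S̄) dσ/dx = −(σ/K_RI)·dP_eq/dS|_S̄. Cheap; slightly underestimates
  σ_S relative to the ensemble model (the curvature of P_eq is dropped).
* **Nonlinear Krogh-based pair model.** At every ODE evaluation the scalar
  Po2-continuity equation partitions the slice consumption between the two
  capillaries (safeguarded Brent root find, residual < 1e-10 mmHg; the
  total-flux constraint is eliminated algebraically so it holds exactly).
  Negative branches — one capillary oxygenating the other — are covered by
  the piecewise extravascular-drop function. Different radii, densities and
  velocities per capillary are allowed; countercurrent flow is handled by
  shooting on the unknown upstream saturation (tolerance 1e-6).
* **Explicit pair model.** Closed-form partition
  j_t = j̄ ± (P_c,φ − P_c,ψ)/(2 K_CI) with
  K_CI = K_IV + (ln(r_t,mean/r_w) − ½)/(2π D_t α_t); requires equal
  geometry and linear density (velocities may differ). The two interaction
  terms are antisymmetric, so pair-total oxygen is conserved identically.
* **Linearized ΔS model.** Q_O2(S̄) dΔS/dx = −(ΔS/K_CI)·dP_eq/dS|_S̄,
  giving L_CI = K_CI·Q_O2(S̄)/(dP_eq/dS) and τ_CI = L_CI/v_rbc, which is
  velocity-independent because Q_O2 ∝ v_rbc.
* **Equal-outflux reference.** Each capillary assigned half the slice
  consumption, no coupling; the non-interacting baseline against which the
  reduction of ΔS is measured.

S̄ in the analytic scales defaults to the mean-ODE value at x = L/2.

## Numerical choices

* All ODEs use adaptive Runge–Kutta 4(5) (`scipy.solve_ivp`) with
  rtol = 1e-8, atol = 1e-10 and dense output sampled at 1 μm (both
  configurable). Halving the tolerances moves the venous saturation by
  < 1e-8.
* Saturation is clamped to [0, 1 − 1e-12] inside right-hand sides to avoid
  the P_eq singularity; if a trajectory actually reaches 1e-6 or
  1 − 1e-6 the integration stops and raises with the position — depletion
  is treated as a loud failure, not silently negative saturation.
* The dj_t/dx correction term of the mean equation (nonzero only for a
  varying tissue radius) is integrated by default; in the nonlinear pair
  model its equivalent is obtained by solving a 2×2 linear system with
  flux-partition sensitivities (finite differences on the partition), which
  makes the convective flux balance exact up to integrator tolerance.
* Exponential decay scales are fitted by unweighted least squares on
  ln σ_S vs x; K_RI is fitted by bounded scalar minimization of the
  integrated squared σ_S error (relative tolerance 1e-3, warning when the
  minimum sits at a search bound).
* The Po2-oscillation penetration radius is defined by matching cylindrical
  shell integrals, π(r_osc² − r_w²)ΔP_max = 2π∫ r ΔP dr, so that a constant
  envelope on [r_w, r_t] yields r_osc = r_t exactly; a flag reproduces the
  planar convention without the shell factor. The empirical estimator
  K_OS ≈ 1.49·Δr_osc − 3.58 (clamped at zero) is labelled as such.

## The discrete-RBC solver

The validation solver is deliberately reduced relative to a moving-mesh CFD
treatment:

* fixed axisymmetric grid; radial cells grouped into four static regions
  (RBC lane r < r_c, plasma annulus, endothelium, tissue with geometric
  grading ×1.3 capped at 2.4 μm). Default Δx = 0.6 μm, L = 100 μm.
* unit-CFL advection (Δt = Δx/v_rbc): the lumen field and the RBC
  indicator shift by exactly one cell per step, so the indicator suffers no
  numerical diffusion. RBC trains are spawned to reproduce the requested
  linear density up to cell rounding (the effective value is reported).
* each RBC carries one mean saturation; the Hb–O2 reaction
  f = k₋(S − (1−S)(P/P50)^n) acts in its occupied cells. Because the bound
  capacity C0 exceeds the solubility by four orders of magnitude, the
  dissolved side is stiff: the reaction is integrated by backward Euler per
  cell at frozen S (monotone scalar equation, safeguarded Newton), and S
  then drops by exactly the transferred oxygen, so the exchange conserves
  oxygen to machine precision.
* diffusion (region-wise D·α, harmonic interface conductances, zero-flux
  outer and axial boundaries) plus the zero-order tissue sink are advanced
  by backward Euler with one sparse LU factorization reused for the whole
  run. Reaction and diffusion are sub-cycled (default 8 per advection step):
  with a single step the lane Po2 sags tens of mmHg between reaction
  updates, which visibly weakens the simulated diffusive interaction.
* the lane has static, μ_LD-homogenized α and D; the moving indicator gates
  only the reaction and the hemoglobin content. This keeps the implicit
  operator constant in time.
* runs start from a mean-ODE/Krogh estimate (including the intravascular
  drop K_IV·j_t) and are declared statistically steady when the mean outlet
  saturation over one inlet-pattern period changes by < 1e-4 between
  periods (checked after 0.3 s of simulated time; the criterion is a design
  choice — the tissue Po2 store relaxes with time constant ~α_t·ΔP/M0 ≈ 1 s,
  so a poor initial field, not the RBC dynamics, dominates the transient).
  Statistics (outlet per-RBC saturations, time-mean field, max–min Po2
  envelope at x = L/2, per-step (x, S) samples for σ_S(x)) are then
  accumulated over an integer number of inlet-pattern periods.

What the solver does and does not validate: it reproduces, from resolved
physics, the monotone near-exponential decay of σ_S and a fitted K_RI of
the right magnitude (consistent within a factor ~1.3 with the
K_IV + K_OS(Δr_osc) estimate at baseline). It is not bit-comparable to a
full moving-mesh implementation: intra-RBC gradients, plasma velocity
profiles and the Fåhraeus–Lindqvist rheology are all absent, and its
fitted K_RI (~13–14 at baseline) should be read as the reduced model's own
coefficient, not a replacement for values fitted to fully resolved
simulations. Agreement between the PDE route and the fitted-coefficient
ODE route (within 15% in outlet σ_S) is therefore an internal-consistency
statement about the decay mechanism, not a claim about any particular
K_RI value in vivo.

## Study conditions emulated by the defaults

The default inlet conditions are the canonical heterogeneity scenarios: an
alternating two-value RBC train (0.8/0.6, i.e. σ_S,a = 0.1 about a mean of
0.7) representing the merge of two branches, a uniform random inlet
ensemble (equal weight per RBC, seeded), and per-capillary inlet values
0.8/0.6 for the parallel pair. These represent small-scale heterogeneity
immediately downstream of converging bifurcations; they do not emulate
network-scale heterogeneity, pulsatile flow, or temporally varying
hematocrit, so passing tests say nothing about those regimes.

## Known limitations

* Zero-order consumption: at low tissue Po2, Michaelis–Menten kinetics
  would raise tissue Po2 and shift the supplied-region partition.
* No Bohr effect and no myoglobin-facilitated diffusion; both would modify
  dP_eq/dS or the effective tissue diffusivity and hence every decay scale.
* The Hill curve is inaccurate at low saturation; the Adair path bounds the
  resulting τ_CI error (≤ ~10% at low S̄ with the shipped constants).
* The pair models assume the equal-area reduction of a regular array to a
  diagonal pair; irregular spacings are out of scope.
* The ODE models' accuracy degrades when linear densities or velocities
  differ strongly between capillaries; the ordering relative to the
  equal-outflux reference is still correct, but distal ΔS is overestimated.
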