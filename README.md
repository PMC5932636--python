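# coshlib

Models for the evolution and decay of hemoglobin-saturation heterogeneity
(HSH) in capillaries.

## The problem

Capillary transit time heterogeneity (CTH) — the spread of red-blood-cell
(RBC) transit times through a capillary bed — is widely used as a proxy for
how unevenly blood delivers oxygen to tissue. But transit time alone does
not determine the oxygen content of blood leaving a capillary. Two diffusive
mechanisms actively homogenize hemoglobin saturation (HS, denoted S) on the
way to the venous end:

1. **RBC diffusive interaction.** Downstream of a converging bifurcation,
   RBCs with different S share one tissue cylinder. A cell above the
   ensemble mean has a higher equilibrium Po2 and unloads faster; one below
   unloads slower. The standard deviation σ_S of the per-RBC saturations
   decays nearly exponentially along the vessel.
2. **Capillary diffusive interaction.** Parallel capillaries with different
   S split the metabolic consumption of the tissue between them according
   to the continuity of tissue Po2: the better-oxygenated vessel supplies a
   larger tissue region, so the inter-capillary saturation difference
   ΔS = S_φ − S_ψ also decays nearly exponentially.

Both mechanisms act on time scales of one to two tenths of a second —
shorter than measured capillary transit times — so capillary outflow
saturation heterogeneity (COSH) is substantially smaller than CTH alone
would suggest. This package implements the ordinary-differential-equation
models of both mechanisms, their analytic decay scales, and a reduced
discrete-RBC finite-volume solver used as an internal validation oracle.
It is aimed at researchers in microvascular oxygen transport and
physiological modeling.

## The models

With the oxy-hemoglobin equilibrium curve P_eq(S) = P50·(S/(1−S))^(1/n)
(Hill; a four-constant Adair form is also available), the total oxygen
convective capacity of a capillary is

    Q_O2(S) = v_rbc (μ_LD π r_c² C0 + π r_p² α_eff dP_eq/dS),

and the mean saturation obeys Q_O2(S) dS/dx = −j_t(x), where
j_t = M0 π (r_t² − r_w²) is the consumption per unit length of the
supplied Krogh cylinder. The interaction models add a single resistance
coefficient each:

    Q_O2(S_i) dS_i/dx = −j_t − (1/K_RI)(P_eq(S_i) − mean_w[P_eq(S)])   (RBCs)
    Q_O2(S̄)  dΔS/dx  = −(ΔS/K_CI) dP_eq/dS|_S̄                     (capillaries)

K_CI has the closed form K_IV + (ln(r_t,mean/r_w) − ½)/(2π D_t α_t); K_RI
is fitted (K_IV is the intravascular resistance coefficient). Both models
define decay lengths L = K·Q_O2(S̄)/(dP_eq/dS) and decay times τ = L/v_rbc;
τ_CI is exactly independent of the RBC velocity and depends only weakly
(logarithmically) on capillary spacing.

## Worked example

RBC diffusive interaction at the baseline mouse-cortex parameters
(alternating inlet S = 0.8/0.6, K_RI = 11.1 mmHg·μm·s/μm³O2, μ_LD = 0.3,
v_rbc = 1 mm/s, L = 300 μm):

```python
import numpy as np
from coshlib import integrate_ensemble_nonlinear, SaturationEnsemble
from coshlib.oxyhb import hill_curve
from coshlib.params import CapillarySpec, TissueSpec, Solubilities
from coshlib.rbc_interaction import fit_exponential_decay

sol, curve = Solubilities(), hill_curve()
cap = CapillarySpec(r_c=1.5, r_p=2.0, r_w=2.6, mu_LD=0.3, v_rbc=1000.0, L=300.0)
tis = TissueSpec(r_t=23.0, M0=1e-3)

ens = SaturationEnsemble(values=np.array([0.8, 0.6]))
prof = integrate_ensemble_nonlinear(ens, 11.1, cap, tis, sol, curve)
fit = fit_exponential_decay(prof.x, prof.sigma, v_rbc=cap.v_rbc)
```

This prints (via the obvious format strings):

```
mean saturation: 0.700 -> 0.263
sigma_S:         0.1000 -> 0.0158 (6.3x reduction)
decay length L_RI = 168 um, decay time tau_RI = 0.168 s
```

The mean saturation falls from 0.70 to 0.26 over the 300 μm vessel while
the spread among RBCs collapses roughly sevenfold; the fitted decay time of
0.17 s is well below typical measured capillary transit times (~0.2–0.8 s),
which is the core quantitative point: diffusive interaction has enough time
to homogenize saturation while blood traverses the capillary bed.

The same models are exposed on the command line:

```
coshlib rbc-interaction --kri 11.1 --inlet alternating:0.8,0.6 --out sigma.csv
coshlib capillary-interaction --inlets 0.8,0.6 --spacing 40 --model explicit --out pair.csv
coshlib discrete-sim --inlet alternating:0.8,0.6 --out run/
coshlib sweep --model tau_ci --param mu_LD=0.2,0.4,0.6 --out sweep.csv
```

## Layout

| module | contents |
| --- | --- |
| `coshlib.oxyhb` | Hill/Adair equilibrium curves, slopes, slope minimizer |
| `coshlib.params` | geometry, hematocrit, solubilities, resistance coefficients, presets |
| `coshlib.mean_saturation` | mean-S ODE, Krogh tissue Po2, BKCR comparison model |
| `coshlib.rbc_interaction` | ensemble and linearized σ_S models, decay fitting, K_RI estimation, Po2-oscillation spreading |
| `coshlib.capillary_interaction` | nonlinear/explicit/linearized pair models, flux partition, τ_CI |
| `coshlib.discrete_solver` | reduced axisymmetric finite-volume solver with moving RBCs |
| `coshlib.experiments` | inlet generators, parameter sweeps |
| `coshlib.cli` | `coshlib` command-line entry point |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
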