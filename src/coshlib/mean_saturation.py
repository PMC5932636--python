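"""Mean hemoglobin-saturation ODE along a capillary and Krogh tissue profiles.

The axial evolution of the mean saturation follows from the mass balance
between the convective oxygen flux in the capillary and the metabolic
consumption in the tissue slice at each axial position,

    Q_O2(S) dS/dx = -j_t(x) + v_rbc pi r_p^2 alpha_eff (1 - H_T) K_IV dj_t/dx,

where Q_O2 is the total oxygen convective capacity and j_t the consumption
per unit length.  The correction term involving dj_t/dx vanishes for a
straight tissue cylinder and is small otherwise, but is integrated by
default for completeness.

The tissue Po2 around the capillary follows the Krogh solution of the
radial diffusion equation with a zero-order sink and zero-flux outer
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from coshlib.oxyhb import OxyHbCurve
from coshlib.params import (
    CapillarySpec,
    ResistanceSet,
    Solubilities,
    TissueSpec,
    consumption_per_length,
    convective_capacity,
    effective_solubility,
)

#: saturation below which the integration is halted as depleted
S_DEPLETED = 1e-6


class SaturationDepletionError(RuntimeError):
    """Raised when the saturation leaves (0, 1) during integration."""

    def __init__(self, x: float, boundary: str):
        self.x = x
        self.boundary = boundary
        super().__init__(
            f"saturation reached the {boundary} boundary at x = {x:.3f} um")


@dataclass(frozen=True)
class SaturationProfile:
    """Axial saturation profile S(x) with the RBC velocity used.

    ``x`` is a strictly increasing grid in um starting at 0, ``S`` the
    saturation at each grid point; ``transit_time`` re-expresses the grid
    as tau = x / v_rbc.
    """

    x: np.ndarray
    S: np.ndarray
    v_rbc: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        S = np.asarray(self.S, dtype=float)
        if x.ndim != 1 or x.shape != S.shape:
            raise ValueError("x and S must be 1-d arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "S", S)

    @property
    def transit_time(self) -> np.ndarray:
        return self.x / self.v_rbc

    @property
    def S_a(self) -> float:
        return float(self.S[0])

    @property
    def S_v(self) -> float:
        return float(self.S[-1])

    def at(self, x):
        """Saturation interpolated at axial position(s) x."""
        return np.interp(x, self.x, self.S)


def _mean_rhs_factory(spec, tissue, sol, curve, K_IV, include_djt_term):
    alpha_eff = effective_solubility(spec.H_T, sol)
    corr = spec.v_rbc * math.pi * spec.r_p**2 * alpha_eff * (1 - spec.H_T) * K_IV

    def rhs(x, y):
        S = min(max(y[0], S_DEPLETED), 1.0 - S_DEPLETED)
        jt = consumption_per_length(x, tissue, spec.r_w)
        num = -jt
        if include_djt_term:
            num += corr * tissue.djt_dx(x, spec.r_w)
        return [num / convective_capacity(S, spec, sol, curve)]

    return rhs


def integrate_mean(S_a: float,
                   spec: CapillarySpec,
                   tissue: TissueSpec,
                   sol: Solubilities,
                   curve: OxyHbCurve,
                   resistances: Optional[ResistanceSet] = None,
                   include_djt_term: bool = True,
                   rtol: float = 1e-8,
                   atol: float = 1e-10,
                   dx_out: float = 1.0) -> SaturationProfile:
    """Integrate the mean-saturation ODE from the arterial inlet.

    Parameters
    ----------
    S_a : float
        Inlet (arterial) saturation, in (0, 1).
    include_djt_term : bool
        Whether to integrate the dj_t/dx correction term (exactly zero for
        a constant tissue radius).
    rtol, atol : float
        Tolerances of the adaptive Runge-Kutta 4(5) integrator.
    dx_out : float
        Output sampling step of the dense solution, um.

    Returns
    -------
    SaturationProfile
        Saturation sampled every ``dx_out`` um on [0, L].

    Raises
    ------
    SaturationDepletionError
        If the saturation reaches 0 or 1 before the venous end.
    """
    if not (0 < S_a < 1):
        raise ValueError("inlet saturation must lie in (0, 1)")
    resistances = resistances or ResistanceSet()
    K_IV = resistances.k_iv_at(spec.mu_LD)
    rhs = _mean_rhs_factory(spec, tissue, sol, curve, K_IV, include_djt_term)

    def depleted(x, y):
        return y[0] - S_DEPLETED

    def saturated(x, y):
        return (1.0 - S_DEPLETED) - y[0]

    depleted.terminal = True
    saturated.terminal = True

    res = solve_ivp(rhs, (0.0, spec.L), [S_a], method="RK45",
                    rtol=rtol, atol=atol, dense_output=True,
                    events=[depleted, saturated])
    if res.t_events[0].size:
        raise SaturationDepletionError(float(res.t_events[0][0]), "depleted")
    if res.t_events[1].size:
        raise SaturationDepletionError(float(res.t_events[1][0]), "saturated")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"mean-saturation integration failed: {res.message}")

    x = np.arange(0.0, spec.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], spec.L)
    S = res.sol(x)[0]
    meta = {"S_a": S_a, "rtol": rtol, "atol": atol,
            "include_djt_term": include_djt_term}
    return SaturationProfile(x=x, S=S, v_rbc=spec.v_rbc, metadata=meta)


def saturation_vs_transit_time(profile: SaturationProfile) -> pd.DataFrame:
    """Reparameterize a profile by transit time tau = x / v_rbc.

    Returns a table with columns ``tau_s`` and ``S``; S(tau) equals
    S(x = v_rbc tau) exactly since the velocity is constant.
    """
    return pd.DataFrame({"tau_s": profile.transit_time, "S": profile.S})


def wall_po2(x: float, profile: SaturationProfile, spec: CapillarySpec,
             tissue: TissueSpec, resistances: ResistanceSet,
             curve: OxyHbCurve) -> float:
    """Po2 at the outer capillary wall, P_w = P_eq(S(x)) - K_IV j_t(x)."""
    S = float(profile.at(x))
    jt = consumption_per_length(x, tissue, spec.r_w)
    K_IV = resistances.k_iv_at(spec.mu_LD)
    return float(curve.po2(S)) - K_IV * jt


def krogh_tissue_po2(x: float, r, profile: SaturationProfile,
                     spec: CapillarySpec, tissue: TissueSpec,
                     resistances: ResistanceSet, curve: OxyHbCurve):
    """Tissue Po2 at axial position x and radius r (Krogh solution).

    P(x, r) = P_w(x) - M0/(4 D_t alpha_t) [2 r_t^2 ln(r/r_w) - r^2 + r_w^2]
    for r_w <= r <= r_t(x); the radial derivative vanishes at r = r_t.
    """
    r = np.asarray(r, dtype=float)
    r_t = tissue.r_t_at(x)
    if np.any(r < spec.r_w) or np.any(r > r_t):
        raise ValueError("radius outside [r_w, r_t]")
    P_w = wall_po2(x, profile, spec, tissue, resistances, curve)
    fac = tissue.M0 / (4 * tissue.D_t * tissue.alpha_t)
    out = P_w - fac * (2 * r_t**2 * np.log(r / spec.r_w) - r**2 + spec.r_w**2)
    return out if out.ndim else float(out)


def extravascular_drop(j_t: float, tissue: TissueSpec, r_w: float) -> float:
    """Extravascular Po2 drop associated with a local oxygen outflux j_t.

    The supplied tissue radius is recovered from the outflux,
    r_t = sqrt(j_t/(M0 pi) + r_w^2), and the Krogh drop between the wall
    and r_t is returned.  A negative outflux (capillary being oxygenated by
    its surroundings) produces no extravascular drop on this side, so 0 is
    returned for j_t < 0.
    """
    if j_t < 0:
        return 0.0
    if tissue.M0 == 0:
        if j_t == 0:
            return 0.0
        raise ValueError("positive outflux with zero consumption rate")
    r_t = math.sqrt(j_t / (tissue.M0 * math.pi) + r_w**2)
    fac = tissue.M0 / (4 * tissue.D_t * tissue.alpha_t)
    return fac * (2 * r_t**2 * math.log(r_t / r_w) - r_t**2 + r_w**2)


def bkcr_profile(C_a: float, k: float, tau: float, alpha_rbc: float,
                 p50: float, n: float, B: float, C_t: float,
                 rtol: float = 1e-8, atol: float = 1e-12,
                 n_out: int = 101) -> pd.DataFrame:
    """Bohr-Kety-Crone-Renkin comparison model on the unit coordinate.

    Integrates dC/dx~ = -k tau (alpha_rbc P50 (C/(B - C))^(1/n) - C_t) for
    the bound oxygen concentration C over the normalized axial coordinate
    x~ in [0, 1].  ``k`` is the single rate constant of the model (no
    default is provided; it is a free input), ``tau`` the transit time and
    ``B`` the maximal bound oxygen concentration.

    Returns a table with columns ``x_norm`` and ``C``.
    """
    if not (0 <= C_a <= B):
        raise ValueError("inlet concentration must lie in [0, B]")

    def rhs(x, y):
        C = min(max(y[0], 0.0), B * (1 - 1e-12))
        return [-k * tau * (alpha_rbc * p50 * (C / (B - C)) ** (1.0 / n) - C_t)]

    def exhausted(x, y):
        return y[0]

    def full(x, y):
        return B - y[0]

    exhausted.terminal = True
    full.terminal = True

    res = solve_ivp(rhs, (0.0, 1.0), [C_a], method="RK45", rtol=rtol,
                    atol=atol, dense_output=True, events=[exhausted, full])
    for te, name in zip(res.t_events, ("lower", "upper")):
        if te.size:
            raise SaturationDepletionError(float(te[0]), name)
    x = np.linspace(0.0, 1.0, n_out)
    return pd.DataFrame({"x_norm": x, "C": res.sol(x)[0]})
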