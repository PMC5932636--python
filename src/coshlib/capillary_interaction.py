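"""Diffusive interaction between parallel capillaries.

Two parallel capillaries (phi and psi) with different saturations share a
tissue slice of area A at every axial position.  Neglecting axial
diffusion, the oxygen outfluxes must balance the metabolic consumption of
the slice,

    j_t,phi(x) + j_t,psi(x) = M0 (A - 2 pi r_w^2),

while the continuity of tissue Po2 at the interface between the two
(variable-radius) Krogh cylinders partitions the total flux between them.
Three models of decreasing fidelity are provided:

* the *nonlinear Krogh-based model*: the flux partition is re-solved from
  the continuity condition at every ODE evaluation; different flows and
  radii per capillary are allowed, including one capillary oxygenating the
  other (negative outflux);
* the *explicit Krogh-based model*: equal geometry and linear density are
  assumed, which yields the closed-form partition
  j_t,phi = j_bar + (P_c,phi - P_c,psi) / (2 K_CI) with the
  capillary-interaction resistance coefficient K_CI;
* the *linearized model* for the saturation difference
  Delta S = S_phi - S_psi, whose near-exponential decay defines the
  length scale L_CI = K_CI Q_O2(S_bar) (dP_eq/dS)^-1 and the velocity-
  independent time scale tau_CI = L_CI / v_rbc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from coshlib.oxyhb import OxyHbCurve
from coshlib.params import (
    CapillarySpec,
    ResistanceSet,
    Solubilities,
    TissueSpec,
    convective_capacity,
    effective_solubility,
    k_ci,
)
from coshlib.mean_saturation import (
    S_DEPLETED,
    SaturationDepletionError,
    extravascular_drop,
)


# ---------------------------------------------------------------------- #
# state container
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class CapillaryPairState:
    """Two parallel capillaries sharing a tissue slice.

    ``A`` is the area of the normal slice supplied by the pair (um^2); with
    spacing d in a regular array each capillary supplies an area d^2, so
    A = 2 d^2 and the mean Krogh radius is r_t_mean = sqrt(A / (2 pi))
    = d / sqrt(pi).
    """

    spec_phi: CapillarySpec
    spec_psi: CapillarySpec
    S_a_phi: float
    S_a_psi: float
    tissue: TissueSpec
    sol: Solubilities
    curve: OxyHbCurve
    A: float
    resistances: ResistanceSet = field(default_factory=ResistanceSet)

    def __post_init__(self):
        for s in (self.S_a_phi, self.S_a_psi):
            if not (0 < s < 1):
                raise ValueError("inlet saturations must lie in (0, 1)")
        if self.A <= math.pi * (self.spec_phi.r_w**2 + self.spec_psi.r_w**2):
            raise ValueError("slice area must exceed the capillary lumens")
        if not math.isclose(self.spec_phi.L, self.spec_psi.L):
            raise ValueError("both capillaries must span the same domain length")

    @classmethod
    def from_spacing(cls, spacing: float, **kwargs) -> "CapillaryPairState":
        """Build a pair state with slice area A = 2 * spacing^2."""
        return cls(A=2.0 * spacing**2, **kwargs)

    @property
    def L(self) -> float:
        return self.spec_phi.L

    @property
    def r_t_mean(self) -> float:
        return math.sqrt(self.A / (2.0 * math.pi))

    @property
    def total_consumption_per_length(self) -> float:
        """M0 (A - 2 pi r_w^2), um^3 O2 um^-1 s^-1 (exact at every x)."""
        rw2 = self.spec_phi.r_w**2 + self.spec_psi.r_w**2
        return self.tissue.M0 * (self.A - math.pi * rw2)

    def k_iv_phi(self) -> float:
        return self.resistances.k_iv_at(self.spec_phi.mu_LD)

    def k_iv_psi(self) -> float:
        return self.resistances.k_iv_at(self.spec_psi.mu_LD)

    def k_ci(self) -> float:
        """Capillary-interaction coefficient for the (equal-geometry) pair."""
        if self.resistances.K_CI is not None:
            return self.resistances.K_CI
        return k_ci(self.k_iv_phi(), self.tissue.D_t, self.tissue.alpha_t,
                    self.r_t_mean, self.spec_phi.r_w)


@dataclass(frozen=True)
class PairProfiles:
    """Axial saturation and outflux profiles of a capillary pair."""

    x: np.ndarray
    S_phi: np.ndarray
    S_psi: np.ndarray
    jt_phi: np.ndarray
    jt_psi: np.ndarray
    v_phi: float
    v_psi: float
    metadata: dict = field(default_factory=dict)

    @property
    def delta_S(self) -> np.ndarray:
        return self.S_phi - self.S_psi

    @property
    def delta_S_a(self) -> float:
        return float(self.delta_S[0])

    @property
    def delta_S_v(self) -> float:
        return float(self.delta_S[-1])

    @property
    def drop_fraction(self) -> float:
        """Fraction of the inlet saturation difference lost over the domain."""
        return 1.0 - self.delta_S_v / self.delta_S_a


# ---------------------------------------------------------------------- #
# flux partition (nonlinear Krogh-based model)
# ---------------------------------------------------------------------- #
def solve_flux_partition(P_c_phi: float, P_c_psi: float, A: float,
                         tissue: TissueSpec, r_w: float,
                         K_IV_phi: float, K_IV_psi: float,
                         residual_tol: float = 1e-10) -> tuple[float, float]:
    """Partition the slice consumption between the two capillaries.

    Solves the scalar nonlinear equation expressing the continuity of
    tissue Po2 at the interface between the two Krogh cylinders, with the
    total flux constrained to the slice consumption.  Negative branches
    (one capillary oxygenating the other) are handled by the piecewise
    extravascular drop.

    Returns ``(j_t_phi, j_t_psi)``.
    """
    j_tot = tissue.M0 * (A - 2.0 * math.pi * r_w**2)

    def residual(j_phi):
        j_psi = j_tot - j_phi
        side_phi = P_c_phi - K_IV_phi * j_phi - extravascular_drop(
            j_phi, tissue, r_w)
        side_psi = P_c_psi - K_IV_psi * j_psi - extravascular_drop(
            j_psi, tissue, r_w)
        return side_phi - side_psi

    # residual is strictly decreasing in j_phi; expand a bracket around the
    # physical range until the signs differ
    half_width = abs(j_tot) + 1.0
    lo, hi = 0.5 * j_tot - half_width, 0.5 * j_tot + half_width
    for _ in range(60):
        if residual(lo) > 0 and residual(hi) < 0:
            break
        lo -= half_width
        hi += half_width
        half_width *= 2.0
    else:
        raise RuntimeError(
            "no physical bracket for the flux partition: "
            f"P_c_phi={P_c_phi}, P_c_psi={P_c_psi}, j_tot={j_tot}")
    j_phi = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(residual(j_phi)) > residual_tol:  # pragma: no cover - defensive
        raise RuntimeError("flux partition residual above tolerance")
    return j_phi, j_tot - j_phi


def _pair_correction_coeffs(state: CapillaryPairState):
    """Coefficients c_i = v pi r_p^2 alpha_eff (1 - H_T) K_IV per capillary."""
    out = []
    for spec, kiv in ((state.spec_phi, state.k_iv_phi()),
                      (state.spec_psi, state.k_iv_psi())):
        alpha_eff = effective_solubility(spec.H_T, state.sol)
        out.append(spec.v_rbc * math.pi * spec.r_p**2 * alpha_eff
                   * (1 - spec.H_T) * kiv)
    return np.array(out)


def integrate_pair_nonlinear(state: CapillaryPairState,
                             rtol: float = 1e-8,
                             atol: float = 1e-10,
                             dx_out: float = 1.0,
                             include_djt_term: bool = True,
                             countercurrent: bool = False,
                             shooting_tol: float = 1e-6) -> PairProfiles:
    """Integrate the nonlinear Krogh-based pair model.

    The flux partition is re-solved at every ODE evaluation (no lagging).
    With ``include_djt_term`` the dj_t/dx correction of the mean-saturation
    equation is included through the chain rule, which makes the convective
    flux balance exact up to integrator tolerance.  With ``countercurrent``
    the psi capillary flows in the -x direction and its inlet saturation is
    imposed at x = L by shooting on the unknown x = 0 value.
    """
    curve = state.curve
    K_phi, K_psi = state.k_iv_phi(), state.k_iv_psi()
    c = _pair_correction_coeffs(state)
    r_w = state.spec_phi.r_w
    signs = np.array([1.0, -1.0 if countercurrent else 1.0])

    def partition(S):
        P = curve.po2(np.clip(S, S_DEPLETED, 1 - S_DEPLETED))
        return np.array(solve_flux_partition(
            float(P[0]), float(P[1]), state.A, state.tissue, r_w,
            K_phi, K_psi))

    def rhs(x, y):
        S = np.clip(y, S_DEPLETED, 1 - S_DEPLETED)
        j = partition(S)
        Q = np.array([
            convective_capacity(S[0], state.spec_phi, state.sol, curve),
            convective_capacity(S[1], state.spec_psi, state.sol, curve)])
        if not include_djt_term:
            return signs * (-j) / Q
        # chain rule dj_i/dx = sum_k (dj_i/dS_k) S'_k; solve the 2x2 linear
        # system Q_i S'_i - c_i sum_k a_ik S'_k = -s_i j_i
        h = 1e-7
        a = np.empty((2, 2))
        for k in range(2):
            Sk = S.copy()
            Sk[k] += h
            a[:, k] = (partition(Sk) - j) / h
        M = np.diag(Q) - c[:, None] * a
        return np.linalg.solve(M, -signs * j)

    def depleted(x, y):
        return np.min(y) - S_DEPLETED

    def saturated(x, y):
        return (1 - S_DEPLETED) - np.max(y)

    depleted.terminal = True
    saturated.terminal = True

    def integrate(y0):
        res = solve_ivp(rhs, (0.0, state.L), y0, method="RK45", rtol=rtol,
                        atol=atol, dense_output=True,
                        events=[depleted, saturated])
        if res.t_events[0].size:
            raise SaturationDepletionError(float(res.t_events[0][0]),
                                           "depleted")
        if res.t_events[1].size:
            raise SaturationDepletionError(float(res.t_events[1][0]),
                                           "saturated")
        if not res.success:  # pragma: no cover - defensive
            raise RuntimeError(f"pair integration failed: {res.message}")
        return res

    if not countercurrent:
        res = integrate([state.S_a_phi, state.S_a_psi])
    else:
        # shoot on the unknown saturation of psi at x = 0 (its venous end);
        # trial values that deplete (or saturate) before x = L map to a
        # signed penalty so the bracket stays usable
        def mismatch(s_psi_0):
            try:
                r = integrate([state.S_a_phi, s_psi_0])
            except SaturationDepletionError as err:
                return -1.0 if err.boundary == "depleted" else 1.0
            return r.sol(state.L)[1] - state.S_a_psi

        lo, hi = 5e-3, 1 - 5e-3
        s0 = brentq(mismatch, lo, hi, xtol=shooting_tol)
        res = integrate([state.S_a_phi, s0])

    x = np.arange(0.0, state.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], state.L)
    S = res.sol(x)
    j = np.array([partition(S[:, i]) for i in range(x.size)]).T
    return PairProfiles(x=x, S_phi=S[0], S_psi=S[1], jt_phi=j[0], jt_psi=j[1],
                        v_phi=state.spec_phi.v_rbc, v_psi=state.spec_psi.v_rbc,
                        metadata={"model": "nonlinear",
                                  "countercurrent": countercurrent,
                                  "include_djt_term": include_djt_term})


# ---------------------------------------------------------------------- #
# explicit and linearized models
# ---------------------------------------------------------------------- #
def _require_equal_geometry(state: CapillaryPairState, equal_velocity: bool):
    p, q = state.spec_phi, state.spec_psi
    same = (math.isclose(p.mu_LD, q.mu_LD) and math.isclose(p.r_c, q.r_c)
            and math.isclose(p.r_p, q.r_p) and math.isclose(p.r_w, q.r_w))
    if not same:
        raise ValueError(
            "this model assumes equal linear density and geometry in both "
            "capillaries; use the nonlinear Krogh-based model instead")
    if equal_velocity and not math.isclose(p.v_rbc, q.v_rbc):
        raise ValueError(
            "this model assumes equal RBC velocities; use the explicit or "
            "nonlinear model instead")


def integrate_pair_explicit(state: CapillaryPairState,
                            rtol: float = 1e-8,
                            atol: float = 1e-10,
                            dx_out: float = 1.0) -> PairProfiles:
    """Integrate the explicit Krogh-based pair model.

    Uses the closed-form flux partition with coefficient K_CI and the mean
    outflux j_bar = M0 pi (r_t_mean^2 - r_w^2); equal linear density and
    geometry are required (velocities may differ).  The two interaction
    terms are antisymmetric, so the total outflux is conserved exactly.
    """
    _require_equal_geometry(state, equal_velocity=False)
    curve = state.curve
    K_CI = state.k_ci()
    r_w = state.spec_phi.r_w
    j_bar = state.tissue.M0 * math.pi * (state.r_t_mean**2 - r_w**2)

    def fluxes(S):
        P = curve.po2(np.clip(S, S_DEPLETED, 1 - S_DEPLETED))
        dj = (P[0] - P[1]) / (2.0 * K_CI)
        return np.array([j_bar + dj, j_bar - dj])

    def rhs(x, y):
        S = np.clip(y, S_DEPLETED, 1 - S_DEPLETED)
        j = fluxes(S)
        Q = np.array([
            convective_capacity(S[0], state.spec_phi, state.sol, curve),
            convective_capacity(S[1], state.spec_psi, state.sol, curve)])
        return -j / Q

    def depleted(x, y):
        return np.min(y) - S_DEPLETED

    def saturated(x, y):
        return (1 - S_DEPLETED) - np.max(y)

    depleted.terminal = True
    saturated.terminal = True

    res = solve_ivp(rhs, (0.0, state.L), [state.S_a_phi, state.S_a_psi],
                    method="RK45", rtol=rtol, atol=atol, dense_output=True,
                    events=[depleted, saturated])
    if res.t_events[0].size:
        raise SaturationDepletionError(float(res.t_events[0][0]), "depleted")
    if res.t_events[1].size:
        raise SaturationDepletionError(float(res.t_events[1][0]), "saturated")

    x = np.arange(0.0, state.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], state.L)
    S = res.sol(x)
    j = np.array([fluxes(S[:, i]) for i in range(x.size)]).T
    return PairProfiles(x=x, S_phi=S[0], S_psi=S[1], jt_phi=j[0], jt_psi=j[1],
                        v_phi=state.spec_phi.v_rbc, v_psi=state.spec_psi.v_rbc,
                        metadata={"model": "explicit", "K_CI": K_CI})


@dataclass(frozen=True)
class DeltaProfile:
    """Mean saturation and inter-capillary saturation difference vs x."""

    x: np.ndarray
    S_mean: np.ndarray
    delta_S: np.ndarray
    v_rbc: float
    metadata: dict = field(default_factory=dict)


def integrate_delta_linearized(S_a_mean: float,
                               delta_S_a: float,
                               state: CapillaryPairState,
                               rtol: float = 1e-8,
                               atol: float = 1e-10,
                               dx_out: float = 1.0,
                               freeze_mean: bool = False) -> DeltaProfile:
    """Integrate the linearized model for the saturation difference.

    Co-integrates the mean-saturation ODE (with the average outflux j_bar)
    and Q_O2(S_bar) d(Delta S)/dx = -(Delta S / K_CI) dP_eq/dS|_S_bar.
    Equal velocities, linear densities and geometry are required.  With
    ``freeze_mean`` the mean saturation is held at its inlet value, in
    which case Delta S decays exactly exponentially with length L_CI.
    """
    _require_equal_geometry(state, equal_velocity=True)
    curve = state.curve
    K_CI = state.k_ci()
    spec = state.spec_phi
    r_w = spec.r_w
    j_bar = state.tissue.M0 * math.pi * (state.r_t_mean**2 - r_w**2)

    def rhs(x, y):
        S = min(max(y[0], S_DEPLETED), 1 - S_DEPLETED)
        Q = convective_capacity(S, spec, state.sol, curve)
        dmean = 0.0 if freeze_mean else -j_bar / Q
        ddelta = -y[1] * curve.slope(S) / (K_CI * Q)
        return [dmean, ddelta]

    def depleted(x, y):
        return y[0] - S_DEPLETED

    depleted.terminal = True

    res = solve_ivp(rhs, (0.0, state.L), [S_a_mean, delta_S_a],
                    method="RK45", rtol=rtol, atol=atol, dense_output=True,
                    events=[depleted])
    if res.t_events[0].size:
        raise SaturationDepletionError(float(res.t_events[0][0]), "depleted")

    x = np.arange(0.0, state.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], state.L)
    S_mean, dS = res.sol(x)
    return DeltaProfile(x=x, S_mean=S_mean, delta_S=dS, v_rbc=spec.v_rbc,
                        metadata={"model": "linearized", "K_CI": K_CI})


def equal_flux_reference(state: CapillaryPairState,
                         rtol: float = 1e-8,
                         atol: float = 1e-10,
                         dx_out: float = 1.0) -> PairProfiles:
    """Non-interacting reference: each capillary takes half the consumption.

    Each capillary is integrated independently with the constant outflux
    j_t = M0 (A - 2 pi r_w^2) / 2; any decay of the saturation difference
    then comes only from the curvature of the equilibrium curve, not from
    diffusive interaction.
    """
    curve = state.curve
    j_half = 0.5 * state.total_consumption_per_length

    profiles = []
    for spec, S_a in ((state.spec_phi, state.S_a_phi),
                      (state.spec_psi, state.S_a_psi)):
        def rhs(x, y, spec=spec):
            S = min(max(y[0], S_DEPLETED), 1 - S_DEPLETED)
            return [-j_half / convective_capacity(S, spec, state.sol, curve)]

        def depleted(x, y):
            return y[0] - S_DEPLETED

        depleted.terminal = True
        res = solve_ivp(rhs, (0.0, state.L), [S_a], method="RK45",
                        rtol=rtol, atol=atol, dense_output=True,
                        events=[depleted])
        if res.t_events[0].size:
            raise SaturationDepletionError(float(res.t_events[0][0]),
                                           "depleted")
        profiles.append(res)

    x = np.arange(0.0, state.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], state.L)
    S_phi = profiles[0].sol(x)[0]
    S_psi = profiles[1].sol(x)[0]
    j = np.full_like(x, j_half)
    return PairProfiles(x=x, S_phi=S_phi, S_psi=S_psi, jt_phi=j, jt_psi=j,
                        v_phi=state.spec_phi.v_rbc, v_psi=state.spec_psi.v_rbc,
                        metadata={"model": "equalflux"})


# ---------------------------------------------------------------------- #
# analytic decay scales
# ---------------------------------------------------------------------- #
def interaction_scales(S_mean: float,
                       spec: CapillarySpec,
                       tissue: TissueSpec,
                       resistances: ResistanceSet,
                       sol: Solubilities,
                       curve: OxyHbCurve,
                       r_t_mean: Optional[float] = None) -> tuple[float, float]:
    """Analytic decay length and time of the inter-capillary HS difference.

    L_CI = K_CI Q_O2(S_bar) (dP_eq/dS|_S_bar)^-1 and tau_CI = L_CI / v_rbc
    = K_CI (mu_LD pi r_c^2 C0 (dP_eq/dS)^-1 + pi r_p^2 alpha_eff); the RBC
    velocity cancels in tau_CI.  ``r_t_mean`` defaults to the tissue radius
    of ``tissue``.

    Returns ``(L_CI, tau_CI)`` in (um, s).
    """
    if not (0 < S_mean < 1):
        raise ValueError("mean saturation must lie in (0, 1)")
    if resistances.K_CI is not None:
        K_CI = resistances.K_CI
    else:
        r_t = r_t_mean if r_t_mean is not None else tissue.r_t_at(0.0)
        K_CI = k_ci(resistances.k_iv_at(spec.mu_LD), tissue.D_t,
                    tissue.alpha_t, r_t, spec.r_w)
    Q = convective_capacity(S_mean, spec, sol, curve)
    slope = curve.slope(S_mean)
    L_CI = K_CI * Q / slope
    return L_CI, L_CI / spec.v_rbc


def pair_conservation_error(profiles: PairProfiles,
                            state: CapillaryPairState) -> float:
    """Relative error of the pair's total oxygen balance.

    Compares the sum of the convective flux losses f(S_a) - f(S_v) of both
    capillaries (with the intravascular Po2 evaluated at the local outflux)
    against the integrated slice consumption.
    """
    from coshlib.params import total_convective_flux

    total = 0.0
    for S, j, spec, kiv in (
            (profiles.S_phi, profiles.jt_phi, state.spec_phi,
             state.k_iv_phi()),
            (profiles.S_psi, profiles.jt_psi, state.spec_psi,
             state.k_iv_psi())):
        f_a = total_convective_flux(S[0], spec, state.sol, state.curve,
                                    float(j[0]), kiv)
        f_v = total_convective_flux(S[-1], spec, state.sol, state.curve,
                                    float(j[-1]), kiv)
        total += float(f_a - f_v)
    consumed = state.total_consumption_per_length * state.L
    return abs(total - consumed) / consumed
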