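"""Vessel geometry, hemodynamics, solubilities and resistance coefficients.

Canonical internal unit system: micrometers, seconds, mmHg, and cubic
micrometers of (gaseous-equivalent) oxygen.  Literature values are usually
given in cgs units; the conversion helpers below are the single place where
units are changed.

Note that an oxygen solubility expressed in ml O2 mmHg^-1 cm^-3 is
numerically identical in um^3 O2 um^-3 mmHg^-1 (both are volume fractions
per mmHg), while diffusivities in cm^2/s scale by 1e8 to um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from coshlib.oxyhb import OxyHbCurve, hill_curve

# ---------------------------------------------------------------------- #
# unit conversions (round-trip exact)
# ---------------------------------------------------------------------- #
CM2_PER_S_TO_UM2_PER_S = 1.0e8

#: molar volume of an ideal gas at 0 degC, 1 atm (ml/mol)
V_MOL_STP = 22413.96


def diffusivity_to_um2_s(D_cgs: float) -> float:
    """Convert a diffusivity from cm^2/s to um^2/s."""
    return D_cgs * CM2_PER_S_TO_UM2_PER_S


def diffusivity_to_cgs(D_um: float) -> float:
    """Convert a diffusivity from um^2/s to cm^2/s (inverse round-trips exactly)."""
    return D_um / CM2_PER_S_TO_UM2_PER_S


def solubility_to_um3(alpha_cgs: float) -> float:
    """ml O2 mmHg^-1 cm^-3  ->  um^3 O2 um^-3 mmHg^-1 (numerically identical)."""
    return alpha_cgs * 1.0


def molar_volume_ideal_gas(T_celsius: float) -> float:
    """Ideal-gas molar volume at 1 atm in ml/mol for temperature in Celsius."""
    if T_celsius <= -273.15:
        raise ValueError("temperature below absolute zero")
    return V_MOL_STP * (T_celsius + 273.15) / 273.15


# ---------------------------------------------------------------------- #
# domain types
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Solubilities:
    """Region-wise oxygen solubilities and blood oxygen-binding capacity.

    Solubilities are in um^3 O2 um^-3 mmHg^-1.  ``n_hb`` is the heme density
    in mol/cm^3 and ``v_mol`` the oxygen molar volume in ml/mol; their
    product ``C0 = n_hb * v_mol`` (ml O2/cm^3 == um^3 O2/um^3) is the volume
    of oxygen bound per unit RBC volume at full saturation.
    """

    alpha_c: float = 3.38e-5   # RBC
    alpha_p: float = 2.82e-5   # plasma
    alpha_w: float = 3.89e-5   # capillary wall
    alpha_t: float = 3.89e-5   # tissue
    n_hb: float = 2.03e-5      # mol/cm^3
    v_mol: float = 2.544e4     # ml/mol

    def __post_init__(self):
        for name in ("alpha_c", "alpha_p", "alpha_w", "alpha_t", "n_hb", "v_mol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def C0(self) -> float:
        """Heme-bound O2 capacity, um^3 O2 per um^3 of RBC."""
        return self.n_hb * self.v_mol


@dataclass(frozen=True)
class CapillarySpec:
    """Capillary geometry and flow state.

    Radii in um (RBC radius ``r_c`` < lumen radius ``r_p`` < outer
    endothelium radius ``r_w``), RBC volume in um^3, RBC velocity in um/s,
    linear density ``mu_LD`` the fraction of vessel length occupied by RBCs,
    and domain length ``L`` in um.  The Fahraeus effect is neglected, so the
    discharge hematocrit equals the tube hematocrit.
    """

    r_c: float = 1.5
    r_p: float = 2.0
    r_w: float = 2.6
    V_rbc: float = 59.0
    v_rbc: float = 1000.0
    mu_LD: float = 0.3
    L: float = 100.0
    h_d: Optional[float] = None  # only accepted if equal to H_T

    def __post_init__(self):
        if not (0 < self.r_c <= self.r_p < self.r_w):
            raise ValueError("radii must satisfy 0 < r_c <= r_p < r_w")
        if self.V_rbc <= 0 or self.v_rbc <= 0 or self.L <= 0:
            raise ValueError("V_rbc, v_rbc and L must be positive")
        if not (0 < self.mu_LD < 1):
            raise ValueError("linear density must lie in (0, 1)")
        if not (0 < self.H_T < 1):
            raise ValueError("tube hematocrit outside (0, 1)")
        if self.h_d is not None and not math.isclose(self.h_d, self.H_T,
                                                     rel_tol=1e-12):
            raise ValueError("discharge hematocrit must equal tube hematocrit "
                             "(Fahraeus effect is neglected)")

    @property
    def H_T(self) -> float:
        """Tube hematocrit, mu_LD * (r_c/r_p)^2."""
        return self.mu_LD * (self.r_c / self.r_p) ** 2

    @property
    def H_D(self) -> float:
        """Discharge hematocrit; equal to the tube hematocrit here."""
        return self.H_T

    @property
    def L_rbc(self) -> float:
        """Length of the cylindrical model RBC, V_rbc / (pi r_c^2), um."""
        return self.V_rbc / (math.pi * self.r_c**2)

    @property
    def rbc_flux(self) -> float:
        """RBC flow v_rbc * mu_LD / L_rbc, cells per second."""
        return self.v_rbc * self.mu_LD / self.L_rbc


RadiusLike = Union[float, Callable[[float], float]]


@dataclass(frozen=True)
class TissueSpec:
    """Tissue cylinder supplied by a capillary.

    ``r_t`` is the tissue radius in um, either a constant or a callable of
    the axial position x.  ``M0`` is the oxygen consumption rate per unit
    tissue volume (um^3 O2 um^-3 s^-1), ``D_t`` the tissue oxygen diffusivity
    (um^2/s) and ``alpha_t`` the tissue solubility (um^3 O2 um^-3 mmHg^-1).
    """

    r_t: RadiusLike = 23.0
    M0: float = 1.0e-3
    D_t: float = 2.41e-5 * CM2_PER_S_TO_UM2_PER_S
    alpha_t: float = 3.89e-5

    def __post_init__(self):
        if self.M0 < 0:
            raise ValueError("M0 must be non-negative")
        if self.D_t <= 0 or self.alpha_t <= 0:
            raise ValueError("D_t and alpha_t must be positive")

    def r_t_at(self, x: float) -> float:
        return self.r_t(x) if callable(self.r_t) else float(self.r_t)

    def j_t(self, x: float, r_w: float) -> float:
        """Consumption per unit capillary length at x, um^3 O2 um^-1 s^-1."""
        return consumption_per_length(x, self, r_w)

    def djt_dx(self, x: float, r_w: float, h: float = 1e-3) -> float:
        """Axial derivative of j_t; zero for a constant tissue radius."""
        if not callable(self.r_t):
            return 0.0
        return (self.j_t(x + h, r_w) - self.j_t(x - h, r_w)) / (2 * h)


@dataclass(frozen=True)
class ResistanceSet:
    """Resistance coefficients, mmHg um s / um^3 O2.

    ``K_IV_half`` is the intravascular coefficient at linear density 0.5;
    the value at other densities follows K_IV = 0.5 * K_IV_half / mu_LD.
    ``K_OS`` is the extravascular (oscillation-spreading) contribution to
    the RBC-interaction coefficient K_RI = K_IV + K_OS; ``K_CI`` is the
    capillary-interaction coefficient.
    """

    K_IV_half: float = 5.15
    K_IV: Optional[float] = None
    K_OS: Optional[float] = None
    K_RI: Optional[float] = None
    K_CI: Optional[float] = None

    def __post_init__(self):
        for name in ("K_IV_half", "K_IV", "K_OS", "K_RI", "K_CI"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.K_RI is not None and self.K_IV is not None
                and self.K_OS is not None
                and not math.isclose(self.K_RI, self.K_IV + self.K_OS,
                                     rel_tol=1e-9)):
            raise ValueError("K_RI must equal K_IV + K_OS")
        if (self.K_CI is not None and self.K_IV is not None
                and self.K_CI < self.K_IV):
            raise ValueError("K_CI must be >= K_IV")

    def k_iv_at(self, mu_LD: float) -> float:
        """K_IV at a given linear density (explicit K_IV takes precedence)."""
        if self.K_IV is not None:
            return self.K_IV
        return k_iv(mu_LD, self.K_IV_half)


# ---------------------------------------------------------------------- #
# algebraic relations
# ---------------------------------------------------------------------- #
def tube_hematocrit(mu_LD: float, r_c: float, r_p: float) -> float:
    """Tube hematocrit H_T = mu_LD * (r_c/r_p)^2."""
    if not (0 < r_c <= r_p):
        raise ValueError("require 0 < r_c <= r_p")
    if not (0 < mu_LD < 1):
        raise ValueError("linear density must lie in (0, 1)")
    h = mu_LD * (r_c / r_p) ** 2
    if not (0 < h < 1):
        raise ValueError("tube hematocrit outside (0, 1)")
    return h


def linear_density(H_T: float, r_c: float, r_p: float) -> float:
    """Inverse of :func:`tube_hematocrit`: mu_LD = H_T * (r_p/r_c)^2."""
    if not (0 < r_c <= r_p):
        raise ValueError("require 0 < r_c <= r_p")
    mu = H_T * (r_p / r_c) ** 2
    if not (0 < mu < 1):
        raise ValueError("linear density outside (0, 1)")
    return mu


def rbc_length_and_flux(spec: CapillarySpec) -> tuple[float, float]:
    """Model RBC length (um) and RBC flow (cells/s) for a capillary."""
    return spec.L_rbc, spec.rbc_flux


def effective_solubility(H_T: float, sol: Solubilities) -> float:
    """alpha_eff = H_T alpha_c + (1 - H_T) alpha_p (um^3 O2 um^-3 mmHg^-1)."""
    if not (0 <= H_T <= 1):
        raise ValueError("H_T must lie in [0, 1]")
    return H_T * sol.alpha_c + (1 - H_T) * sol.alpha_p


def convective_capacity(S, spec: CapillarySpec, sol: Solubilities,
                        curve: OxyHbCurve):
    """Total oxygen convective capacity Q_O2(S).

    Q_O2 = v_rbc * (mu_LD pi r_c^2 C0 + pi r_p^2 alpha_eff dP_eq/dS),
    um^3 O2 s^-1 per unit saturation.  The first (hemoglobin) term dominates
    the dissolved term at physiologic parameters.
    """
    alpha_eff = effective_solubility(spec.H_T, sol)
    return spec.v_rbc * (spec.mu_LD * math.pi * spec.r_c**2 * sol.C0
                         + math.pi * spec.r_p**2 * alpha_eff * curve.slope(S))


def total_convective_flux(S, spec: CapillarySpec, sol: Solubilities,
                          curve: OxyHbCurve, j_t: float, K_IV: float):
    """Total convective oxygen flux f(S) through the capillary, um^3 O2/s.

    f = v_rbc (pi r_p^2 H_D C0 S + pi r_p^2 alpha_eff P_IV) with the
    intravascular Po2 P_IV = P_eq(S) - (1 - H_T) K_IV j_t.
    """
    alpha_eff = effective_solubility(spec.H_T, sol)
    P_eq = curve.po2(S)
    P_iv = P_eq - (1 - spec.H_T) * K_IV * j_t
    return spec.v_rbc * math.pi * spec.r_p**2 * (
        spec.H_D * sol.C0 * np.asarray(S, dtype=float) + alpha_eff * P_iv)


def k_iv(mu_LD: float, K_IV_half: float = 5.15) -> float:
    """Intravascular resistance coefficient K_IV = 0.5 K_IV_half / mu_LD."""
    if mu_LD <= 0:
        raise ValueError("linear density must be positive")
    return 0.5 * K_IV_half / mu_LD


def k_ci(K_IV: float, D_t: float, alpha_t: float, r_t_mean: float,
         r_w: float) -> float:
    """Capillary-interaction resistance coefficient.

    K_CI = K_IV + (1 / (2 pi D_t alpha_t)) * (ln(r_t_mean / r_w) - 1/2).

    For r_t_mean <= r_w * e^0.5 the extravascular term is non-positive;
    this is allowed (thin tissue sleeve) but unusual.
    """
    if r_t_mean <= r_w:
        raise ValueError("mean tissue radius must exceed the wall radius")
    extra = (math.log(r_t_mean / r_w) - 0.5) / (2 * math.pi * D_t * alpha_t)
    return K_IV + extra


def krogh_radius_from_spacing(d: float) -> float:
    """Equal-area Krogh cylinder radius for capillary spacing d: sqrt(d^2/pi)."""
    if d <= 0:
        raise ValueError("spacing must be positive")
    return d / math.sqrt(math.pi)


def consumption_per_length(x: float, tissue: TissueSpec, r_w: float) -> float:
    """Metabolic consumption in the tissue slice at x per unit length.

    j_t(x) = M0 pi (r_t(x)^2 - r_w^2), um^3 O2 um^-1 s^-1.
    """
    r_t = tissue.r_t_at(x)
    if r_t < r_w:
        raise ValueError("tissue radius must be at least the wall radius")
    return tissue.M0 * math.pi * (r_t**2 - r_w**2)


# ---------------------------------------------------------------------- #
# parameter presets
# ---------------------------------------------------------------------- #
def mouse_cortex_baseline(geometry: str = "single") -> dict:
    """Baseline mouse cerebral-cortex parameter set.

    ``geometry="single"`` is the single-capillary cylinder (r_c = 1.5 um,
    r_w = 2.6 um, r_t = 23 um); ``geometry="array"`` is the parallel
    capillary array (r_c = 1.6 um, r_w = 2.5 um, spacing 40 um, i.e.
    r_t_mean = 22.6 um by the equal-area rule).  Defaults: v_rbc = 1 mm/s,
    mu_LD = 0.3, M0 = 1e-3 um^3 O2 um^-3 s^-1, L = 100 um.

    Returns a dict with keys ``curve``, ``capillary``, ``tissue``, ``sol``,
    ``resistances`` and, for the array geometry, ``spacing``.
    """
    sol = Solubilities()
    curve = hill_curve()
    resistances = ResistanceSet()
    if geometry == "single":
        cap = CapillarySpec(r_c=1.5, r_p=2.0, r_w=2.6, L=100.0)
        tis = TissueSpec(r_t=23.0)
        return {"curve": curve, "capillary": cap, "tissue": tis,
                "sol": sol, "resistances": resistances}
    if geometry == "array":
        spacing = 40.0
        cap = CapillarySpec(r_c=1.6, r_p=2.0, r_w=2.5, L=100.0)
        tis = TissueSpec(r_t=krogh_radius_from_spacing(spacing))
        return {"curve": curve, "capillary": cap, "tissue": tis,
                "sol": sol, "resistances": resistances, "spacing": spacing}
    raise ValueError(f"unknown geometry {geometry!r}")
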