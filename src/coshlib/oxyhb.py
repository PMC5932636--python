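"""Oxy-hemoglobin equilibrium curves.

The equilibrium between oxygen partial pressure P (mmHg) and hemoglobin
saturation S is modeled either with the Hill equation

    S_eq(P) = P^n / (P^n + P50^n),       P_eq(S) = P50 * (S/(1-S))**(1/n),

or with the four-constant Adair equation

    S_eq(P) = (a1 P + 2 a2 P^2 + 3 a3 P^3 + 4 a4 P^4)
              / (4 * (1 + a1 P + a2 P^2 + a3 P^3 + a4 P^4)),

which is more accurate at low saturation.  The slope dP_eq/dS enters the
total oxygen convective capacity of blood and thereby every decay-scale
formula in this package, so it is exposed alongside the forward and inverse
maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

logger = logging.getLogger(__name__)

#: Saturation is clamped below this value to avoid the S -> 1 singularity of
#: the inverse curve.
S_MAX = 1.0 - 1e-12

#: Default Adair constants (units mmHg^-1, mmHg^-2, mmHg^-3, mmHg^-4).
#: Synthetic set obtained by least-squares adjustment of the four-constant
#: Adair form to the mouse Hill curve (n = 2.64, P50 = 47.9 mmHg) on
#: S in [0.05, 0.95]; it reproduces the Hill curve closely at mid
#: saturations while showing the characteristic Adair behavior (finite
#: initial slope) at low P.  Override via the ``oxyhb.adair_coeffs`` config
#: entry when measured constants for a specific species are available.
DEFAULT_ADAIR_COEFFS: Tuple[float, float, float, float] = (
    1.0000e-04,
    4.1876e-04,
    1.0000e-08,
    1.9025e-07,
)


def clamp_saturation(S):
    """Clamp saturation into [0, 1 - 1e-12]; log if clamping actually occurs.

    Used by integrators to keep trial states away from the P_eq singularity;
    genuine depletion is handled by their terminal events instead.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S > S_MAX) or np.any(S < 0.0):
        logger.debug("saturation clamped into [0, 1-1e-12]")
    return np.clip(S, 0.0, S_MAX)


@dataclass(frozen=True)
class OxyHbCurve:
    """Oxy-hemoglobin equilibrium curve (Hill or Adair).

    Parameters
    ----------
    kind : {"hill", "adair"}
        Functional form of the equilibrium curve.
    n : float
        Hill exponent (dimensionless). Retained for the Adair curve as the
        descriptive cooperativity of the underlying dataset.
    p50 : float
        Half-saturation oxygen partial pressure in mmHg.
    adair_coeffs : tuple of 4 floats, optional
        Adair constants (per-mmHg powers); only used for ``kind="adair"``.
    """

    kind: str = "hill"
    n: float = 2.64
    p50: float = 47.9
    adair_coeffs: Optional[Tuple[float, float, float, float]] = None

    def __post_init__(self):
        if self.kind not in ("hill", "adair"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not (self.n > 0 and self.p50 > 0):
            raise ValueError("Hill exponent and P50 must be positive")
        if self.kind == "adair":
            coeffs = self.adair_coeffs or DEFAULT_ADAIR_COEFFS
            coeffs = tuple(float(c) for c in coeffs)
            if len(coeffs) != 4 or any(c <= 0 for c in coeffs):
                raise ValueError("adair_coeffs must be four positive constants")
            object.__setattr__(self, "adair_coeffs", coeffs)

    # ------------------------------------------------------------------ #
    # forward map S_eq(P)
    # ------------------------------------------------------------------ #
    def saturation(self, P):
        """Equilibrium saturation S_eq(P) for oxygen partial pressure P >= 0."""
        P = np.asarray(P, dtype=float)
        if np.any(P < 0):
            raise ValueError("oxygen partial pressure must be non-negative")
        if self.kind == "hill":
            Pn = P ** self.n
            out = Pn / (Pn + self.p50 ** self.n)
        else:
            a1, a2, a3, a4 = self.adair_coeffs
            num = a1 * P + 2 * a2 * P**2 + 3 * a3 * P**3 + 4 * a4 * P**4
            den = 4.0 * (1.0 + a1 * P + a2 * P**2 + a3 * P**3 + a4 * P**4)
            out = num / den
        return out if out.ndim else float(out)

    # ------------------------------------------------------------------ #
    # inverse map P_eq(S)
    # ------------------------------------------------------------------ #
    def po2(self, S):
        """Equilibrium oxygen partial pressure P_eq(S), 0 <= S < 1 (mmHg)."""
        S_arr = np.asarray(S, dtype=float)
        if np.any(S_arr < 0) or np.any(S_arr >= 1):
            raise ValueError("saturation must lie in [0, 1)")
        if self.kind == "hill":
            out = self.p50 * (S_arr / (1.0 - S_arr)) ** (1.0 / self.n)
            return out if out.ndim else float(out)
        flat = np.atleast_1d(S_arr)
        out = np.array([self._adair_inverse(float(s)) for s in flat])
        return out.reshape(S_arr.shape) if S_arr.ndim else float(out[0])

    def _adair_inverse(self, s: float) -> float:
        if s == 0.0:
            return 0.0
        hi = 500.0
        # expand the bracket if needed; saturation is strictly increasing
        while self.saturation(hi) < s:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - unreachable for valid S
                raise RuntimeError("failed to bracket Adair inverse")
        return brentq(lambda p: self.saturation(p) - s, 0.0, hi,
                      xtol=1e-14, rtol=1e-12)

    # ------------------------------------------------------------------ #
    # slope dP_eq/dS
    # ------------------------------------------------------------------ #
    def slope(self, S):
        """Derivative dP_eq/dS at saturation S in (0, 1), in mmHg.

        For the Hill curve the analytic form P_eq(S) / (n S (1-S)) is used.
        For the Adair curve the slope is 1 / S_eq'(P) evaluated at
        P = P_eq(S), with S_eq'(P) differentiated analytically.
        """
        S_arr = np.asarray(S, dtype=float)
        if np.any(S_arr <= 0) or np.any(S_arr >= 1):
            raise ValueError("slope is defined for saturation in (0, 1)")
        if self.kind == "hill":
            out = self.p50 * (S_arr / (1.0 - S_arr)) ** (1.0 / self.n) / (
                self.n * S_arr * (1.0 - S_arr))
            return out if out.ndim else float(out)
        P = np.atleast_1d(self.po2(S_arr))
        out = 1.0 / self._adair_dSdP(P)
        return out.reshape(S_arr.shape) if S_arr.ndim else float(out[0])

    def _adair_dSdP(self, P):
        a1, a2, a3, a4 = self.adair_coeffs
        num = a1 * P + 2 * a2 * P**2 + 3 * a3 * P**3 + 4 * a4 * P**4
        dnum = a1 + 4 * a2 * P + 9 * a3 * P**2 + 16 * a4 * P**3
        den = 1.0 + a1 * P + a2 * P**2 + a3 * P**3 + a4 * P**4
        dden = a1 + 2 * a2 * P + 3 * a3 * P**2 + 4 * a4 * P**3
        return (dnum * den - num * dden) / (4.0 * den**2)

    def slope_minimizer(self) -> float:
        """Saturation at which dP_eq/dS is minimal.

        For the Hill curve the closed form (1 - 1/n)/2 holds; cooperativity
        n <= 1 degenerates to the infimum at S -> 0, reported as 0.0.  For
        the Adair curve a bounded scalar search is used.
        """
        if self.kind == "hill":
            return max(0.0, 0.5 * (1.0 - 1.0 / self.n))
        res = minimize_scalar(lambda s: self.slope(s), bounds=(1e-4, 0.99),
                              method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x)


def hill_curve(n: float = 2.64, p50: float = 47.9) -> OxyHbCurve:
    """Convenience constructor for a Hill equilibrium curve."""
    return OxyHbCurve(kind="hill", n=n, p50=p50)


def adair_curve(coeffs: Optional[Iterable[float]] = None,
                n: float = 2.64, p50: float = 47.9) -> OxyHbCurve:
    """Convenience constructor for an Adair equilibrium curve."""
    coeffs = tuple(coeffs) if coeffs is not None else None
    return OxyHbCurve(kind="adair", n=n, p50=p50, adair_coeffs=coeffs)


# ---------------------------------------------------------------------- #
# module-level functional API
# ---------------------------------------------------------------------- #
def saturation_from_po2(curve: OxyHbCurve, P):
    """S_eq(P); see :meth:`OxyHbCurve.saturation`."""
    return curve.saturation(P)


def po2_from_saturation(curve: OxyHbCurve, S):
    """P_eq(S); see :meth:`OxyHbCurve.po2`."""
    return curve.po2(S)


def slope_dpeq_ds(curve: OxyHbCurve, S):
    """dP_eq/dS; see :meth:`OxyHbCurve.slope`."""
    return curve.slope(S)


def slope_minimizer(curve: OxyHbCurve) -> float:
    """Saturation minimizing dP_eq/dS; see :meth:`OxyHbCurve.slope_minimizer`."""
    return curve.slope_minimizer()
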