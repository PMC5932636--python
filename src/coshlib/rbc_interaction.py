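"""Diffusive interaction between RBCs within a single capillary.

Downstream of a converging bifurcation, RBCs enter a capillary with
different saturations.  Oxygen exchange through the shared tissue couples
them: a cell above the ensemble-mean saturation unloads faster, one below
unloads slower.  Treating the saturation as a random variable S with
ensemble mean S_bar, the model equation per RBC class is

    Q_O2(S) dS/dx = -j_t(x) - (1/K_RI) * (P_eq(S) - mean_w[P_eq(S)]),

with the RBC-interaction resistance coefficient K_RI as single parameter.
Linearizing P_eq about S_bar yields an equation for the standard deviation,

    Q_O2(S_bar) d(sigma_S)/dx = -(sigma_S / K_RI) * dP_eq/dS|_S_bar,

whose solution is near-exponential; the decay length L_RI and time scale
tau_RI = L_RI / v_rbc are obtained by a log-linear exponential fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from coshlib.oxyhb import OxyHbCurve
from coshlib.params import (
    CapillarySpec,
    Solubilities,
    TissueSpec,
    consumption_per_length,
    convective_capacity,
)
from coshlib.mean_saturation import (
    S_DEPLETED,
    SaturationDepletionError,
)


# ---------------------------------------------------------------------- #
# ensembles
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SaturationEnsemble:
    """Finite weighted ensemble of RBC saturation classes.

    ``values`` are the per-class saturations in (0, 1); ``weights`` are the
    RBC-flow fractions of each class (non-negative, summing to one; equal
    weights by default).
    """

    values: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("saturation values must lie in (0, 1)")
        if self.weights is None:
            w = np.full(v.size, 1.0 / v.size)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != v.shape or np.any(w < 0):
                raise ValueError("weights must be non-negative, same shape")
            total = w.sum()
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("weights must sum to 1")
            w = w / total
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @property
    def mean(self) -> float:
        return float(self.weights @ self.values)

    @property
    def sigma(self) -> float:
        m = self.mean
        return float(math.sqrt(self.weights @ (self.values - m) ** 2))


def converging_bifurcation_mix(parents: Sequence[SaturationEnsemble],
                               rbc_flows: Sequence[float]) -> SaturationEnsemble:
    """Mix parent-branch ensembles at a converging bifurcation.

    Parent ensembles are concatenated with weights scaled by the RBC-flow
    fraction of each branch, so the mixed mean equals the RBC-flow-weighted
    average of the parent means exactly.
    """
    flows = np.asarray(rbc_flows, dtype=float)
    if flows.size != len(parents) or np.any(flows <= 0):
        raise ValueError("one positive RBC flow per parent branch required")
    fracs = flows / flows.sum()
    values = np.concatenate([p.values for p in parents])
    weights = np.concatenate([f * p.weights for f, p in zip(fracs, parents)])
    return SaturationEnsemble(values=values, weights=weights)


@dataclass(frozen=True)
class EnsembleProfile:
    """Axial evolution of a saturation ensemble: values[i, j] is class j at x[i]."""

    x: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    v_rbc: float
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.values @ self.weights

    @property
    def sigma(self) -> np.ndarray:
        m = self.mean
        return np.sqrt(((self.values - m[:, None]) ** 2) @ self.weights)

    def ensemble_at_outlet(self) -> SaturationEnsemble:
        return SaturationEnsemble(values=self.values[-1], weights=self.weights)


@dataclass(frozen=True)
class SigmaProfile:
    """Mean saturation and its standard deviation along the capillary."""

    x: np.ndarray
    S_mean: np.ndarray
    sigma: np.ndarray
    v_rbc: float
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# integrators
# ---------------------------------------------------------------------- #
def _check_events(res):
    if res.t_events and res.t_events[0].size:
        raise SaturationDepletionError(float(res.t_events[0][0]), "depleted")
    if len(res.t_events) > 1 and res.t_events[1].size:
        raise SaturationDepletionError(float(res.t_events[1][0]), "saturated")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"integration failed: {res.message}")


def integrate_ensemble_nonlinear(ens_a: SaturationEnsemble,
                                 K_RI: float,
                                 spec: CapillarySpec,
                                 tissue: TissueSpec,
                                 sol: Solubilities,
                                 curve: OxyHbCurve,
                                 rtol: float = 1e-8,
                                 atol: float = 1e-10,
                                 dx_out: float = 1.0) -> EnsembleProfile:
    """Co-integrate the nonlinear interaction ODE for every RBC class.

    ``K_RI`` may be ``numpy.inf`` to switch interaction off, in which case
    each class follows its own mean-saturation ODE independently.
    """
    if not (K_RI > 0):
        raise ValueError("K_RI must be positive (use inf for no interaction)")
    w = ens_a.weights
    inv_kri = 0.0 if math.isinf(K_RI) else 1.0 / K_RI

    def rhs(x, y):
        S = np.clip(y, S_DEPLETED, 1.0 - S_DEPLETED)
        jt = consumption_per_length(x, tissue, spec.r_w)
        Peq = curve.po2(S)
        Peq_bar = w @ Peq
        Q = convective_capacity(S, spec, sol, curve)
        return (-jt - inv_kri * (Peq - Peq_bar)) / Q

    def depleted(x, y):
        return np.min(y) - S_DEPLETED

    def saturated(x, y):
        return (1.0 - S_DEPLETED) - np.max(y)

    depleted.terminal = True
    saturated.terminal = True

    res = solve_ivp(rhs, (0.0, spec.L), ens_a.values, method="RK45",
                    rtol=rtol, atol=atol, dense_output=True,
                    events=[depleted, saturated])
    _check_events(res)
    x = np.arange(0.0, spec.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], spec.L)
    values = res.sol(x).T
    return EnsembleProfile(x=x, values=values, weights=w, v_rbc=spec.v_rbc,
                           metadata={"K_RI": K_RI, "rtol": rtol, "atol": atol})


def integrate_sigma_linearized(S_a_mean: float,
                               sigma_a: float,
                               K_RI: float,
                               spec: CapillarySpec,
                               tissue: TissueSpec,
                               sol: Solubilities,
                               curve: OxyHbCurve,
                               rtol: float = 1e-8,
                               atol: float = 1e-10,
                               dx_out: float = 1.0) -> SigmaProfile:
    """Co-integrate the mean-saturation ODE and the linearized sigma_S ODE."""
    if sigma_a < 0:
        raise ValueError("inlet standard deviation must be non-negative")
    if not (K_RI > 0):
        raise ValueError("K_RI must be positive (use inf for no interaction)")
    inv_kri = 0.0 if math.isinf(K_RI) else 1.0 / K_RI

    def rhs(x, y):
        S = min(max(y[0], S_DEPLETED), 1.0 - S_DEPLETED)
        sigma = y[1]
        jt = consumption_per_length(x, tissue, spec.r_w)
        Q = convective_capacity(S, spec, sol, curve)
        dS = -jt / Q
        dsigma = -sigma * inv_kri * curve.slope(S) / Q
        return [dS, dsigma]

    def depleted(x, y):
        return y[0] - S_DEPLETED

    def saturated(x, y):
        return (1.0 - S_DEPLETED) - y[0]

    depleted.terminal = True
    saturated.terminal = True

    res = solve_ivp(rhs, (0.0, spec.L), [S_a_mean, sigma_a], method="RK45",
                    rtol=rtol, atol=atol, dense_output=True,
                    events=[depleted, saturated])
    _check_events(res)
    x = np.arange(0.0, spec.L + 0.5 * dx_out, dx_out)
    x[-1] = min(x[-1], spec.L)
    S_mean, sigma = res.sol(x)
    return SigmaProfile(x=x, S_mean=S_mean, sigma=sigma, v_rbc=spec.v_rbc,
                        metadata={"K_RI": K_RI})


# ---------------------------------------------------------------------- #
# decay-scale fitting
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class ExponentialFit:
    """Result of a log-linear single-exponential fit y = a exp(-x / L)."""

    L_decay: float          # decay length, um (positive magnitude)
    amplitude: float        # fitted a
    r_squared: float        # of the log-linear fit
    slope: float            # signed slope of ln y vs x (1/um)
    tau_decay: Optional[float] = None   # L_decay / v_rbc if velocity given


def fit_exponential_decay(x, y, v_rbc: Optional[float] = None) -> ExponentialFit:
    """Fit a single exponential to y(x) by least squares on ln y.

    The decay length is reported as a positive magnitude; with ``v_rbc``
    given, the decay time tau = L / v_rbc is reported as well.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-d arrays of equal length >= 2")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires strictly positive y")
    slope, logc = np.polyfit(x, np.log(y), 1)
    resid = np.log(y) - (slope * x + logc)
    ss_tot = np.sum((np.log(y) - np.log(y).mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    L = math.inf if slope == 0 else 1.0 / abs(slope)
    tau = None if v_rbc is None else L / v_rbc
    return ExponentialFit(L_decay=L, amplitude=float(np.exp(logc)),
                          r_squared=float(r2), slope=float(slope),
                          tau_decay=tau)


def fit_kri(x_ref,
            sigma_ref,
            spec: CapillarySpec,
            tissue: TissueSpec,
            sol: Solubilities,
            curve: OxyHbCurve,
            S_a_mean: float,
            bounds: tuple[float, float] = (0.5, 200.0),
            model: str = "linearized",
            ens_a: Optional[SaturationEnsemble] = None,
            rel_tol: float = 1e-3) -> float:
    """Fit K_RI by minimizing the integrated squared sigma_S model error.

    The objective is the integral over x of (sigma_model - sigma_ref)^2,
    evaluated on the reference grid by the trapezoidal rule.  The default
    comparison model is the (cheap) linearized sigma_S equation; the
    nonlinear ensemble model is selectable via ``model="nonlinear"`` with a
    matching inlet ensemble.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if model not in ("linearized", "nonlinear"):
        raise ValueError("model must be 'linearized' or 'nonlinear'")
    if model == "nonlinear" and ens_a is None:
        raise ValueError("nonlinear fitting requires an inlet ensemble")
    sigma_a = float(sigma_ref[0])

    def objective(kri):
        if model == "linearized":
            prof = integrate_sigma_linearized(S_a_mean, sigma_a, kri, spec,
                                              tissue, sol, curve,
                                              rtol=1e-7, atol=1e-10)
            sig = np.interp(x_ref, prof.x, prof.sigma)
        else:
            prof = integrate_ensemble_nonlinear(ens_a, kri, spec, tissue,
                                                sol, curve,
                                                rtol=1e-7, atol=1e-10)
            sig = np.interp(x_ref, prof.x, prof.sigma)
        return np.trapezoid((sig - sigma_ref) ** 2, x_ref)

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": rel_tol * bounds[0]})
    kri = float(res.x)
    span = bounds[1] - bounds[0]
    if kri - bounds[0] < 1e-2 * span or bounds[1] - kri < 1e-2 * span:
        warnings.warn("fitted K_RI is at a search bound; the reference "
                      "profile may show no (or too slow) decay",
                      RuntimeWarning)
    return kri


# ---------------------------------------------------------------------- #
# Po2 oscillation spreading
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class OscillationProfile:
    """Radial envelope of tissue Po2 fluctuations caused by passing RBCs.

    ``r`` starts at the capillary wall radius r_w; ``delta_P`` is the
    peak-to-trough Po2 fluctuation amplitude at each radius (mmHg).
    """

    r: np.ndarray
    delta_P: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        dP = np.asarray(self.delta_P, dtype=float)
        if r.shape != dP.shape or r.ndim != 1 or r.size < 2:
            raise ValueError("r and delta_P must be 1-d arrays, length >= 2")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r must be strictly increasing")
        if np.any(dP < 0):
            raise ValueError("fluctuation amplitudes must be non-negative")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "delta_P", dP)

    @property
    def r_w(self) -> float:
        return float(self.r[0])

    @property
    def delta_P_max(self) -> float:
        return float(self.delta_P[0])


def oscillation_spreading(profile: OscillationProfile,
                          cylindrical: bool = True) -> tuple[float, float]:
    """Penetration radius and integral spreading distance of Po2 oscillations.

    Equates the cylindrical-shell integral of a rectangle of amplitude
    delta_P_max between r_w and r_osc with that of the actual envelope:

        pi (r_osc^2 - r_w^2) delta_P_max = 2 pi * integral r delta_P dr,

    so that a constant envelope on [r_w, r_t] yields r_osc = r_t.  With
    ``cylindrical=False`` the right-hand side is the plain integral of
    r*delta_P without the factor 2 pi (the literal planar convention).
    Returns ``(r_osc, delta_r_osc)`` with delta_r_osc = r_osc - r_w.
    """
    if profile.delta_P_max <= 0:
        raise ValueError("delta_P_max must be positive")
    integral = np.trapezoid(profile.r * profile.delta_P, profile.r)
    factor = 2.0 if cylindrical else 1.0 / math.pi
    r_osc = math.sqrt(profile.r_w**2 + factor * integral / profile.delta_P_max)
    return r_osc, r_osc - profile.r_w


def kos_from_spreading(delta_r_osc: float, slope: float = 1.49,
                       intercept: float = -3.58) -> float:
    """Empirical K_OS estimate from the oscillation spreading distance.

    Linear estimator K_OS = slope * delta_r_osc + intercept (clamped at 0),
    calibrated against simulations where K_OS and delta_r_osc are strongly
    correlated.  This is an empirical estimator, not an exact relation.
    """
    if delta_r_osc < 0:
        raise ValueError("spreading distance must be non-negative")
    return max(0.0, slope * delta_r_osc + intercept)
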