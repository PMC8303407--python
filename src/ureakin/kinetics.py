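"""Volume kinetics, the time transformation, and the characteristic roots.

During dialysis the compartment volumes shrink linearly,

    Vex(t) = Vex(0) - (omega_f - omega_pl) t,
    Vin(t) = Vin(0) - omega_pl t,

and the mass balances for the average concentrations are

    Vex(t) dCex/dt = -Ah (Cex - Cin) + omega_pl Cin
                     + (omega_f - omega_pl) Cex - K Cex,
    Vin(t) dCin/dt =  Ah (Cex - Cin) + S.

The substitution dt* = dt / Vex(t) turns this variable-coefficient system
into a constant-coefficient one; eliminating Cin gives the second-order ODE

    alpha C'' + beta C' + gamma C = S     (derivatives w.r.t. t*),

whose characteristic roots lambda1 >= lambda2 drive the closed-form
solutions in :mod:`ureakin.analytic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateClearanceError,
    InfeasibleTreatmentError,
    InvalidArgumentError,
    ModelAssumptionError,
    TimeDomainError,
    UnsupportedRegimeError,
)
from .parameters import PatientParameters, TreatmentParameters

# Absolute clamp (mL/min) for float round-off in eps*Vin0 - Vex0.
_OMEGA_TOL = 1e-9


def plasma_refilling_rate(
    v_ex0: float,
    v_in0: float,
    eps: float,
    omega_f: float,
    t_eval: float,
) -> float:
    """Plasma-refilling rate (mL/min) implied by the constant volume ratio.

    omega_pl = {eps Vin(0) - [Vex(0) - omega_f t]} / [(1 + eps) t]

    When ``eps`` equals ``v_ex0 / v_in0`` exactly this reduces to
    ``omega_f / (1 + eps)``, independent of ``t_eval``; a rounded ``eps``
    introduces a small t-dependence.
    """
    if t_eval <= 0:
        raise InvalidArgumentError(f"t_eval must be positive, got {t_eval}")
    if omega_f < 0:
        raise InvalidArgumentError(f"omega_f must be non-negative, got {omega_f}")
    omega_pl = (eps * v_in0 - (v_ex0 - omega_f * t_eval)) / ((1.0 + eps) * t_eval)
    if abs(omega_pl) < _OMEGA_TOL:
        omega_pl = 0.0
    if omega_pl < 0:
        raise ModelAssumptionError(
            f"estimated omega_pl = {omega_pl:.6g} mL/min is negative"
        )
    if omega_f > 0 and omega_pl >= omega_f:
        raise ModelAssumptionError(
            f"estimated omega_pl = {omega_pl:.6g} mL/min is not below "
            f"omega_f = {omega_f:.6g} mL/min"
        )
    if omega_f == 0 and omega_pl > _OMEGA_TOL:
        raise ModelAssumptionError(
            "positive refilling estimated without ultrafiltration"
        )
    return omega_pl


def resolve_treatment(
    patient: PatientParameters, treat: TreatmentParameters
) -> TreatmentParameters:
    """Return ``treat`` with ``omega_pl`` filled in.

    A ``None`` refilling rate is estimated once from the constant-ratio
    relation at ``t_eval = t_end`` and treated as a constant thereafter;
    an explicit value is passed through untouched (user override).
    """
    if treat.omega_pl is not None:
        return treat
    omega_pl = plasma_refilling_rate(
        patient.v_ex0, patient.v_in0, patient.eps, treat.omega_f, treat.t_end
    )
    return treat.model_copy(update={"omega_pl": omega_pl})


def _require_resolved(treat: TreatmentParameters) -> float:
    if treat.omega_pl is None:
        raise InvalidArgumentError(
            "omega_pl is unresolved; call resolve_treatment() first"
        )
    return treat.omega_pl


def compartment_volumes(t, patient: PatientParameters, treat: TreatmentParameters):
    """Compartment volumes (Vex(t), Vin(t)) in mL; ``t`` scalar or array.

    Raises :class:`InfeasibleTreatmentError` if either volume is
    non-positive anywhere on the requested times.
    """
    omega_pl = _require_resolved(treat)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > treat.t_end):
        raise TimeDomainError("t must lie in [0, t_end] during dialysis")
    v_ex = patient.v_ex0 - (treat.omega_f - omega_pl) * t_arr
    v_in = patient.v_in0 - omega_pl * t_arr
    if np.any(v_ex <= 0) or np.any(v_in <= 0):
        raise InfeasibleTreatmentError(
            "ultrafiltration exceeds available fluid: a compartment volume "
            "reaches zero before t_end"
        )
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(v_ex), float(v_in)
    return v_ex, v_in


def transformed_time(t, patient: PatientParameters, treat: TreatmentParameters):
    """Map physical time t to the transformed time t* with dt* = dt/Vex(t).

    t* = -ln[1 - (omega_f - omega_pl) t / Vex(0)] / (omega_f - omega_pl),
    with the analytic limit t* = t / Vex(0) when omega_f = omega_pl
    (constant extracellular volume).
    """
    omega_pl = _require_resolved(treat)
    net = treat.omega_f - omega_pl
    t_arr = np.asarray(t, dtype=float)
    x = net * t_arr / patient.v_ex0
    if np.any(1.0 - x <= 0):
        raise TimeDomainError(
            "t beyond the extracellular collapse time Vex(0)/(omega_f - omega_pl)"
        )
    if net == 0.0:
        ts = t_arr / patient.v_ex0
    else:
        ts = -np.log1p(-x) / net
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(ts)
    return ts


def physical_time(ts, patient: PatientParameters, treat: TreatmentParameters):
    """Inverse of :func:`transformed_time`."""
    omega_pl = _require_resolved(treat)
    net = treat.omega_f - omega_pl
    ts_arr = np.asarray(ts, dtype=float)
    if net == 0.0:
        t = ts_arr * patient.v_ex0
    else:
        t = -patient.v_ex0 * np.expm1(-net * ts_arr) / net
    if np.isscalar(ts) or np.ndim(ts) == 0:
        return float(t)
    return t


@dataclass(frozen=True)
class OdeCoefficients:
    """Coefficients and characteristic roots of the transformed-time ODE.

    ``alpha C'' + beta C' + gamma C = S`` with roots labelled
    ``lambda1 >= lambda2`` (mL/min). Vieta:
    ``lambda1 + lambda2 = beta/alpha``, ``lambda1 * lambda2 = gamma/alpha``.
    """

    alpha: float
    beta: float
    gamma: float
    lambda1: float
    lambda2: float


def ode_coefficients(
    patient: PatientParameters, treat: TreatmentParameters
) -> OdeCoefficients:
    """Coefficients alpha, beta, gamma and roots lambda1 >= lambda2.

    alpha = 1 / [eps (Ah + omega_pl)]
    beta  = [(1 + eps) Ah + K - omega_f + omega_pl] / [eps (Ah + omega_pl)]
    gamma = Ah (K - omega_f) / (Ah + omega_pl)

    Raises :class:`DegenerateClearanceError` when K = omega_f (gamma = 0)
    and :class:`UnsupportedRegimeError` when the discriminant is
    non-positive (the repeated/complex-root branch is not covered by the
    closed forms).
    """
    omega_pl = _require_resolved(treat)
    ah, eps = patient.ah, patient.eps
    k, omega_f = treat.k_clear, treat.omega_f
    if k == omega_f:
        raise DegenerateClearanceError(
            "K equals omega_f: gamma = 0 leaves the particular solution "
            "S/gamma undefined"
        )
    denom = ah + omega_pl
    alpha = 1.0 / (eps * denom)
    beta = ((1.0 + eps) * ah + k - omega_f + omega_pl) / (eps * denom)
    gamma = ah * (k - omega_f) / denom
    disc = beta * beta - 4.0 * alpha * gamma
    if disc <= 0:
        raise UnsupportedRegimeError(
            "repeated or complex characteristic root; only the distinct-"
            "real-root regime is supported"
        )
    sq = math.sqrt(disc)
    lambda1 = (beta + sq) / (2.0 * alpha)
    lambda2 = (beta - sq) / (2.0 * alpha)
    return OdeCoefficients(alpha, beta, gamma, lambda1, lambda2)
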