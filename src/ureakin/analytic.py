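"""Closed-form concentration solutions during and after dialysis.

During dialysis (0 <= t <= T), with B(t) = 1 - (omega_f - omega_pl) t / Vex(0):

    Cex(t) = C1 B^(l1/w) + C2 B^(l2/w) + S/gamma,        w = omega_f - omega_pl
    Cin(t) = w1 C1 B^(l1/w) + w2 C2 B^(l2/w) + wp S/gamma

with mode weights w_i = (Ah + K - omega_f + omega_pl - lambda_i)/(Ah + omega_pl)
and wp the same expression without the root. The integration constants C1, C2
follow from the equal initial concentrations Cex(0) = Cin(0) = Cs.

After dialysis (t >= T) the volumes are frozen at their end-of-dialysis
values and the re-equilibration (rebound) is a single exponential,

    Cex(t) = C3 exp(-lambda3 t) + C4 + S t / (Vex(T) + Vin(T)),
    lambda3 = Ah (Vex(T) + Vin(T)) / (Vex(T) Vin(T)),

with C3, C4 fixed by continuity of both concentrations at t = T.

Internally B^(lambda/w) is evaluated as exp(-lambda t*) with the transformed
time t* (log-space; silent underflow to 0 is fine — the fast mode decays
within minutes), which also covers the omega_f = omega_pl limit. The post
phase is evaluated around t = T (exp(-lambda3 (t - T))) so that large Ah
cannot overflow; the verbatim absolute-time constant C3 is still exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TimeDomainError
from .kinetics import (
    OdeCoefficients,
    compartment_volumes,
    ode_coefficients,
    resolve_treatment,
    transformed_time,
)
from .parameters import MGDL_PER_MGML, PatientParameters, TreatmentParameters

__all__ = [
    "DuringConstants",
    "PostConstants",
    "ConcentrationSeries",
    "during_constants",
    "concentration_during",
    "post_constants",
    "concentration_post",
    "simulate_timeline",
]


@dataclass(frozen=True)
class DuringConstants:
    """Integration constants of the during-dialysis solution (mg/mL).

    ``c1 + c2 + particular`` equals the initial concentration Cs.
    """

    c1: float
    c2: float
    particular: float  # S/gamma


@dataclass(frozen=True)
class PostConstants:
    """State and constants of the post-dialysis (rebound) solution.

    Concentrations in mg/mL, volumes in mL, ``lambda3`` in 1/min.
    ``c3`` is the absolute-time constant; ``c3_shifted = c3 exp(-lambda3 T)``
    is the overflow-safe form actually used for evaluation.
    """

    lambda3: float
    c3: float
    c4: float
    v_ex_T: float
    v_in_T: float
    c_ex_T: float
    c_in_T: float
    t_end: float
    c3_shifted: float


@dataclass
class ConcentrationSeries:
    """A two-phase concentration timeline on an explicit time grid.

    Concentrations in mg/dL, volumes in mL; ``phase`` is ``"during"`` for
    t <= T and ``"post"`` beyond.
    """

    times: np.ndarray
    phase: np.ndarray
    c_ex: np.ndarray
    c_in: np.ndarray
    v_ex: np.ndarray
    v_in: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "phase": self.phase,
                "c_ex_mg_dl": self.c_ex,
                "c_in_mg_dl": self.c_in,
                "v_ex_ml": self.v_ex,
                "v_in_ml": self.v_in,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mode_weights(patient, treat, coeffs):
    base = patient.ah + treat.k_clear - treat.omega_f + treat.omega_pl
    denom = patient.ah + treat.omega_pl
    return (
        (base - coeffs.lambda1) / denom,
        (base - coeffs.lambda2) / denom,
        base / denom,
    )


def during_constants(
    patient: PatientParameters,
    treat: TreatmentParameters,
    coeffs: OdeCoefficients | None = None,
) -> DuringConstants:
    """Integration constants C1, C2 from Cex(0) = Cin(0) = Cs.

    C1 = [Ah(K-wf)(-K+wf+l2) Cs - l2 (Ah+wpl) S] / [Ah(K-wf)(l2-l1)],
    C2 the same with l1 in place of l2 and an overall sign flip.
    """
    treat = resolve_treatment(patient, treat)
    if coeffs is None:
        coeffs = ode_coefficients(patient, treat)
    ah = patient.ah
    k, wf, wpl = treat.k_clear, treat.omega_f, treat.omega_pl
    l1, l2 = coeffs.lambda1, coeffs.lambda2
    cs = patient.c_s_mgml
    s = patient.s_prod
    denom = ah * (k - wf) * (l2 - l1)
    c1 = (ah * (k - wf) * (-k + wf + l2) * cs - l2 * (ah + wpl) * s) / denom
    c2 = -(ah * (k - wf) * (-k + wf + l1) * cs - l1 * (ah + wpl) * s) / denom
    return DuringConstants(c1=c1, c2=c2, particular=s / coeffs.gamma)


def concentration_during(
    t,
    patient: PatientParameters,
    treat: TreatmentParameters,
    coeffs: OdeCoefficients | None = None,
    consts: DuringConstants | None = None,
):
    """(Cex, Cin) in mg/dL at time(s) ``t`` during dialysis, 0 <= t <= T."""
    treat = resolve_treatment(patient, treat)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > treat.t_end):
        raise TimeDomainError("during-phase times must lie in [0, t_end]")
    if coeffs is None:
        coeffs = ode_coefficients(patient, treat)
    if consts is None:
        consts = during_constants(patient, treat, coeffs)
    ts = transformed_time(t_arr, patient, treat)
    e1 = np.exp(-coeffs.lambda1 * np.asarray(ts))
    e2 = np.exp(-coeffs.lambda2 * np.asarray(ts))
    w1, w2, wp = _mode_weights(patient, treat, coeffs)
    c_ex = consts.c1 * e1 + consts.c2 * e2 + consts.particular
    c_in = w1 * consts.c1 * e1 + w2 * consts.c2 * e2 + wp * consts.particular
    c_ex = c_ex * MGDL_PER_MGML
    c_in = c_in * MGDL_PER_MGML
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(c_ex), float(c_in)
    return c_ex, c_in


def post_constants(
    patient: PatientParameters,
    treat: TreatmentParameters,
    end_state: tuple[float, float] | None = None,
    coeffs: OdeCoefficients | None = None,
    consts: DuringConstants | None = None,
) -> PostConstants:
    """Constants of the rebound solution from the end-of-dialysis state.

    ``end_state`` is (Cex(T), Cin(T)) in mg/dL; when omitted it is taken
    from the during-dialysis closed form, which is the continuity
    condition at t = T.
    """
    treat = resolve_treatment(patient, treat)
    v_ex_T, v_in_T = compartment_volumes(treat.t_end, patient, treat)
    if end_state is None:
        end_state = concentration_during(treat.t_end, patient, treat, coeffs, consts)
    c_ex_T = end_state[0] / MGDL_PER_MGML
    c_in_T = end_state[1] / MGDL_PER_MGML
    ah, s = patient.ah, patient.s_prod
    v_tot = v_ex_T + v_in_T
    lambda3 = ah * v_tot / (v_ex_T * v_in_T)
    c3_shifted = -((c_in_T - c_ex_T) * ah / v_ex_T - s / v_tot) / lambda3
    with np.errstate(over="ignore"):
        c3 = float(c3_shifted * np.exp(lambda3 * treat.t_end))
    c4 = (
        c_ex_T
        + (c_in_T - c_ex_T) * ah / (v_ex_T * lambda3)
        - (s / v_tot) * (1.0 / lambda3 + treat.t_end)
    )
    return PostConstants(
        lambda3=lambda3,
        c3=c3,
        c4=c4,
        v_ex_T=v_ex_T,
        v_in_T=v_in_T,
        c_ex_T=c_ex_T,
        c_in_T=c_in_T,
        t_end=treat.t_end,
        c3_shifted=c3_shifted,
    )


def concentration_post(t, post: PostConstants, patient: PatientParameters):
    """(Cex, Cin) in mg/dL at time(s) ``t >= T`` after dialysis."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < post.t_end):
        raise TimeDomainError("post-phase times must satisfy t >= t_end")
    ah, s = patient.ah, patient.s_prod
    v_tot = post.v_ex_T + post.v_in_T
    decay = post.c3_shifted * np.exp(-post.lambda3 * (t_arr - post.t_end))
    drift = s * t_arr / v_tot
    c_ex = decay + post.c4 + drift
    c_in = (
        (1.0 - post.v_ex_T * post.lambda3 / ah) * decay
        + post.c4
        + (s / v_tot) * (t_arr + post.v_ex_T / ah)
    )
    c_ex = c_ex * MGDL_PER_MGML
    c_in = c_in * MGDL_PER_MGML
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(c_ex), float(c_in)
    return c_ex, c_in


def simulate_timeline(
    patient: PatientParameters,
    treat: TreatmentParameters,
    grid,
) -> ConcentrationSeries:
    """Evaluate the two-phase closed-form solution on a time grid.

    Times up to and including T use the during-dialysis solution; later
    times use the rebound solution seeded with the end-of-dialysis state
    (continuity handoff). Volumes are the linear during-dialysis kinetics,
    frozen at Vex(T), Vin(T) afterwards.
    """
    treat = resolve_treatment(patient, treat)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-d array of times")
    if np.any(grid < 0):
        raise TimeDomainError("grid times must be non-negative")

    coeffs = ode_coefficients(patient, treat)
    consts = during_constants(patient, treat, coeffs)
    during = grid <= treat.t_end

    c_ex = np.empty_like(grid)
    c_in = np.empty_like(grid)
    v_ex = np.empty_like(grid)
    v_in = np.empty_like(grid)
    phase = np.where(during, "during", "post")

    if during.any():
        c_ex[during], c_in[during] = concentration_during(
            grid[during], patient, treat, coeffs, consts
        )
        ve, vi = compartment_volumes(grid[during], patient, treat)
        v_ex[during], v_in[during] = ve, vi
    post = None
    if (~during).any():
        post = post_constants(patient, treat, coeffs=coeffs, consts=consts)
        c_ex[~during], c_in[~during] = concentration_post(grid[~during], post, patient)
        v_ex[~during] = post.v_ex_T
        v_in[~during] = post.v_in_T
    return ConcentrationSeries(
        times=grid, phase=phase, c_ex=c_ex, c_in=c_in, v_ex=v_ex, v_in=v_in
    )
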