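"""Explicit-Euler finite-difference integration of the mass balances.

This module is the independent numerical check on the closed forms in
:mod:`ureakin.analytic`: it integrates the variable-volume mass-balance
ODEs directly, with no time transformation and no characteristic roots.
Explicit Euler is used deliberately — the scheme is trivially auditable
and first-order convergence toward the analytic solution is itself one of
the checks.

Concentrations are in mg/dL at this interface (production S, mg/min, is
converted internally).

The published difference formulas this mirrors contain two apparent
typographical slips relative to the underlying mass balances: the
during-phase extracellular update shows a bare ``(omega_f - omega_pl) t``
term where the balance requires ``(omega_f - omega_pl) Cex(t)``, and the
intracellular update divides by the end-of-dialysis volume Vin(T) instead
of Vin(t). The consistent (mass-balance) forms are the default; pass
``as_printed=True`` to reproduce the printed variants for forensic
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import ConcentrationSeries
from .errors import InfeasibleTreatmentError, InvalidArgumentError
from .kinetics import compartment_volumes, resolve_treatment
from .parameters import MGDL_PER_MGML, PatientParameters, TreatmentParameters

__all__ = ["SolverSettings", "fd_step_during", "fd_step_post", "fd_simulate"]


@dataclass(frozen=True)
class SolverSettings:
    """Finite-difference settings: step ``dt`` (min, at most 0.1 so the
    explicit scheme stays well inside its accuracy regime for clinical
    parameter ranges) and horizon ``t_max`` (min)."""

    dt: float = 0.005
    t_max: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 0.1:
            raise InvalidArgumentError("dt must satisfy 0 < dt <= 0.1 min")
        if self.t_max < 0:
            raise InvalidArgumentError("t_max must be non-negative")


def fd_step_during(
    state: tuple[float, float],
    t: float,
    patient: PatientParameters,
    treat: TreatmentParameters,
    dt: float,
    as_printed: bool = False,
) -> tuple[float, float]:
    """One explicit-Euler step of the during-dialysis balances from time t.

    Cex += -(dt/Vex(t)) {K Cex + Ah(Cex - Cin) - wpl Cin - (wf - wpl) Cex}
    Cin += +(dt/Vin(t)) {Ah(Cex - Cin) + S}
    """
    treat = resolve_treatment(patient, treat)
    c_ex, c_in = state
    v_ex, v_in = compartment_volumes(t, patient, treat)
    k, ah = treat.k_clear, patient.ah
    wf, wpl = treat.omega_f, treat.omega_pl
    s = patient.s_prod * MGDL_PER_MGML  # mg/min -> (mg/dL)*mL/min
    drain = (wf - wpl) * t if as_printed else (wf - wpl) * c_ex
    new_ex = c_ex - dt / v_ex * (k * c_ex + ah * (c_ex - c_in) - wpl * c_in - drain)
    if as_printed:
        v_in_T = patient.v_in0 - wpl * treat.t_end
        new_in = c_in + dt / v_in_T * (ah * (c_ex - c_in) + s)
    else:
        new_in = c_in + dt / v_in * (ah * (c_ex - c_in) + s)
    return new_ex, new_in


def fd_step_post(
    state: tuple[float, float],
    patient: PatientParameters,
    end_volumes: tuple[float, float],
    dt: float,
) -> tuple[float, float]:
    """One explicit-Euler step of the constant-volume rebound balances."""
    c_ex, c_in = state
    v_ex_T, v_in_T = end_volumes
    ah = patient.ah
    s = patient.s_prod * MGDL_PER_MGML
    new_ex = c_ex - ah * dt / v_ex_T * (c_ex - c_in)
    new_in = c_in + dt / v_in_T * (ah * (c_ex - c_in) + s)
    return new_ex, new_in


def fd_simulate(
    patient: PatientParameters,
    treat: TreatmentParameters,
    settings: SolverSettings = SolverSettings(),
    as_printed: bool = False,
    grid=None,
    initial_state: tuple[float, float] | None = None,
) -> ConcentrationSeries:
    """Integrate both phases and return the trajectory.

    With ``grid=None`` every step is returned; otherwise the trajectory is
    sampled at the nearest step to each requested time. The post phase
    starts from the during-phase end state with volumes frozen at
    Vex(T), Vin(T). ``initial_state`` overrides (Cex(0), Cin(0)) in mg/dL
    (defaults to Cs in both compartments).
    """
    treat = resolve_treatment(patient, treat)
    dt = settings.dt
    t_end = min(treat.t_end, settings.t_max)
    n_during = int(round(t_end / dt))
    n_total = int(round(settings.t_max / dt))

    times = np.arange(n_total + 1) * dt
    c_ex = np.empty(n_total + 1)
    c_in = np.empty(n_total + 1)
    state = (patient.c_s, patient.c_s) if initial_state is None else initial_state
    c_ex[0], c_in[0] = state

    # Inline scalar form of fd_step_during / fd_step_post (same updates;
    # equivalence is covered by the tests) — the per-step functions carry
    # array/validation overhead that dominates at small dt.
    k, ah = treat.k_clear, patient.ah
    wf, wpl = treat.omega_f, treat.omega_pl
    s = patient.s_prod * MGDL_PER_MGML
    v_ex0, v_in0 = patient.v_ex0, patient.v_in0
    v_in_print = v_in0 - wpl * treat.t_end
    ce, ci = state
    for i in range(n_during):
        t = i * dt
        v_ex_t = v_ex0 - (wf - wpl) * t
        v_in_t = v_in0 - wpl * t
        if v_ex_t <= 0 or v_in_t <= 0:
            raise InfeasibleTreatmentError(
                "ultrafiltration exceeds available fluid during FD run"
            )
        exch = ah * (ce - ci)
        drain = (wf - wpl) * t if as_printed else (wf - wpl) * ce
        ce_new = ce - dt / v_ex_t * (k * ce + exch - wpl * ci - drain)
        ci += dt / (v_in_print if as_printed else v_in_t) * (exch + s)
        ce = ce_new
        c_ex[i + 1], c_in[i + 1] = ce, ci

    end_volumes = compartment_volumes(min(treat.t_end, t_end), patient, treat)
    if n_total > n_during:
        v_ex_T, v_in_T = end_volumes
        for i in range(n_during, n_total):
            exch = ah * (ce - ci)
            ce_new = ce - dt / v_ex_T * exch
            ci += dt / v_in_T * (exch + s)
            ce = ce_new
            c_ex[i + 1], c_in[i + 1] = ce, ci

    during = times <= treat.t_end + 1e-12
    v_ex = np.where(
        during, patient.v_ex0 - (treat.omega_f - treat.omega_pl) * times, end_volumes[0]
    )
    v_in = np.where(during, patient.v_in0 - treat.omega_pl * times, end_volumes[1])
    phase = np.where(during, "during", "post")

    if grid is not None:
        idx = np.rint(np.asarray(grid, dtype=float) / dt).astype(int)
        if np.any(idx < 0) or np.any(idx > n_total):
            raise InvalidArgumentError("grid times outside [0, t_max]")
        times, phase = times[idx], phase[idx]
        c_ex, c_in, v_ex, v_in = c_ex[idx], c_in[idx], v_ex[idx], v_in[idx]
    return ConcentrationSeries(
        times=times, phase=phase, c_ex=c_ex, c_in=c_in, v_ex=v_ex, v_in=v_in
    )
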