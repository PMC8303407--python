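"""Single-compartment comparator formulas: Gotch and Shinzato, plus Kt/V.

Both treat the whole urea distribution volume Ventire = Vex(0) + Vin(0) as
one well-mixed pool drained by a clearance K. The Gotch formula is a pure
exponential washout; the Shinzato formula adds a constant urea generation
term S, giving a steady state at S/K during dialysis and a linear drift
S/Ventire afterwards. They are used here as the baselines the
two-compartment model is compared against, after matching each formula's
clearance to the same end-of-dialysis concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidArgumentError, NoSolutionError, TimeDomainError
from .parameters import MGDL_PER_MGML

__all__ = [
    "SingleCompartmentParameters",
    "shinzato_concentration",
    "gotch_concentration",
    "ktv",
    "match_end_concentration",
]


@dataclass(frozen=True)
class SingleCompartmentParameters:
    """Pool volume (mL), clearance (mL/min), initial concentration (mg/dL),
    production rate (mg/min), and dialysis duration (min)."""

    v_entire: float
    k_sc: float
    c_s: float
    s_prod: float
    t_end: float

    def __post_init__(self) -> None:
        if self.v_entire <= 0:
            raise InvalidArgumentError("v_entire must be positive")
        if self.k_sc < 0:
            raise InvalidArgumentError("k_sc must be non-negative")
        if self.t_end <= 0:
            raise InvalidArgumentError("t_end must be positive")


def shinzato_concentration(t, p: SingleCompartmentParameters):
    """Shinzato single-pool concentration, mg/dL, for any t >= 0.

    During dialysis: C(t) = Cs exp(-Kt/V) + (S/K)(1 - exp(-Kt/V));
    after:           C(t) = C(T) + (S/V)(t - T).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise TimeDomainError("t must be non-negative")
    if p.k_sc == 0 and np.any(t_arr <= p.t_end):
        raise InvalidArgumentError(
            "k_sc = 0 has no during-dialysis closed form (S/K undefined)"
        )
    cs = p.c_s / MGDL_PER_MGML
    decay = np.exp(-p.k_sc * np.minimum(t_arr, p.t_end) / p.v_entire)
    c = cs * decay + (p.s_prod / p.k_sc) * (1.0 - decay)
    c = c + (p.s_prod / p.v_entire) * np.maximum(t_arr - p.t_end, 0.0)
    c = c * MGDL_PER_MGML
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(c)
    return c


def gotch_concentration(t, p: SingleCompartmentParameters):
    """Gotch single-pool concentration Cs exp(-Kt/V), mg/dL; defined only
    during dialysis (0 <= t <= T)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > p.t_end):
        raise TimeDomainError("the Gotch formula is defined on [0, t_end] only")
    c = (p.c_s / MGDL_PER_MGML) * np.exp(-p.k_sc * t_arr / p.v_entire)
    c = c * MGDL_PER_MGML
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(c)
    return c


def ktv(k: float, t: float, v: float) -> float:
    """Dialysis-adequacy index Kt/V (dimensionless)."""
    if v <= 0:
        raise InvalidArgumentError("v must be positive")
    return k * t / v


def match_end_concentration(
    c_target_T: float,
    p: SingleCompartmentParameters,
    model: str = "shinzato",
) -> float:
    """Clearance K (mL/min) such that the chosen single-pool formula hits
    ``c_target_T`` mg/dL at the end of dialysis.

    Deterministic bracketed root finding (Brent) on the monotone
    end-concentration objective; the initial bracket
    [1e-3, 10 Ventire/T] is expanded geometrically if needed.
    """
    if model not in ("shinzato", "gotch"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    if model == "gotch" and not 0.0 < c_target_T < p.c_s:
        raise NoSolutionError(
            "Gotch end concentration must lie strictly between 0 and Cs"
        )

    def end_conc(k: float) -> float:
        q = SingleCompartmentParameters(
            v_entire=p.v_entire, k_sc=k, c_s=p.c_s, s_prod=p.s_prod, t_end=p.t_end
        )
        f = shinzato_concentration if model == "shinzato" else gotch_concentration
        return f(p.t_end, q) - c_target_T

    lo, hi = 1e-3, 10.0 * p.v_entire / p.t_end
    for _ in range(8):
        try:
            f_lo, f_hi = end_conc(lo), end_conc(hi)
        except (OverflowError, FloatingPointError):  # pragma: no cover
            raise NoSolutionError("objective not evaluable on bracket")
        if f_lo == 0.0:
            return lo
        if f_hi == 0.0:
            return hi
        if f_lo * f_hi < 0:
            return float(brentq(end_conc, lo, hi, xtol=1e-12, rtol=1e-12))
        lo, hi = lo / 10.0, hi * 10.0
    raise NoSolutionError(
        f"target {c_target_T} mg/dL unattainable by the {model} formula "
        "(outside its reachable end-concentration range)"
    )
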