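"""Estimation of (K, Ah, S) from measured blood concentrations, and a
synthetic-measurement generator emulating clinical blood sampling.

Measured blood concentration is identified with the extracellular
concentration Cex: dialysis samples blood, and blood is part of the
extracellular pool. The fit is joint unweighted least squares over all
points (during and post phase together), solved with a bounded
deterministic trust-region-reflective optimizer; randomness lives only in
the synthetic generator.

The estimator follows the scikit-learn protocol (``fit(X, y)`` /
``predict(X)``, fitted attributes with a trailing underscore), so it
composes with sklearn model selection; :func:`fit_parameters` is the thin
functional wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .analytic import (
    concentration_during,
    concentration_post,
    during_constants,
    post_constants,
)
from .errors import IdentifiabilityWarning, InvalidArgumentError, KineticsError
from .kinetics import ode_coefficients, resolve_treatment
from .parameters import PatientParameters, TreatmentParameters

__all__ = [
    "MeasurementSeries",
    "FitResult",
    "SyntheticSpec",
    "CLINICAL_SAMPLE_TIMES",
    "generate_measurements",
    "TwoCompartmentRegressor",
    "fit_parameters",
    "model_blood_concentration",
]

#: Default blood-sampling schedule (min): hourly-ish draws during a 240-min
#: session plus five draws over the first hour after it, when the rebound
#: is steepest — the cadence of clinical rebound studies.
CLINICAL_SAMPLE_TIMES = (
    0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0,
    245.0, 250.0, 260.0, 280.0, 300.0,
)

#: Free-parameter names mapped to the attributes that hold them.
_FREE_ATTR = {"K": "k_clear", "Ah": "ah", "S": "s_prod"}
_DEFAULT_BOUNDS = {"K": (None, 500.0), "Ah": (10.0, 5000.0), "S": (0.0, 20.0)}


def model_blood_concentration(
    times, patient: PatientParameters, treat: TreatmentParameters
) -> np.ndarray:
    """Two-compartment Cex (mg/dL) at arbitrary times spanning both phases."""
    treat = resolve_treatment(patient, treat)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    coeffs = ode_coefficients(patient, treat)
    consts = during_constants(patient, treat, coeffs)
    out = np.empty_like(times)
    during = times <= treat.t_end
    if during.any():
        out[during] = concentration_during(
            times[during], patient, treat, coeffs, consts
        )[0]
    if (~during).any():
        post = post_constants(patient, treat, coeffs=coeffs, consts=consts)
        out[~during] = concentration_post(times[~during], post, patient)[0]
    return out


@dataclass
class MeasurementSeries:
    """A measured (or synthetic) blood concentration time series.

    ``times`` strictly increasing (min), ``c_measured`` in mg/dL,
    ``phase`` per point (``"during"``/``"post"``).
    """

    times: np.ndarray
    c_measured: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_measured = np.asarray(self.c_measured, dtype=float)
        self.phase = np.asarray(self.phase)
        if self.times.size == 0:
            raise InvalidArgumentError("measurement series is empty")
        if not (self.times.size == self.c_measured.size == self.phase.size):
            raise InvalidArgumentError("times, c_measured, phase sizes differ")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")

    @property
    def n_post(self) -> int:
        return int(np.sum(self.phase == "post"))

    @classmethod
    def from_arrays(cls, times, c_measured, t_end: float) -> "MeasurementSeries":
        times = np.asarray(times, dtype=float)
        phase = np.where(times <= t_end, "during", "post")
        return cls(times=times, c_measured=c_measured, phase=phase)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.times, "c_mg_dl": self.c_measured, "phase": self.phase}
        )


@dataclass(frozen=True)
class FitResult:
    """Point estimates with the residual sum of squares (mg/dL)^2 and
    optimizer metadata."""

    k_hat: float
    ah_hat: float
    s_hat: float
    rss: float
    n_iter: int
    converged: bool


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic clinical series: true parameters, sampling
    times (min), additive Gaussian noise sd (mg/dL), and RNG seed."""

    patient: PatientParameters
    treat: TreatmentParameters
    sample_times: tuple[float, ...] = CLINICAL_SAMPLE_TIMES
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")


def generate_measurements(spec: SyntheticSpec) -> MeasurementSeries:
    """Sample the two-compartment Cex at the given times and add
    independent zero-mean Gaussian noise; reproducible under a fixed seed."""
    times = np.asarray(spec.sample_times, dtype=float)
    truth = model_blood_concentration(times, spec.patient, spec.treat)
    rng = np.random.default_rng(spec.seed)
    noisy = truth + rng.normal(0.0, spec.noise_sd, size=times.size)
    return MeasurementSeries.from_arrays(times, noisy, spec.treat.t_end)


class TwoCompartmentRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the two-compartment blood-concentration model.

    Parameters double as the fixed values of the non-free quantities and
    the initial point for the free ones (override via ``init``). Defaults
    are the standard Japanese treatment conditions (K = 200 mL/min,
    Ah = 500 mL/min, S = 4 mg/min, 36 L fluid split 4:6, Cs = 80 mg/dL,
    240 min, 20 mL/min ultrafiltration).

    Parameters
    ----------
    free : tuple of {"K", "Ah", "S"}
        Which parameters the optimizer may vary.
    bounds : dict, optional
        Per-parameter ``(lo, hi)`` overrides. Defaults:
        K in (omega_f, 500], Ah in [10, 5000], S in [0, 20].
    init : dict, optional
        Per-parameter starting values for the free parameters.
    penalty : float
        Residual magnitude substituted when a trial point is infeasible
        for the model (degenerate clearance, collapsed volume, ...).

    Attributes
    ----------
    k_, ah_, s_ : float
        Estimates (free) or fixed inputs (not free) after ``fit``.
    rss_ : float
        Residual sum of squares at the solution, (mg/dL)^2.
    n_iter_ : int
        Number of residual evaluations used.
    converged_ : bool
        Optimizer success flag (a failed fit is reported, not raised).
    """

    def __init__(
        self,
        *,
        k_clear: float = 200.0,
        ah: float = 500.0,
        s_prod: float = 4.0,
        v_ex0: float = 14400.0,
        v_in0: float = 21600.0,
        eps: float | None = None,
        c_s: float = 80.0,
        t_end: float = 240.0,
        omega_f: float = 20.0,
        omega_pl: float | None = None,
        free: tuple[str, ...] = ("K", "Ah", "S"),
        bounds: dict | None = None,
        init: dict | None = None,
        penalty: float = 1e6,
    ):
        self.k_clear = k_clear
        self.ah = ah
        self.s_prod = s_prod
        self.v_ex0 = v_ex0
        self.v_in0 = v_in0
        self.eps = eps
        self.c_s = c_s
        self.t_end = t_end
        self.omega_f = omega_f
        self.omega_pl = omega_pl
        self.free = free
        self.bounds = bounds
        self.init = init
        self.penalty = penalty

    # -- model assembly ----------------------------------------------------
    def _assemble(self, k: float, ah: float, s: float):
        patient = PatientParameters(
            v_ex0=self.v_ex0,
            v_in0=self.v_in0,
            eps=self.eps,
            c_s=self.c_s,
            s_prod=s,
            ah=ah,
        )
        treat = TreatmentParameters(
            k_clear=k, t_end=self.t_end, omega_f=self.omega_f, omega_pl=self.omega_pl
        )
        return patient, resolve_treatment(patient, treat)

    def _values(self) -> dict[str, float]:
        return {"K": self.k_clear, "Ah": self.ah, "S": self.s_prod}

    def _bounds_for(self, name: str) -> tuple[float, float]:
        lo, hi = _DEFAULT_BOUNDS[name]
        if lo is None:  # K: open interval above omega_f
            lo = self.omega_f + 1e-3
        if self.bounds and name in self.bounds:
            lo, hi = self.bounds[name]
        return float(lo), float(hi)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise InvalidArgumentError("X and y have different lengths")
        free = tuple(self.free)
        for name in free:
            if name not in _FREE_ATTR:
                raise InvalidArgumentError(f"unknown free parameter {name!r}")
        if "S" in free and not np.any(t > self.t_end):
            warnings.warn(
                "no post-dialysis points: the production rate S is weakly "
                "identified from during-dialysis data alone",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        if free and t.size < len(free) + 1:
            warnings.warn(
                f"only {t.size} points for {len(free)} free parameters",
                IdentifiabilityWarning,
                stacklevel=2,
            )

        values = self._values()

        def unpack(theta):
            trial = dict(values)
            for name, v in zip(free, theta):
                trial[name] = float(v)
            return trial

        def residual(theta):
            trial = unpack(theta)
            try:
                patient, treat = self._assemble(trial["K"], trial["Ah"], trial["S"])
                model = model_blood_concentration(t, patient, treat)
            except (KineticsError, ValueError):
                return np.full(t.size, self.penalty)
            return model - y

        if free:
            x0 = np.array(
                [
                    (self.init or {}).get(name, values[name])
                    for name in free
                ],
                dtype=float,
            )
            lo = np.array([self._bounds_for(n)[0] for n in free])
            hi = np.array([self._bounds_for(n)[1] for n in free])
            x0 = np.clip(x0, lo, hi)
            res = least_squares(
                residual, x0, bounds=(lo, hi), method="trf", x_scale="jac"
            )
            fitted = unpack(res.x)
            self.rss_ = float(np.sum(res.fun**2))
            self.n_iter_ = int(res.nfev)
            self.converged_ = bool(res.success)
        else:
            fitted = dict(values)
            self.rss_ = float(np.sum(residual(())**2))
            self.n_iter_ = 0
            self.converged_ = True
        self.k_ = fitted["K"]
        self.ah_ = fitted["Ah"]
        self.s_ = fitted["S"]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "k_"):
            raise InvalidArgumentError("estimator is not fitted")
        t = np.asarray(X, dtype=float).reshape(-1)
        patient, treat = self._assemble(self.k_, self.ah_, self.s_)
        return model_blood_concentration(t, patient, treat)

    def result_(self) -> FitResult:
        return FitResult(
            k_hat=self.k_,
            ah_hat=self.ah_,
            s_hat=self.s_,
            rss=self.rss_,
            n_iter=self.n_iter_,
            converged=self.converged_,
        )


def fit_parameters(
    data: MeasurementSeries,
    patient: PatientParameters,
    treat: TreatmentParameters,
    free: tuple[str, ...] = ("K", "Ah", "S"),
    bounds: dict | None = None,
    init: dict | None = None,
) -> FitResult:
    """Functional wrapper around :class:`TwoCompartmentRegressor`.

    ``patient``/``treat`` supply the fixed values and the default initial
    point for the free parameters.
    """
    est = TwoCompartmentRegressor(
        k_clear=treat.k_clear,
        ah=patient.ah,
        s_prod=patient.s_prod,
        v_ex0=patient.v_ex0,
        v_in0=patient.v_in0,
        eps=patient.eps,
        c_s=patient.c_s,
        t_end=treat.t_end,
        omega_f=treat.omega_f,
        omega_pl=treat.omega_pl,
        free=free,
        bounds=bounds,
        init=init,
    )
    est.fit(data.times, data.c_measured)
    return est.result_()
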