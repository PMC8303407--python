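"""Parameter types, unit conventions, and config-file handling.

Unit conventions used throughout the package
--------------------------------------------
volumes            mL
flows (K, omega_f, omega_pl, Ah)   mL/min
time               min
toxin production S mg/min
concentrations     mg/dL at every public interface; mg/mL internally
                   (1 mg/mL = 100 mg/dL), so that S/gamma
                   (mg/min / (mL/min) = mg/mL) is dimensionally consistent
                   with concentration terms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: mg/dL per mg/mL.
MGDL_PER_MGML = 100.0


class PatientParameters(BaseModel):
    """Patient-side parameters of the two-compartment model.

    Attributes
    ----------
    v_ex0, v_in0 : float
        Extracellular / intracellular fluid volume at the start of
        dialysis, mL.
    eps : float
        Constant extracellular:intracellular volume ratio
        ``eps = Vex/Vin``. Derived from ``v_ex0 / v_in0`` when omitted;
        a (possibly rounded) explicit value is accepted as supplied.
    c_s : float
        Initial toxin concentration of both compartments, mg/dL.
    s_prod : float
        Constant toxin (urea) production rate, mg/min.
    ah : float
        Volumetric mass-transfer coefficient between the compartments —
        total exchange surface area times the overall mass-transfer
        coefficient — mL/min.
    """

    model_config = ConfigDict(frozen=True)

    v_ex0: float = Field(gt=0)
    v_in0: float = Field(gt=0)
    eps: float = Field(gt=0)
    c_s: float = Field(ge=0)
    s_prod: float = Field(ge=0)
    ah: float = Field(gt=0)

    @model_validator(mode="before")
    @classmethod
    def _derive_eps(cls, data: Any) -> Any:
        if isinstance(data, dict) and data.get("eps") is None:
            try:
                data = {**data, "eps": float(data["v_ex0"]) / float(data["v_in0"])}
            except (KeyError, TypeError, ValueError, ZeroDivisionError):
                pass
        return data

    @property
    def c_s_mgml(self) -> float:
        """Initial concentration in internal units (mg/mL)."""
        return self.c_s / MGDL_PER_MGML


class TreatmentParameters(BaseModel):
    """Dialysis-treatment parameters.

    Attributes
    ----------
    k_clear : float
        Dialyzer clearance K, mL/min.
    t_end : float
        Dialysis duration T, min.
    omega_f : float
        Ultrafiltration flow rate, mL/min.
    omega_pl : float or None
        Plasma-refilling rate, mL/min. ``None`` means "estimate from the
        constant-volume-ratio relation"; see
        :func:`ureakin.kinetics.resolve_treatment`.
    """

    model_config = ConfigDict(frozen=True)

    k_clear: float = Field(ge=0)
    t_end: float = Field(gt=0)
    omega_f: float = Field(ge=0)
    omega_pl: float | None = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "TreatmentParameters":
        if self.omega_pl is not None:
            if self.omega_pl < 0:
                raise ValueError("omega_pl must be non-negative")
            if self.omega_f > 0 and self.omega_pl >= self.omega_f:
                raise ValueError(
                    "omega_pl: plasma refilling must stay below the "
                    "ultrafiltration rate omega_f"
                )
            if self.omega_f == 0 and self.omega_pl > 0:
                raise ValueError("omega_pl: refilling without ultrafiltration")
        if self.k_clear == self.omega_f:
            raise ValueError(
                "k_clear: degenerate clearance — K equals omega_f, the forcing "
                "coefficient gamma vanishes and no closed-form solution exists"
            )
        return self


def body_fluid_volumes(
    weight_kg: float = 60.0,
    fluid_fraction: float = 0.60,
    extracellular_fraction: float = 0.40,
) -> tuple[float, float]:
    """Anthropometric convention for the compartment volumes, in mL.

    Defaults are the average values conventionally used for Japanese
    dialysis patients: 60 kg body weight, 60 % body fluid, and a 4:6
    extracellular:intracellular split (1 kg of fluid taken as 1000 mL).

    Returns ``(v_ex0, v_in0)``.
    """
    total = weight_kg * fluid_fraction * 1000.0
    v_ex0 = total * extracellular_fraction
    return v_ex0, total - v_ex0


#: Standard treatment conditions (the package's worked example): K = 200
#: mL/min, T = 240 min over a 36 L urea distribution volume split 4:6,
#: Cs = 80 mg/dL, 4.8 L ultrafiltered, Ah = 500 mL/min, S = 4 mg/min.
DEFAULT_CONFIG: dict[str, Any] = {
    "K": 200.0,
    "T": 240.0,
    "eps": 0.667,
    "Vex0": 14400.0,
    "Vin0": 21600.0,
    "Cs": 80.0,
    "omega_f": 20.0,
    "omega_pl": None,
    "Ah": 500.0,
    "S": 4.0,
}

_CONFIG_KEYS = set(DEFAULT_CONFIG)


def params_from_mapping(
    raw: dict[str, Any],
) -> tuple[PatientParameters, TreatmentParameters]:
    """Build parameter objects from a config mapping keyed by the
    conventional symbols (K, T, eps, Vex0, Vin0, Cs, omega_f, omega_pl,
    Ah, S). Unknown keys are rejected; ``omega_pl: null`` leaves the
    refilling rate to be estimated."""
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **raw}
    patient = PatientParameters(
        v_ex0=cfg["Vex0"],
        v_in0=cfg["Vin0"],
        eps=cfg["eps"],
        c_s=cfg["Cs"],
        s_prod=cfg["S"],
        ah=cfg["Ah"],
    )
    treat = TreatmentParameters(
        k_clear=cfg["K"],
        t_end=cfg["T"],
        omega_f=cfg["omega_f"],
        omega_pl=cfg["omega_pl"],
    )
    return patient, treat


class InvalidConfigError(ValueError):
    """Config file contains unknown or malformed entries."""


def load_config(path: str | Path) -> tuple[PatientParameters, TreatmentParameters]:
    """Load a JSON or YAML config file (dispatch on extension; YAML parses
    JSON too, so unknown extensions fall back to YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: expected a mapping at top level")
    return params_from_mapping(raw)
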